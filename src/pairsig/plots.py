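"""Optional KM and tdROC plots (matplotlib, file output only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_km(km_result: dict, path: str | Path) -> None:
    """Step-plot the Kaplan–Meier curves of a km_logrank result."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in km_result["km_curves"].items():
        ax.step(curve["time"], curve["survival"], where="post", label=label)
    p = km_result.get("logrank_p")
    if p is not None:
        ax.set_title(f"log-rank p = {p:.3g}")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(roc: dict, path: str | Path) -> None:
    """Plot a time-dependent ROC curve from a td_roc result."""
    import numpy as np

    fpr = 1.0 - roc["specificity"]
    order = np.argsort(fpr)
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.plot(np.concatenate(([0], fpr[order], [1])),
            np.concatenate(([0], roc["sensitivity"][order], [1])),
            drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{roc['horizon']:.0f}-month AUC = {roc['auc']:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
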