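"""Regenerate the stored expected signature for the toy regression fixture.

Run from the repository root:

    python scripts/regenerate_toy_expected.py

Rewrites tests/data/toy_expected_signature.json from the deterministic toy
cohort (pairsig.simulate.make_toy_fixture) under the fixed toy pipeline
settings used by the test suite.
"""

from pathlib import Path

from pairsig.pipeline import PipelineConfig, run_pipeline_frames
from pairsig.simulate import make_toy_fixture

TOY_PIPELINE = dict(train_fraction=0.6, screen_alpha=0.05, n_folds=4, seed=7)


def main() -> None:
    expr, clin, truth = make_toy_fixture()
    res = run_pipeline_frames(expr, clin, PipelineConfig(**TOY_PIPELINE))
    sig = res["signature"]
    out = Path(__file__).resolve().parent.parent / "tests" / "data" / \
        "toy_expected_signature.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    sig.to_json(out)
    recovered = set(truth.planted_pair_ids) & set(sig.pair_ids)
    print(f"wrote {out} ({len(sig)} pairs, cutoff {sig.cutoff:.4f}, "
          f"recovered {len(recovered)}/{len(truth.planted_pairs)} planted pairs)")


if __name__ == "__main__":
    main()
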