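"""Reading, writing and aligning expression matrices, clinical tables and gene lists.

Conventions
-----------
* Expression matrices are pandas DataFrames with gene ids as the index and
  sample ids as columns; values are nonnegative normalized expression on any
  within-sample-comparable scale (FPKM, TPM, array intensity, qPCR relative
  expression — the downstream rank transform only uses within-sample order).
* Clinical tables are pandas DataFrames indexed by ``sample_id`` with columns
  ``os_time`` (months, > 0), ``os_event`` (0 = censored, 1 = death) and the
  optional coded covariates ``age``, ``gender`` (0 = female, 1 = male),
  ``mgmt_status`` (0 = methylated, 1 = unmethylated, NaN = missing),
  ``dataset``, ``subtype``, ``chemo``, ``radio``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

#: days per month used when converting day-scaled survival times
DAYS_PER_MONTH = 30.4375

_GENDER_CODES = {
    "female": 0, "f": 0, "0": 0,
    "male": 1, "m": 1, "1": 1,
}
_MGMT_CODES = {
    "methylated": 0, "0": 0,
    "unmethylated": 1, "un-methylated": 1, "1": 1,
}


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise InputError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    return "," if fmt == "csv" else "\t"


def read_expression(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV/CSV.

    The first column holds gene ids, the header row sample ids.  Duplicate
    gene rows are collapsed by keeping the row with the highest mean; genes
    with any missing value are dropped.  Both actions are logged.
    """
    path = Path(path)
    sep = _sep_for(path, format)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse expression file {path}: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise InputError(f"expression matrix in {path} is empty")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression values in {path}: {exc}") from exc

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise InputError(f"duplicate sample ids in {path}: {dups}")

    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        order = df.mean(axis=1).groupby(level=0).transform("max") == df.mean(axis=1)
        # keep-highest-mean; a stable first() breaks exact mean ties
        df = df[order].groupby(level=0, sort=False).first()
        logger.info("collapsed %d duplicate gene rows (kept highest mean)", n_dup)

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        df = df.dropna(axis=0)
        logger.info("dropped %d genes with missing values", n_missing)
    if df.empty:
        raise InputError(f"expression matrix in {path} has no complete gene rows")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"negative expression values in {path}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    # %.17g guarantees exact float64 round-trip through text
    expr.to_csv(path, sep=_sep_for(path, format), index_label="gene_id",
                float_format="%.17g")


def read_clinical(path: str | Path, format: str | None = None,
                  time_unit: str = "months") -> pd.DataFrame:
    """Read and validate a clinical table.

    Required columns: ``sample_id``, ``os_time``, ``os_event``.  Textual
    covariate values are mapped to the numeric coding (female -> 0, male -> 1;
    methylated -> 0, unmethylated -> 1).  ``time_unit='days'`` converts
    survival times to months.
    """
    path = Path(path)
    sep = _sep_for(path, format)
    try:
        df = pd.read_csv(path, sep=sep)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse clinical file {path}: {exc}") from exc

    required = {"sample_id", "os_time", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"clinical table {path} lacks columns: {sorted(missing)}")

    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample ids in {path}: {dups}")
    df = df.set_index("sample_id")

    df["os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
    df["os_event"] = pd.to_numeric(df["os_event"], errors="coerce")
    for sid, row in df.iterrows():
        if not np.isfinite(row["os_time"]) or row["os_time"] <= 0:
            raise ValidationError(f"sample {sid!r}: os_time must be > 0, got {row['os_time']}")
        if row["os_event"] not in (0, 1):
            raise ValidationError(f"sample {sid!r}: os_event must be 0 or 1, got {row['os_event']}")
    df["os_event"] = df["os_event"].astype(int)
    if time_unit == "days":
        df["os_time"] = df["os_time"] / DAYS_PER_MONTH
    elif time_unit != "months":
        raise InputError(f"unknown time_unit {time_unit!r}")

    if "gender" in df.columns:
        df["gender"] = _recode(df["gender"], _GENDER_CODES, "gender")
    if "mgmt_status" in df.columns:
        df["mgmt_status"] = _recode(df["mgmt_status"], _MGMT_CODES, "mgmt_status")
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    for flag in ("chemo", "radio"):
        if flag in df.columns:
            df[flag] = pd.to_numeric(df[flag], errors="coerce")
    return df


def _recode(col: pd.Series, mapping: dict[str, int], name: str) -> pd.Series:
    def one(v: object) -> float:
        if pd.isna(v):
            return np.nan
        key = str(v).strip().lower()
        # already-numeric coding passes through
        if key in mapping:
            return float(mapping[key])
        try:
            fv = float(key)
        except ValueError:
            raise ValidationError(f"cannot code {name} value {v!r}") from None
        if fv in (0.0, 1.0):
            return fv
        raise ValidationError(f"cannot code {name} value {v!r}")

    return col.map(one)


def write_clinical(clin: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    clin.to_csv(path, sep=_sep_for(path, format), index_label="sample_id")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a gene list: one id per line, '#' comments and blank lines ignored."""
    genes: list[str] = []
    seen = set()
    n_dup = 0
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line in seen:
            n_dup += 1
            continue
        seen.add(line)
        genes.append(line)
    if n_dup:
        logger.info("ignored %d duplicate gene ids in %s", n_dup, path)
    if not genes:
        raise InputError(f"gene list {path} is empty")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def align_cohort(expr: pd.DataFrame, clin: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict expression and clinical data to their shared samples, same order.

    Sample order follows the expression matrix.  Idempotent; raises
    :class:`InputError` on an empty intersection.
    """
    shared = [s for s in expr.columns if s in set(clin.index)]
    if not shared:
        raise InputError("expression and clinical tables share no samples")
    n_drop_expr = expr.shape[1] - len(shared)
    n_drop_clin = clin.shape[0] - len(shared)
    if n_drop_expr or n_drop_clin:
        logger.info("align_cohort dropped %d expression / %d clinical samples",
                    n_drop_expr, n_drop_clin)
    return expr[shared], clin.loc[shared]


def intersect_gene_universe(matrices: Iterable[pd.DataFrame],
                            gene_set: Sequence[str]) -> list[str]:
    """Genes present in ``gene_set`` and in every matrix, in gene_set order."""
    matrices = list(matrices)
    if not matrices:
        raise InputError("need at least one expression matrix")
    present: set[str] = set(gene_set)
    for m in matrices:
        present &= set(m.index)
    result = [g for g in gene_set if g in present]
    if not result:
        raise InputError("gene universe intersection is empty")
    return result
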