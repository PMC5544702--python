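"""Core data model, file readers/writers, and run configuration.

Expression matrices are log-scale gene x sample tables; clinical tables carry
per-sample annotations (grade/stage/size, survival, optional multi-region
tumor ids and free grouping labels).  All on-disk formats are delimited text
(tab canonical, comma accepted) so that data round-trips losslessly at the
printed precision.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("clearscore")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "align",
]

#: Columns of the clinical table with a dedicated dtype; anything else is
#: preserved untouched as opaque annotation.
_CLIN_TYPED = ("grade", "stage", "size", "time", "event", "tumor_id", "group_label")


class ClearScoreError(Exception):
    """Base class for user-facing errors."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log-scale expression values, genes in rows, samples in columns.

    Parameters
    ----------
    data : pandas.DataFrame
        Real-valued matrix indexed by gene id with sample ids as columns.
        All entries must be finite; both axes must be duplicate-free and of
        length >= 2.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ClearScoreError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ClearScoreError(f"duplicate sample ids: {dups}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ClearScoreError(
                f"expression matrix needs >=2 genes and >=2 samples, got {df.shape}"
            )
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            raise ClearScoreError(
                f"expression matrix contains {n_bad} non-finite values; "
                "impute or drop before constructing"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise ClearScoreError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ClearScoreError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(sample_ids)])

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.data[sample_id].to_numpy()


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample clinical annotations keyed by unique sample id.

    Optional fields (grade, stage, size, tumor_id, group_label) are NaN/None
    when absent, never silently zero.  `time` is follow-up in months, `event`
    is 1 for cancer-specific death and 0 for censoring.
    """

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data.copy()
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ClearScoreError(f"duplicate sample ids in clinical table: {dups}")
        for col in ("grade", "stage", "size", "time"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="raise")
        if "time" in df.columns:
            bad = df.index[df["time"].notna() & (df["time"] < 0)]
            if len(bad):
                raise ClearScoreError(f"negative follow-up time for samples: {list(bad)}")
        if "event" in df.columns:
            ev = pd.to_numeric(df["event"], errors="raise")
            bad = df.index[ev.notna() & ~ev.isin([0, 1])]
            if len(bad):
                raise ClearScoreError(f"event must be 0/1; offending samples: {list(bad)}")
            df["event"] = ev
        if "grade" in df.columns:
            g = df["grade"]
            bad = df.index[g.notna() & ~g.isin([1, 2, 3, 4])]
            if len(bad):
                raise ClearScoreError(f"grade must be in 1..4; offending samples: {list(bad)}")
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise ClearScoreError(f"clinical table has no column {name!r}")
        return self.data[name]

    def has_column(self, name: str) -> bool:
        return name in self.data.columns and self.data[name].notna().any()

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ClearScoreError(f"samples not in clinical table: {missing[:10]}")
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def survival(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (time, event, sample_ids) for samples with complete survival."""
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise ClearScoreError("clinical table lacks time/event columns")
        ok = self.data["time"].notna() & self.data["event"].notna()
        sub = self.data.loc[ok]
        return (
            sub["time"].to_numpy(dtype=float),
            sub["event"].to_numpy(dtype=int),
            list(sub.index),
        )


@dataclass(frozen=True)
class RunConfig:
    """Knobs of the scoring algorithm with their standard defaults."""

    gene_filter_threshold: float = 8.0
    gene_filter_fraction: float = 0.10
    subset_fraction: float = 0.5
    n_boot: int = 100
    correlation_method: str = "pearson"  # or "spearman"
    distance_kind: str = "one_minus_corr"  # or "raw_corr"
    centroid_statistic: str = "median"  # or "mean"
    epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subset_fraction <= 1):
            raise ClearScoreError("subset_fraction must be in (0, 1]")
        if self.n_boot < 1:
            raise ClearScoreError("n_boot must be >= 1")
        if self.epsilon <= 0:
            raise ClearScoreError("epsilon must be positive")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ClearScoreError(f"unknown correlation_method {self.correlation_method!r}")
        if self.distance_kind not in ("one_minus_corr", "raw_corr"):
            raise ClearScoreError(f"unknown distance_kind {self.distance_kind!r}")
        if self.centroid_statistic not in ("median", "mean"):
            raise ClearScoreError(f"unknown centroid_statistic {self.centroid_statistic!r}")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a TOML config file; keyword overrides win over file values."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ClearScoreError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression(
    path: str | Path,
    orientation: str = "genes_in_rows",
    impute: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table into a genes x samples matrix.

    The first column holds identifiers (genes for ``genes_in_rows``, samples
    for ``samples_in_rows``).  Values must be numeric; missing entries are a
    hard error unless ``impute`` enables per-gene median imputation.  Values
    are expected to be log-scale already: if more than 1% exceed 30 a warning
    about a likely linear-scale matrix is logged.
    """
    path = Path(path)
    if not path.exists():
        raise ClearScoreError(f"no such file: {path}")
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ClearScoreError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_in_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    # locate non-numeric cells precisely before failing
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ClearScoreError(
            f"non-numeric expression value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    df = coerced
    if df.isna().to_numpy().any():
        if not impute:
            n_missing = int(df.isna().to_numpy().sum())
            raise ClearScoreError(
                f"{n_missing} missing expression values in {path}; "
                "enable imputation or clean the file"
            )
        medians = df.median(axis=1)
        df = df.T.fillna(medians).T
        logger.warning("imputed missing expression values with per-gene medians")
    values = df.to_numpy()
    frac_large = float((values > 30).mean())
    if frac_large > 0.01:
        logger.warning(
            "%.1f%% of expression values exceed 30; matrix may be linear scale, "
            "log-transform upstream if so",
            100 * frac_large,
        )
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write tab-delimited, 6 significant digits, gene ids in first column."""
    out = expr.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a delimited clinical annotation table keyed by ``sample_id``."""
    path = Path(path)
    if not path.exists():
        raise ClearScoreError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"tumor_id": str, "group_label": str})
    if "sample_id" not in df.columns:
        raise ClearScoreError(f"clinical table {path} lacks a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    out = clin.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def align(expr: ExpressionMatrix, clin: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both tables to their common samples, in matching order.

    Ordering follows the expression matrix.  Drop counts per side are logged;
    an empty intersection is a hard error.
    """
    common = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if not common:
        raise ClearScoreError("expression and clinical tables share no samples")
    dropped_expr = expr.n_samples - len(common)
    dropped_clin = len(clin.sample_ids) - len(common)
    if dropped_expr or dropped_clin:
        logger.info(
            "align: dropped %d expression-only and %d clinical-only samples",
            dropped_expr,
            dropped_clin,
        )
    return expr.subset_samples(common), clin.subset(common)
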