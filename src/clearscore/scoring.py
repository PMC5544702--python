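"""Continuous aggressiveness scoring against paired reference centroids.

A sample's raw score is the bootstrap-averaged ratio of its correlation
distance to a "low" reference centroid (e.g. the grade-1 sample set) over
its distance to a "high" centroid (grade 4): values near 0 mean the sample
resembles the low extreme, large values the high extreme.  Cohort raw scores
are then min-max scaled onto [1, 100].
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .iocore import ClearScoreError, ClinicalTable, ExpressionMatrix, RunConfig

logger = logging.getLogger("clearscore")

__all__ = [
    "RSSProfiles",
    "ClearScoreResult",
    "filter_genes",
    "build_rss",
    "raw_score",
    "score_cohort",
    "scale_scores",
    "score_new_samples",
]

#: value assigned to every sample when the cohort's raw scores are all equal
DEGENERATE_SCALED = 50.5


@dataclass(frozen=True)
class RSSProfiles:
    """Paired reference centroids anchoring the two clinical extremes."""

    gene_ids: tuple[str, ...]
    profile_low: np.ndarray
    profile_high: np.ndarray
    n_low: int
    n_high: int
    clinical_axis: str

    def __post_init__(self) -> None:
        for name, prof in (("profile_low", self.profile_low), ("profile_high", self.profile_high)):
            arr = np.asarray(prof, dtype=float)
            if arr.shape != (len(self.gene_ids),):
                raise ClearScoreError(f"{name} length != number of gene ids")
            if not np.isfinite(arr).all():
                raise ClearScoreError(f"{name} contains non-finite values")
            if np.ptp(arr) == 0:
                raise ClearScoreError(f"{name} is constant; correlation undefined")
            object.__setattr__(self, name, arr)
        if self.n_low < 1 or self.n_high < 1:
            raise ClearScoreError("each reference set needs at least one member")

    def swap(self) -> "RSSProfiles":
        return RSSProfiles(
            gene_ids=self.gene_ids,
            profile_low=self.profile_high,
            profile_high=self.profile_low,
            n_low=self.n_high,
            n_high=self.n_low,
            clinical_axis=self.clinical_axis,
        )

    def subset(self, gene_ids: Sequence[str]) -> "RSSProfiles":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return RSSProfiles(
            gene_ids=tuple(gene_ids),
            profile_low=self.profile_low[idx],
            profile_high=self.profile_high[idx],
            n_low=self.n_low,
            n_high=self.n_high,
            clinical_axis=self.clinical_axis,
        )


@dataclass(frozen=True)
class ClearScoreResult:
    """Raw and [1,100]-scaled scores with everything needed to re-apply them."""

    sample_ids: tuple[str, ...]
    raw_scores: np.ndarray
    scaled_scores: np.ndarray
    scale_min: float
    scale_max: float
    params: RunConfig
    rss: RSSProfiles

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw_score": self.raw_scores, "clear_score": self.scaled_scores},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


# ---------------------------------------------------------------------------
# gene filtering and reference construction


def filter_genes(
    expr: ExpressionMatrix,
    threshold: float = 8.0,
    fraction: float = 0.10,
) -> list[str]:
    """Keep genes whose log expression exceeds ``threshold`` in at least
    ``ceil(fraction * n_samples)`` samples; order follows the input matrix."""
    need = int(np.ceil(fraction * expr.n_samples))
    counts = (expr.values > threshold).sum(axis=1)
    kept = [g for g, c in zip(expr.gene_ids, counts) if c >= need]
    if not kept:
        raise ClearScoreError(
            f"gene filter (> {threshold} in >= {need} samples) removed every gene; "
            "relax the threshold or fraction"
        )
    logger.info("gene filter kept %d/%d genes", len(kept), expr.n_genes)
    return kept


def _axis_extremes(
    clin: ClinicalTable, axis: str, low_value, high_value
) -> tuple[list[str], list[str]]:
    vals = clin.column(axis)
    if axis == "size" and low_value is None and high_value is None:
        # extremes never defined for continuous size: bottom/top quartile default
        present = vals.dropna()
        q1, q3 = present.quantile(0.25), present.quantile(0.75)
        low_ids = list(present.index[present <= q1])
        high_ids = list(present.index[present >= q3])
        return low_ids, high_ids
    if low_value is None:
        low_value = vals.min()
    if high_value is None:
        high_value = vals.max()
    if low_value == high_value:
        raise ClearScoreError(f"axis {axis!r}: low and high extreme coincide ({low_value})")
    low_ids = list(vals.index[vals == low_value])
    high_ids = list(vals.index[vals == high_value])
    return low_ids, high_ids


def build_rss(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    axis: str = "grade",
    low_value=None,
    high_value=None,
    statistic: str = "median",
) -> RSSProfiles:
    """Build the paired reference centroids from the two clinical extremes.

    ``expr`` should already be restricted to the filtered gene set.  For the
    grade axis the defaults are grade 1 vs grade 4; for stage, lowest vs
    highest observed; for size, bottom vs top quartile of tumor diameter.
    """
    if axis == "grade" and low_value is None and high_value is None:
        low_value, high_value = 1, 4
    low_ids, high_ids = _axis_extremes(clin, axis, low_value, high_value)
    low_ids = [s for s in low_ids if s in set(expr.sample_ids)]
    high_ids = [s for s in high_ids if s in set(expr.sample_ids)]
    if not low_ids or not high_ids:
        raise ClearScoreError(
            f"axis {axis!r}: empty extreme group (low={len(low_ids)}, high={len(high_ids)})"
        )
    return rss_from_members(expr, low_ids, high_ids, axis, statistic)


def rss_from_members(
    expr: ExpressionMatrix,
    low_ids: Sequence[str],
    high_ids: Sequence[str],
    axis: str,
    statistic: str = "median",
) -> RSSProfiles:
    """Centroids from explicit member lists (also used by the stability
    resampler, where members are bootstrap-drawn with replacement)."""
    if statistic not in ("median", "mean"):
        raise ClearScoreError(f"unknown centroid statistic {statistic!r}")
    agg = np.median if statistic == "median" else np.mean
    low_mat = expr.data[list(low_ids)].to_numpy()
    high_mat = expr.data[list(high_ids)].to_numpy()
    return RSSProfiles(
        gene_ids=tuple(expr.gene_ids),
        profile_low=agg(low_mat, axis=1),
        profile_high=agg(high_mat, axis=1),
        n_low=len(low_ids),
        n_high=len(high_ids),
        clinical_axis=axis,
    )


# ---------------------------------------------------------------------------
# scoring


def _row_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped 2-D arrays."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def _distances(
    s: np.ndarray, low: np.ndarray, high: np.ndarray, cfg: RunConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw distances (rows) of a sample to both centroids."""
    if cfg.correlation_method == "spearman":
        s = rankdata(s, axis=1)
        low = rankdata(low, axis=1)
        high = rankdata(high, axis=1)
    r1 = _row_pearson(s, low)
    r2 = _row_pearson(s, high)
    if cfg.distance_kind == "one_minus_corr":
        d1 = np.maximum(1.0 - r1, cfg.epsilon)
        d2 = np.maximum(1.0 - r2, cfg.epsilon)
    else:  # raw_corr: sign-preserving magnitude floor on the denominator
        d1 = r1
        d2 = np.where(np.abs(r2) < cfg.epsilon, np.copysign(cfg.epsilon, r2 + (r2 == 0)), r2)
    return d1, d2


def _sample_seed(base_seed: int, sample_id: str) -> int:
    # stable across platforms and cohort composition
    return (int(base_seed) + zlib.crc32(str(sample_id).encode("utf-8"))) % 2**32


def raw_score(
    sample_vector: np.ndarray,
    rss: RSSProfiles,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Bootstrap-averaged correlation-distance ratio for one sample.

    Draws ``cfg.n_boot`` gene subsets of size ``round(subset_fraction * N)``
    (without replacement within a draw), computes the distance to each
    centroid over every subset, and returns the mean of d_low / d_high.
    Draws yielding a non-finite correlation (constant subset) are redrawn;
    more than 50% redraws is a hard error.
    """
    s = np.asarray(sample_vector, dtype=float)
    n_genes = len(rss.gene_ids)
    if s.shape != (n_genes,):
        raise ClearScoreError("sample vector length does not match the reference gene set")
    k = int(round(cfg.subset_fraction * n_genes))
    if k < 3:
        raise ClearScoreError(
            f"gene subsets of size {k} are too small for correlation (need >= 3); "
            "increase subset_fraction or the gene set"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if k == n_genes:
        idx = np.tile(np.arange(n_genes), (cfg.n_boot, 1))
    else:
        # vectorized sampling without replacement within each draw
        keys = rng.random((cfg.n_boot, n_genes))
        idx = np.argsort(keys, axis=1)[:, :k]

    d1, d2 = _distances(s[idx], rss.profile_low[idx], rss.profile_high[idx], cfg)
    bad = ~(np.isfinite(d1) & np.isfinite(d2))
    redraws = 0
    max_redraws = max(1, cfg.n_boot // 2)
    while bad.any():
        n_bad = int(bad.sum())
        redraws += n_bad
        if redraws > max_redraws:
            raise ClearScoreError(
                f"more than 50% of bootstrap draws produced undefined correlations "
                f"({redraws} redraws); the expression data is too degenerate"
            )
        logger.debug("redrawing %d degenerate bootstrap subsets", n_bad)
        keys = rng.random((n_bad, n_genes))
        idx_bad = np.argsort(keys, axis=1)[:, :k]
        nd1, nd2 = _distances(
            s[idx_bad], rss.profile_low[idx_bad], rss.profile_high[idx_bad], cfg
        )
        d1[bad], d2[bad] = nd1, nd2
        bad = ~(np.isfinite(d1) & np.isfinite(d2))
    return float(np.mean(d1 / d2))


def scale_scores(raw_scores: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Affine map of cohort raw scores onto [1, 100] (min -> 1, max -> 100).

    Returns the scaled scores plus the fitted (min, max) bounds for later
    out-of-cohort projection.  A degenerate cohort (all raw scores equal)
    maps everything to the midpoint 50.5 with a prominent warning.
    """
    p = np.asarray(raw_scores, dtype=float)
    if p.size < 2:
        raise ClearScoreError("scaling needs at least 2 scores")
    lo, hi = float(p.min()), float(p.max())
    if hi == lo:
        logger.warning(
            "all raw scores identical (%.6g); scaled scores degenerate to %.1f",
            lo,
            DEGENERATE_SCALED,
        )
        return np.full(p.shape, DEGENERATE_SCALED), lo, hi
    return (p - lo) / (hi - lo) * 99.0 + 1.0, lo, hi


def score_cohort(
    expr: ExpressionMatrix,
    rss: RSSProfiles,
    cfg: RunConfig,
) -> ClearScoreResult:
    """Score every sample of a cohort and fit the [1,100] scaling on it.

    Each sample gets an independent RNG stream seeded from ``cfg.seed`` and a
    stable hash of its id, so scores do not depend on cohort order or
    composition.
    """
    if expr.n_samples < 2:
        raise ClearScoreError("cohort scoring needs at least 2 samples")
    sub = expr.subset_genes(rss.gene_ids)
    raw = np.empty(sub.n_samples)
    mat = sub.values
    for j, sid in enumerate(sub.sample_ids):
        rng = np.random.default_rng(_sample_seed(cfg.seed, sid))
        raw[j] = raw_score(mat[:, j], rss, cfg, rng=rng)
    scaled, lo, hi = scale_scores(raw)
    return ClearScoreResult(
        sample_ids=tuple(sub.sample_ids),
        raw_scores=raw,
        scaled_scores=scaled,
        scale_min=lo,
        scale_max=hi,
        params=cfg,
        rss=rss,
    )


def score_new_samples(expr: ExpressionMatrix, fitted: ClearScoreResult) -> pd.Series:
    """Project new samples onto a previously fitted score scale.

    Uses the stored reference centroids, config, and scaling bounds; scaled
    values are clamped to [1, 100] (clamped samples are logged).  Requires at
    least 50% overlap with the reference gene set; the centroids are
    restricted to the overlap.
    """
    rss, cfg = fitted.rss, fitted.params
    have = [g for g in rss.gene_ids if g in set(expr.gene_ids)]
    if len(have) < 0.5 * len(rss.gene_ids):
        raise ClearScoreError(
            f"only {len(have)}/{len(rss.gene_ids)} reference genes present (<50%)"
        )
    rss_use = rss.subset(have) if len(have) < len(rss.gene_ids) else rss
    sub = expr.subset_genes(have)
    span = fitted.scale_max - fitted.scale_min
    out = {}
    n_clamped = 0
    mat = sub.values
    for j, sid in enumerate(sub.sample_ids):
        rng = np.random.default_rng(_sample_seed(cfg.seed, sid))
        cs = raw_score(mat[:, j], rss_use, cfg, rng=rng)
        if span == 0:
            scaled = DEGENERATE_SCALED
        else:
            scaled = (cs - fitted.scale_min) / span * 99.0 + 1.0
        if scaled < 1.0 or scaled > 100.0:
            n_clamped += 1
            scaled = min(max(scaled, 1.0), 100.0)
        out[sid] = scaled
    if n_clamped:
        logger.warning("clamped %d/%d projected scores to [1, 100]", n_clamped, len(out))
    return pd.Series(out, name="clear_score")
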