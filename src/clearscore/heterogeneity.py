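"""Score stability under reference resampling and multi-region heterogeneity.

Stability: bootstrap the membership of the two extreme reference groups,
rebuild centroids, rescore the cohort, and summarize each sample's score
spread as a median absolute deviation (MAD).  Heterogeneity: compare score
dispersion among regions of one tumor against dispersion across all regions.

MAD here is the raw median absolute deviation (no 1.4826 consistency
factor); pass ``scale`` to change that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, pearsonr

from .iocore import ClearScoreError, ClinicalTable, ExpressionMatrix, RunConfig
from .scoring import _axis_extremes, raw_score, rss_from_members, score_cohort

logger = logging.getLogger("clearscore")

__all__ = ["StabilityResult", "HeterogeneityResult", "mad", "rss_stability",
           "multiregion_heterogeneity"]


def mad(x: np.ndarray, scale: float = 1.0) -> float:
    """Median absolute deviation about the median, times ``scale``."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) * scale)


@dataclass(frozen=True)
class StabilityResult:
    sample_ids: tuple[str, ...]
    per_sample_mad: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score_mad": self.per_sample_mad},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


@dataclass(frozen=True)
class HeterogeneityResult:
    per_tumor: pd.DataFrame  # index tumor_id; columns median_score, mad, n_regions
    pooled_mad: float
    mad_score_correlation: tuple[float, float]  # Pearson r, p
    inter_vs_intra_p: float


def rss_stability(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    axis: str = "grade",
    n_replicates: int = 500,
    cfg: RunConfig | None = None,
    low_value=None,
    high_value=None,
) -> StabilityResult:
    """Per-sample MAD of the score across bootstrap-resampled references.

    Each replicate draws both extreme groups' members with replacement
    (unique membership combinations enforced by rejection up to a retry
    cap), rebuilds the centroids, and rescores the cohort.  Replicate raw
    scores are put on the baseline cohort's [1,100] scale (frozen bounds, no
    clamping) before taking the MAD, so the result is in score units.
    """
    cfg = cfg or RunConfig()
    if axis == "grade" and low_value is None and high_value is None:
        low_value, high_value = 1, 4
    low_ids, high_ids = _axis_extremes(clin, axis, low_value, high_value)
    low_ids = [s for s in low_ids if s in set(expr.sample_ids)]
    high_ids = [s for s in high_ids if s in set(expr.sample_ids)]
    if not low_ids or not high_ids:
        raise ClearScoreError(f"axis {axis!r}: empty extreme group")
    if len(low_ids) < 2 and len(high_ids) < 2:
        logger.warning(
            "single-member extreme groups: resampling is degenerate, MADs will be 0"
        )

    baseline = score_cohort(
        expr,
        rss_from_members(expr, low_ids, high_ids, axis, cfg.centroid_statistic),
        cfg,
    )
    span = baseline.scale_max - baseline.scale_min

    rng = np.random.default_rng(cfg.seed)
    seen: set[tuple] = set()
    draws: list[tuple[list[str], list[str]]] = []
    attempts = 0
    cap = max(20 * n_replicates, 1000)
    while len(draws) < n_replicates:
        attempts += 1
        lo = tuple(sorted(rng.choice(low_ids, size=len(low_ids), replace=True)))
        hi = tuple(sorted(rng.choice(high_ids, size=len(high_ids), replace=True)))
        combo = (lo, hi)
        if combo in seen and attempts <= cap:
            continue
        if combo in seen:
            logger.warning(
                "could not find %d unique reference combinations; allowing repeats",
                n_replicates,
            )
        seen.add(combo)
        draws.append((list(lo), list(hi)))

    sub = expr.subset_genes(list(baseline.rss.gene_ids))
    mat = sub.values
    scores = np.empty((n_replicates, sub.n_samples))
    from .scoring import _sample_seed  # per-sample streams, as in score_cohort

    for r, (lo, hi) in enumerate(draws):
        try:
            rep_rss = rss_from_members(sub, lo, hi, axis, cfg.centroid_statistic)
        except ClearScoreError:
            # constant centroid from a pathological resample: reuse baseline
            rep_rss = baseline.rss
        # same gene-subset streams in every replicate: the MAD then isolates
        # variation caused by the resampled reference memberships alone
        for j, sid in enumerate(sub.sample_ids):
            srng = np.random.default_rng(_sample_seed(cfg.seed, sid))
            scores[r, j] = raw_score(mat[:, j], rep_rss, cfg, rng=srng)

    if span > 0:
        scores = (scores - baseline.scale_min) / span * 99.0 + 1.0
    mads = np.array([mad(scores[:, j]) for j in range(sub.n_samples)])
    return StabilityResult(
        sample_ids=tuple(sub.sample_ids),
        per_sample_mad=mads,
        n_replicates=n_replicates,
    )


def multiregion_heterogeneity(
    region_scores: pd.Series,
    region_to_tumor: pd.Series,
) -> HeterogeneityResult:
    """Intra- vs intertumoral dispersion of per-region scores.

    Per tumor: median score, MAD across its regions, region count.  Pooled
    MAD is taken over all regions.  The median-score/MAD Pearson correlation
    uses tumors with >= 2 regions.  The inter-vs-intra comparison is a
    one-way ANOVA of absolute deviations from tumor medians against absolute
    deviations from the pooled median.
    """
    common = [s for s in region_scores.index if s in set(region_to_tumor.index)]
    if not common:
        raise ClearScoreError("no regions shared between scores and tumor mapping")
    scores = region_scores.loc[common].astype(float)
    tumors = region_to_tumor.loc[common]
    if tumors.isna().any():
        raise ClearScoreError("tumor_id missing for some regions")
    if tumors.nunique() < 2:
        raise ClearScoreError("need at least 2 tumors")

    rows = []
    within_dev = []
    for tid, grp in scores.groupby(tumors):
        rows.append((tid, float(np.median(grp)), mad(grp.to_numpy()), len(grp)))
        if len(grp) >= 2:
            med = np.median(grp)
            within_dev.extend(np.abs(grp.to_numpy() - med))
    per_tumor = pd.DataFrame(
        rows, columns=["tumor_id", "median_score", "mad", "n_regions"]
    ).set_index("tumor_id")
    if (per_tumor["n_regions"] >= 2).sum() == 0:
        raise ClearScoreError("every tumor has a single region; heterogeneity undefined")

    pooled = mad(scores.to_numpy())
    pooled_dev = np.abs(scores.to_numpy() - np.median(scores.to_numpy()))

    multi = per_tumor[per_tumor["n_regions"] >= 2]
    if len(multi) >= 3 and multi["mad"].nunique() > 1:
        r, p = pearsonr(multi["median_score"], multi["mad"])
        corr = (float(r), float(p))
    else:
        corr = (float("nan"), float("nan"))
        logger.warning("too few multi-region tumors for a MAD-score correlation")

    anova = f_oneway(np.asarray(within_dev), pooled_dev)
    return HeterogeneityResult(
        per_tumor=per_tumor,
        pooled_mad=pooled,
        mad_score_correlation=corr,
        inter_vs_intra_p=float(anova.pvalue),
    )
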