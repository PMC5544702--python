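"""Compact signature derivation from score-based sample rankings.

Three sample ranking queues (one per clinical axis used to anchor the score)
are screened against every gene's expression with Spearman and Kendall rank
correlations; the most positively and negatively correlated genes per queue
are intersected across queues, and the final signature is picked from that
candidate pool by univariate survival sensitivity (proportional-hazards
score test, smallest p first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, kendalltau, rankdata

from .iocore import ClearScoreError, ClinicalTable, ExpressionMatrix, RunConfig
from .scoring import build_rss, score_cohort

logger = logging.getLogger("clearscore")

__all__ = [
    "RankQueue",
    "SignatureResult",
    "build_queues",
    "gene_queue_correlation",
    "candidate_genes",
    "select_signature",
    "derive_signature",
]

DEFAULT_TOP_K_EACH_TAIL = 100
DEFAULT_N_COMMON = 50
DEFAULT_N_SELECT = 18


@dataclass(frozen=True)
class RankQueue:
    """Cohort sample ids in ascending score order for one clinical axis."""

    sample_ids: tuple[str, ...]
    axis: str

    def positions(self) -> pd.Series:
        """1-based queue position per sample id."""
        return pd.Series(
            np.arange(1, len(self.sample_ids) + 1), index=list(self.sample_ids)
        )


@dataclass(frozen=True)
class SignatureResult:
    candidate_genes: tuple[str, ...]
    signature_genes: tuple[str, ...]
    per_gene_stats: pd.DataFrame


def build_queues(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    cfg: RunConfig,
    axes: tuple[str, ...] = ("grade", "stage", "size"),
) -> dict[str, RankQueue]:
    """One independently scored ranking queue per available clinical axis.

    Axes whose extreme groups cannot be formed are skipped with a warning;
    fewer than two usable queues is a hard error.  Ties in score are broken
    by sample id so queues are deterministic.
    """
    queues: dict[str, RankQueue] = {}
    for axis in axes:
        try:
            rss = build_rss(expr, clin, axis=axis, statistic=cfg.centroid_statistic)
            result = score_cohort(expr, rss, cfg)
        except ClearScoreError as exc:
            logger.warning("queue for axis %r omitted: %s", axis, exc)
            continue
        order = sorted(zip(result.scaled_scores, result.sample_ids))
        queues[axis] = RankQueue(sample_ids=tuple(sid for _, sid in order), axis=axis)
    if len(queues) < 2:
        raise ClearScoreError(
            f"only {len(queues)} ranking queue(s) could be built; need at least 2"
        )
    return queues


def gene_queue_correlation(
    expr: ExpressionMatrix,
    queue: RankQueue,
    method: str = "spearman",
) -> pd.Series:
    """Rank correlation of each gene's expression with the queue position.

    Constant genes get a correlation of 0 (flagged via log) rather than NaN.
    """
    if method not in ("spearman", "kendall"):
        raise ClearScoreError(f"unknown correlation method {method!r}")
    missing = [s for s in queue.sample_ids if s not in set(expr.sample_ids)]
    if missing:
        raise ClearScoreError(f"queue samples missing from expression: {missing[:5]}")
    sub = expr.subset_samples(list(queue.sample_ids))
    mat = sub.values  # genes x samples, columns already in queue order
    pos = np.arange(1, mat.shape[1] + 1, dtype=float)

    const = np.ptp(mat, axis=1) == 0
    if const.any():
        logger.warning(
            "%d constant gene(s) assigned correlation 0", int(const.sum())
        )
    if method == "spearman":
        ranks = rankdata(mat, axis=1)
        rc = ranks - ranks.mean(axis=1, keepdims=True)
        pc = pos - pos.mean()
        denom = np.sqrt((rc**2).sum(axis=1) * (pc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (rc @ pc) / denom
    else:
        vals = np.empty(mat.shape[0])
        for i in range(mat.shape[0]):
            vals[i] = kendalltau(mat[i], pos).statistic if not const[i] else np.nan
    vals = np.where(const, 0.0, vals)
    return pd.Series(vals, index=sub.gene_ids, name=f"{method}_{queue.axis}")


def candidate_genes(
    correlations: dict[tuple[str, str], pd.Series],
    top_k_each_tail: int = DEFAULT_TOP_K_EACH_TAIL,
    n_common: int = DEFAULT_N_COMMON,
) -> list[str]:
    """Intersect per-queue extreme-correlation gene sets into candidates.

    ``correlations`` maps (axis, method) -> per-gene correlation.  Per queue,
    Spearman and Kendall coefficients are averaged; the ``top_k_each_tail``
    most positive and most negative genes form that queue's set.  The sets
    are intersected across queues and the intersection ranked by mean
    absolute combined correlation; the first ``n_common`` are returned.  An
    empty intersection falls back to the ranked union, with a warning.
    """
    axes = sorted({axis for axis, _ in correlations})
    if len(axes) < 2:
        raise ClearScoreError("candidate screen needs correlations from >= 2 queues")
    combined: dict[str, pd.Series] = {}
    for axis in axes:
        methods = [m for a, m in correlations if a == axis]
        combined[axis] = sum(correlations[(axis, m)] for m in methods) / len(methods)

    per_queue_sets = []
    for axis in axes:
        c = combined[axis].sort_values(kind="mergesort")
        neg = set(c.index[:top_k_each_tail])
        pos = set(c.index[-top_k_each_tail:])
        per_queue_sets.append(pos | neg)

    common = set.intersection(*per_queue_sets)
    if not common:
        logger.warning("queue gene sets share no genes; falling back to their union")
        common = set.union(*per_queue_sets)

    strength = sum(combined[axis].abs() for axis in axes) / len(axes)
    ranked = sorted(common, key=lambda g: (-strength[g], g))
    return ranked[:n_common]


def _score_test_p(time: np.ndarray, event: np.ndarray, x: np.ndarray) -> float:
    """Univariate proportional-hazards score (log-rank) test p-value at beta=0."""
    from statsmodels.duration.hazard_regression import PHReg

    model = PHReg(time, x.reshape(-1, 1), status=event, ties="efron")
    beta0 = np.zeros(1)
    u = model.score(beta0)
    info = -model.hessian(beta0)
    if not np.isfinite(u).all() or not np.isfinite(info).all() or info[0, 0] <= 0:
        return 1.0
    stat = float(u[0] ** 2 / info[0, 0])
    return float(chi2.sf(stat, df=1))


def select_signature(
    expr: ExpressionMatrix,
    candidates: list[str],
    clin: ClinicalTable,
    n_select: int = DEFAULT_N_SELECT,
) -> SignatureResult:
    """Keep the ``n_select`` candidates with the smallest univariate
    survival p-values (score test of a single-gene proportional-hazards
    model); ties broken by gene id.  Genes whose test cannot be computed get
    p = 1 and a flag."""
    if not candidates:
        raise ClearScoreError("candidate gene list is empty")
    time, event, ids = clin.survival()
    sub = expr.subset_genes(candidates).subset_samples(
        [s for s in ids if s in set(expr.sample_ids)]
    )
    order = {s: i for i, s in enumerate(ids)}
    t = np.array([time[order[s]] for s in sub.sample_ids])
    e = np.array([event[order[s]] for s in sub.sample_ids])
    if sub.n_samples < 3 or int(e.sum()) == 0:
        raise ClearScoreError("not enough survival information to select a signature")

    rows = []
    for g in candidates:
        x = sub.data.loc[g].to_numpy()
        if np.ptp(x) == 0:
            rows.append((g, 1.0, True))
            continue
        try:
            p = _score_test_p(t, e, x)
            rows.append((g, p, False))
        except Exception as exc:  # non-convergence or numerical failure
            logger.warning("survival test failed for gene %s: %s", g, exc)
            rows.append((g, 1.0, True))
    stats = pd.DataFrame(rows, columns=["gene_id", "surv_p", "flagged"]).set_index("gene_id")
    ordered = stats.sort_values(["surv_p", "gene_id"], kind="mergesort").index
    selected = tuple(ordered[:n_select])
    return SignatureResult(
        candidate_genes=tuple(candidates),
        signature_genes=selected,
        per_gene_stats=stats,
    )


def derive_signature(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    cfg: RunConfig,
    top_k_each_tail: int = DEFAULT_TOP_K_EACH_TAIL,
    n_common: int = DEFAULT_N_COMMON,
    n_select: int = DEFAULT_N_SELECT,
) -> tuple[SignatureResult, pd.DataFrame]:
    """Full pipeline: queues -> correlations -> candidates -> selection.

    Returns the signature plus a per-gene table of mean Spearman/Kendall
    correlations, survival p, and selection status.
    """
    queues = build_queues(expr, clin, cfg)
    correlations = {
        (axis, method): gene_queue_correlation(expr, q, method)
        for axis, q in queues.items()
        for method in ("spearman", "kendall")
    }
    candidates = candidate_genes(correlations, top_k_each_tail, n_common)
    result = select_signature(expr, candidates, clin, n_select)

    axes = sorted(queues)
    table = pd.DataFrame(index=pd.Index(expr.gene_ids, name="gene_id"))
    table["mean_spearman"] = sum(correlations[(a, "spearman")] for a in axes) / len(axes)
    table["mean_kendall"] = sum(correlations[(a, "kendall")] for a in axes) / len(axes)
    table["surv_p"] = result.per_gene_stats["surv_p"].reindex(table.index)
    table["selected"] = table.index.isin(result.signature_genes).astype(int)
    return result, table
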