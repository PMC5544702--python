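"""Survival validation and model comparison.

Even subgrouping along the score scale, Kaplan-Meier / log-rank testing,
proportional-hazards fits (Efron ties), nested likelihood-ratio tests, the
adequacy index (fraction of the full model's likelihood-ratio chi-square
captured by a covariate subset), and two-group rank-sum comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2, mannwhitneyu
from statsmodels.duration.hazard_regression import PHReg

from .iocore import ClearScoreError, ClinicalTable

logger = logging.getLogger("clearscore")

__all__ = [
    "CoxFit",
    "ModelComparison",
    "even_groups",
    "km_logrank",
    "cox_fit",
    "compare_models",
    "group_compare",
]


@dataclass(frozen=True)
class CoxFit:
    """Result of a proportional-hazards fit."""

    coefficients: pd.Series
    std_errors: pd.Series
    loglik: float
    loglik_null: float
    wald_p: pd.Series
    score_p: float  # global score (log-rank) test of all covariates at 0
    pseudo_r2: float
    n: int
    n_events: int

    @property
    def lr_stat(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)


@dataclass(frozen=True)
class ModelComparison:
    """Nested comparison of two covariate blocks A and B."""

    loglik_null: float
    loglik_a: float
    loglik_b: float
    loglik_full: float
    lr_add_a_to_b: float
    df_a: int
    p_add_a_to_b: float
    lr_add_b_to_a: float
    df_b: int
    p_add_b_to_a: float
    adequacy_a: float
    adequacy_b: float
    pseudo_r2_a: float
    pseudo_r2_b: float
    pseudo_r2_full: float


def even_groups(scores: pd.Series, n_groups: int) -> pd.Series:
    """Split samples into score-ordered groups of near-equal size.

    Samples are sorted ascending by score (ties broken by sample id) and cut
    into ``n_groups`` whose sizes differ by at most 1; earlier (lower-score)
    groups take the extra members.  Labels are Q1..Qn ascending in score.
    """
    if n_groups < 2:
        raise ClearScoreError("need at least 2 groups")
    n = len(scores)
    if n < n_groups:
        raise ClearScoreError(f"cannot split {n} samples into {n_groups} groups")
    order = scores.reset_index()
    order.columns = ["sample_id", "score"]
    order = order.sort_values(["score", "sample_id"], kind="mergesort")
    base, extra = divmod(n, n_groups)
    labels = []
    for i in range(n_groups):
        size = base + (1 if i < extra else 0)
        labels.extend([f"Q{i + 1}"] * size)
    return pd.Series(labels, index=order["sample_id"].to_numpy(), name="group")


def km_logrank(
    groups: pd.Series, clin: ClinicalTable
) -> tuple[pd.DataFrame, float, float]:
    """Per-group product-limit survival curves and the k-group log-rank test.

    Returns (survival table with columns group/time/at_risk/survival,
    chi-square statistic with k-1 df, p-value).
    """
    time, event, ids = clin.survival()
    surv = pd.DataFrame({"time": time, "event": event}, index=ids)
    common = [s for s in groups.index if s in surv.index]
    if not common:
        raise ClearScoreError("no samples shared between groups and survival data")
    g = groups.loc[common]
    surv = surv.loc[common]
    counts = g.value_counts()
    if (counts == 0).any():
        raise ClearScoreError("a group has zero samples")

    tables = []
    for label in sorted(g.unique()):
        mask = (g == label).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(surv["time"][mask], surv["event"][mask], label=label)
        tab = kmf.event_table.reset_index()
        tab["survival"] = kmf.survival_function_.iloc[:, 0].to_numpy()
        tab["group"] = label
        tables.append(tab[["group", "event_at", "at_risk", "survival"]].rename(
            columns={"event_at": "time"}
        ))
    km = pd.concat(tables, ignore_index=True)

    res = multivariate_logrank_test(surv["time"], g, surv["event"])
    return km, float(res.test_statistic), float(res.p_value)


def _as_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encode categoricals (drop first level) into a numeric design."""
    design = pd.get_dummies(covariates, drop_first=True, dtype=float)
    return design.astype(float)


def _drop_aliased(design: pd.DataFrame, tol: float = 1e-10) -> pd.DataFrame:
    """Drop columns linearly dependent on earlier ones (centered), as coxph
    drops aliased terms; needed when the two compared blocks overlap."""
    x = design.to_numpy() - design.to_numpy().mean(axis=0)
    keep: list[int] = []
    for j in range(x.shape[1]):
        cols = keep + [j]
        if np.linalg.matrix_rank(x[:, cols], tol=tol * max(1.0, np.abs(x).max())) == len(cols):
            keep.append(j)
        else:
            logger.warning("dropping aliased covariate %r from the full model",
                           design.columns[j])
    return design.iloc[:, keep]


def _check_design(design: pd.DataFrame) -> None:
    const = [c for c in design.columns if design[c].nunique() <= 1]
    if const:
        raise ClearScoreError(f"constant covariate(s): {const}")


def _fit_ph(
    time: np.ndarray, event: np.ndarray, design: pd.DataFrame
) -> tuple[PHReg, np.ndarray]:
    model = PHReg(time, design.to_numpy(), status=event, ties="efron")
    with np.errstate(all="ignore"):
        res = model.fit(disp=False)
    params = np.asarray(res.params)
    if not np.isfinite(params).all():
        raise ClearScoreError("proportional-hazards fit did not converge")
    if np.abs(params * design.std().to_numpy()).max() > 50:
        raise ClearScoreError(
            "proportional-hazards fit suggests separation; consider penalization"
        )
    return model, params


def cox_fit(covariates: pd.DataFrame, clin: ClinicalTable) -> CoxFit:
    """Proportional-hazards fit of survival on the given covariates.

    Categorical columns are dummy-encoded.  Reports the partial
    log-likelihood, per-coefficient Wald p-values, the global score
    (log-rank) test, and pseudo-R2 = 1 - exp((2/n)(loglik_null - loglik)).
    """
    time, event, ids = clin.survival()
    common = [s for s in covariates.index if s in set(ids)]
    if not common:
        raise ClearScoreError("no samples shared between covariates and survival data")
    order = {s: i for i, s in enumerate(ids)}
    t = np.array([time[order[s]] for s in common])
    e = np.array([event[order[s]] for s in common])
    design = _as_design(covariates.loc[common])
    _check_design(design)
    if int(e.sum()) < design.shape[1]:
        raise ClearScoreError("fewer events than covariates; model unidentifiable")

    model, params = _fit_ph(t, e, design)
    k = design.shape[1]
    beta0 = np.zeros(k)
    ll_null = float(model.loglike(beta0))
    ll = float(model.loglike(params))

    cov = np.linalg.inv(-model.hessian(params))
    se = np.sqrt(np.diag(cov))
    wald = params / se
    wald_p = pd.Series(chi2.sf(wald**2, df=1), index=design.columns)

    u = model.score(beta0)
    info0 = -model.hessian(beta0)
    score_stat = float(u @ np.linalg.solve(info0, u))
    score_p = float(chi2.sf(score_stat, df=k))

    n = len(common)
    pseudo_r2 = 1.0 - float(np.exp((2.0 / n) * (ll_null - ll)))
    return CoxFit(
        coefficients=pd.Series(params, index=design.columns),
        std_errors=pd.Series(se, index=design.columns),
        loglik=ll,
        loglik_null=ll_null,
        wald_p=wald_p,
        score_p=score_p,
        pseudo_r2=pseudo_r2,
        n=n,
        n_events=int(e.sum()),
    )


def _loglik_of(time, event, design, start=None) -> tuple[float, np.ndarray]:
    model, params = _fit_ph(time, event, design)
    return float(model.loglike(params)), params


def compare_models(
    covariates_a: pd.DataFrame,
    covariates_b: pd.DataFrame,
    clin: ClinicalTable,
) -> ModelComparison:
    """Nested likelihood-ratio comparison of two covariate blocks.

    Fits the null, A-only, B-only and A+B models on the common samples; the
    LR statistic for adding A to B is 2(loglik_full - loglik_B) on
    params(A) degrees of freedom, and symmetrically for B.  The adequacy
    index of A is (loglik_A - loglik_null)/(loglik_full - loglik_null).
    """
    time, event, ids = clin.survival()
    common = [
        s for s in covariates_a.index if s in set(covariates_b.index) and s in set(ids)
    ]
    if len(common) < 3:
        raise ClearScoreError("too few common samples for model comparison")
    order = {s: i for i, s in enumerate(ids)}
    t = np.array([time[order[s]] for s in common])
    e = np.array([event[order[s]] for s in common])

    da = _as_design(covariates_a.loc[common]).add_prefix("a__")
    db = _as_design(covariates_b.loc[common]).add_prefix("b__")
    _check_design(da)
    _check_design(db)
    dfull = _drop_aliased(pd.concat([da, db], axis=1))

    ll_null = float(PHReg(t, da.to_numpy(), status=e, ties="efron").loglike(
        np.zeros(da.shape[1])
    ))
    ll_a, _ = _loglik_of(t, e, da)
    ll_b, _ = _loglik_of(t, e, db)
    ll_full, _ = _loglik_of(t, e, dfull)

    # MLE monotonicity can fail only numerically; nudge within tolerance
    tol = 1e-6
    best_sub = max(ll_a, ll_b)
    if ll_full < best_sub:
        if ll_full < best_sub - tol:
            raise ClearScoreError(
                f"full-model log-likelihood {ll_full:.6f} below nested "
                f"{best_sub:.6f}; numerical failure"
            )
        ll_full = best_sub
    if min(ll_a, ll_b) < ll_null:
        if min(ll_a, ll_b) < ll_null - tol:
            raise ClearScoreError("nested log-likelihood below null; numerical failure")
        ll_a, ll_b = max(ll_a, ll_null), max(ll_b, ll_null)

    df_a, df_b = da.shape[1], db.shape[1]
    lr_ab = 2.0 * (ll_full - ll_b)
    lr_ba = 2.0 * (ll_full - ll_a)
    denom = ll_full - ll_null
    if denom <= 0:
        adequacy_a = adequacy_b = 1.0
        logger.warning("full model adds no likelihood over null; adequacy set to 1")
    else:
        adequacy_a = min(max((ll_a - ll_null) / denom, 0.0), 1.0)
        adequacy_b = min(max((ll_b - ll_null) / denom, 0.0), 1.0)

    n = len(common)
    r2 = lambda ll: 1.0 - float(np.exp((2.0 / n) * (ll_null - ll)))
    return ModelComparison(
        loglik_null=ll_null,
        loglik_a=ll_a,
        loglik_b=ll_b,
        loglik_full=ll_full,
        lr_add_a_to_b=lr_ab,
        df_a=df_a,
        p_add_a_to_b=float(chi2.sf(lr_ab, df=df_a)),
        lr_add_b_to_a=lr_ba,
        df_b=df_b,
        p_add_b_to_a=float(chi2.sf(lr_ba, df=df_b)),
        adequacy_a=adequacy_a,
        adequacy_b=adequacy_b,
        pseudo_r2_a=r2(ll_a),
        pseudo_r2_b=r2(ll_b),
        pseudo_r2_full=r2(ll_full),
    )


def group_compare(
    scores: pd.Series, labels: pd.Series
) -> tuple[float, float, dict[str, float]]:
    """Two-sided Mann-Whitney U comparison of scores between two groups.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.  Returns (U for the first
    group by sorted label, p, per-group medians).
    """
    common = [s for s in scores.index if s in set(labels.index)]
    scores = scores.loc[common]
    labels = labels.loc[common]
    uniq = sorted(labels.dropna().unique())
    if len(uniq) != 2:
        raise ClearScoreError(f"need exactly 2 groups, got {uniq}")
    x = scores[labels == uniq[0]].to_numpy(dtype=float)
    y = scores[labels == uniq[1]].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ClearScoreError("a group has zero samples")
    method = "exact" if (len(x) + len(y)) <= 25 else "asymptotic"
    res = mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    medians = {str(uniq[0]): float(np.median(x)), str(uniq[1]): float(np.median(y))}
    return float(res.statistic), float(res.pvalue), medians
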