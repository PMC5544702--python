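"""Synthetic expression cohorts with known ground truth.

Samples sit on a latent aggressiveness axis u in [0, 1]; their expression is
a convex mixture of two archetype profiles that differ by 2 log-units on a
set of informative genes, plus Gaussian noise.  Grade, stage, and size are
monotone (noisy) transforms of u, and survival follows an exponential
hazard increasing in u.  Everything is reproducible bit-exactly from
(params, seed); the PRNG is numpy's PCG64 via ``default_rng``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iocore import ClearScoreError, ClinicalTable, ExpressionMatrix

logger = logging.getLogger("clearscore")

__all__ = ["SyntheticCohort", "generate_cohort", "generate_multiregion"]

_MAX_RETRIES = 20


@dataclass(frozen=True)
class SyntheticCohort:
    expr: ExpressionMatrix
    clin: ClinicalTable
    latent: pd.Series  # aggressiveness in [0, 1] per sample
    informative_genes: tuple[str, ...]
    generator_params: dict


def _make_expression(
    rng: np.random.Generator,
    u: np.ndarray,
    sample_ids: list[str],
    n_genes: int,
    n_informative: int,
    noise_sd: float,
    effect_size: float = 2.0,
) -> tuple[ExpressionMatrix, tuple[str, ...]]:
    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    base = rng.normal(9.0, 1.0, size=n_genes)  # background so the default filter bites
    a_low = base.copy()
    a_high = base.copy()
    info_idx = np.arange(n_informative)
    # half the informative genes go up with aggressiveness, half down
    signs = np.where(info_idx % 2 == 0, 1.0, -1.0)
    a_high[info_idx] = a_low[info_idx] + effect_size * signs
    mix = np.outer(a_low, 1.0 - u) + np.outer(a_high, u)
    noise = rng.normal(0.0, noise_sd, size=mix.shape) if noise_sd > 0 else 0.0
    values = mix + noise
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    return expr, tuple(gene_ids[i] for i in info_idx)


def _clinical_from_latent(
    rng: np.random.Generator,
    u: np.ndarray,
    sample_ids: list[str],
    hazard_coef: float,
    censor_rate: float,
) -> ClinicalTable:
    grade = np.minimum(1 + np.floor(4 * u), 4).astype(int)
    stage_u = np.clip(u + rng.normal(0, 0.1, size=u.shape), 0, 1)
    stage = np.minimum(1 + np.floor(4 * stage_u), 4).astype(int)
    size = np.clip(2.0 + 10.0 * u + rng.normal(0, 1.0, size=u.shape), 0.5, None)

    # exponential survival; log-hazard increases linearly in 100*u
    base_rate = 0.01
    rate = base_rate * np.exp(hazard_coef * 100.0 * u)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=u.shape)
    else:
        t_cens = np.full(u.shape, np.inf)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)

    return ClinicalTable(
        pd.DataFrame(
            {
                "grade": grade,
                "stage": stage,
                "size": size,
                "time": time,
                "event": event,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )


def generate_cohort(
    n_samples: int = 200,
    n_genes: int = 1000,
    n_informative: int = 30,
    noise_sd: float = 1.0,
    hazard_coef: float = 0.03,
    censor_rate: float = 0.01,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a single-region cohort with latent-driven clinical outcomes.

    Retries the latent draw (up to a cap, with a warning) if either clinical
    extreme (u < 0.25 or u > 0.75) would be empty, which only happens at
    tiny n.
    """
    if n_informative > n_genes:
        raise ClearScoreError("n_informative cannot exceed n_genes")
    if min(n_samples, n_genes, n_informative) < 1:
        raise ClearScoreError("all counts must be positive")
    rng = np.random.default_rng(seed)
    for attempt in range(_MAX_RETRIES):
        u = rng.uniform(0, 1, size=n_samples)
        if (u < 0.25).any() and (u > 0.75).any():
            break
        logger.warning("latent draw left an extreme group empty; redrawing")
    else:
        raise ClearScoreError("could not draw a latent axis spanning both extremes")

    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    expr, informative = _make_expression(
        rng, u, sample_ids, n_genes, n_informative, noise_sd
    )
    clin = _clinical_from_latent(rng, u, sample_ids, hazard_coef, censor_rate)
    params = dict(
        n_samples=n_samples,
        n_genes=n_genes,
        n_informative=n_informative,
        noise_sd=noise_sd,
        hazard_coef=hazard_coef,
        censor_rate=censor_rate,
        seed=seed,
    )
    return SyntheticCohort(
        expr=expr,
        clin=clin,
        latent=pd.Series(u, index=sample_ids, name="latent"),
        informative_genes=informative,
        generator_params=params,
    )


def generate_multiregion(
    n_tumors: int = 10,
    regions_per_tumor: int | list[int] = 6,
    inter_sd: float = 0.2,
    intra_sd: float = 0.05,
    n_genes: int = 1000,
    n_informative: int = 30,
    noise_sd: float = 1.0,
    hazard_coef: float = 0.03,
    censor_rate: float = 0.01,
    seed: int = 0,
) -> SyntheticCohort:
    """Multi-region tumors: tumor-level latent centers plus region jitter.

    Centers are Normal(0.5, inter_sd) and region latents center +
    Normal(0, intra_sd), both clipped to [0, 1].  ``regions_per_tumor`` may
    be a single count or one count per tumor.  The clinical table carries a
    ``tumor_id`` column; sample ids are ``T<t>_R<r>``.
    """
    if inter_sd < 0 or intra_sd < 0:
        raise ClearScoreError("inter_sd and intra_sd must be non-negative")
    if isinstance(regions_per_tumor, int):
        counts = [regions_per_tumor] * n_tumors
    else:
        counts = list(regions_per_tumor)
        if len(counts) != n_tumors:
            raise ClearScoreError("regions_per_tumor list must have one entry per tumor")
    if min(counts) < 1:
        raise ClearScoreError("every tumor needs at least one region")

    rng = np.random.default_rng(seed)
    centers = np.clip(rng.normal(0.5, inter_sd, size=n_tumors), 0, 1)
    u_parts, ids, tumor_ids = [], [], []
    for t, (center, k) in enumerate(zip(centers, counts), start=1):
        jitter = rng.normal(0, intra_sd, size=k) if intra_sd > 0 else np.zeros(k)
        u_parts.append(np.clip(center + jitter, 0, 1))
        ids.extend(f"T{t:02d}_R{r}" for r in range(1, k + 1))
        tumor_ids.extend([f"T{t:02d}"] * k)
    u = np.concatenate(u_parts)

    expr, informative = _make_expression(rng, u, ids, n_genes, n_informative, noise_sd)
    clin = _clinical_from_latent(rng, u, ids, hazard_coef, censor_rate)
    clin_df = clin.data.copy()
    clin_df["tumor_id"] = tumor_ids
    params = dict(
        n_tumors=n_tumors,
        regions_per_tumor=counts,
        inter_sd=inter_sd,
        intra_sd=intra_sd,
        n_genes=n_genes,
        n_informative=n_informative,
        noise_sd=noise_sd,
        hazard_coef=hazard_coef,
        censor_rate=censor_rate,
        seed=seed,
    )
    return SyntheticCohort(
        expr=expr,
        clin=ClinicalTable(clin_df),
        latent=pd.Series(u, index=ids, name="latent"),
        informative_genes=informative,
        generator_params=params,
    )
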