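import numpy as np
import pandas as pd
import pytest

from clearscore import (
    ClinicalTable,
    ExpressionMatrix,
    RunConfig,
    build_rss,
    filter_genes,
    generate_cohort,
    score_cohort,
)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, handwritten values."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[9.0, 10.0, 11.0, 12.0],
             [8.5, 9.5, 10.5, 11.5],
             [12.0, 11.0, 10.0, 9.0]],
            index=["gA", "gB", "gC"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def tiny_clin() -> ClinicalTable:
    return ClinicalTable(
        pd.DataFrame(
            {
                "grade": [1, 2, 3, 4],
                "stage": [1, 1, 2, 2],
                "size": [2.0, 4.0, 6.0, 8.0],
                "time": [60.0, 48.0, 24.0, 12.0],
                "event": [0, 0, 1, 1],
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )


@pytest.fixture
def oracle_cfg() -> RunConfig:
    """Configuration under which the score reduces to a one-line formula."""
    return RunConfig(n_boot=1, subset_fraction=1.0, seed=0)


@pytest.fixture
def fast_cfg() -> RunConfig:
    return RunConfig(n_boot=10, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 60-sample cohort with 150 genes, 15 informative."""
    return generate_cohort(
        n_samples=60, n_genes=150, n_informative=15, noise_sd=0.8, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort_scored(small_cohort):
    c = small_cohort
    kept = filter_genes(c.expr)
    sub = c.expr.subset_genes(kept)
    cfg = RunConfig(n_boot=20, seed=7)
    rss = build_rss(sub, c.clin)
    return sub, cfg, score_cohort(sub, rss, cfg)


def brute_force_score(sample, low, high, epsilon=1e-8):
    """Independent oracle: (1 - r(sample, low)) / (1 - r(sample, high))."""
    r1 = np.corrcoef(sample, low)[0, 1]
    r2 = np.corrcoef(sample, high)[0, 1]
    return max(1 - r1, epsilon) / max(1 - r2, epsilon)
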