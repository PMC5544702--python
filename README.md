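# clearscore

Continuous, reference-anchored scoring of tumor aggressiveness from log-scale
gene expression. A cohort's samples are placed on a [1, 100] scale by the
ratio of their correlation distance to two reference centroids — the per-gene
median profiles of the samples at the two clinical extremes (e.g. grade 1 vs
grade 4) — averaged over bootstrapped gene subsets. The package also derives
a compact transcript signature driving the score, validates it against
survival, compares the continuous model with discrete subtype models, and
quantifies score stability and intra- vs intertumoral heterogeneity. A
synthetic-cohort generator with known ground truth makes every stage testable
offline.

## Library layout

| module                     | contents                                                               |
| -------------------------- | ---------------------------------------------------------------------- |
| `clearscore.iocore`        | `ExpressionMatrix`, `ClinicalTable`, `RunConfig`, TSV readers/writers, `align` |
| `clearscore.scoring`       | `filter_genes`, `build_rss`, `raw_score`, `score_cohort`, `scale_scores`, `score_new_samples` |
| `clearscore.signature`     | rank queues, Spearman/Kendall gene screens, `candidate_genes`, `select_signature`, `derive_signature` |
| `clearscore.survstats`     | `even_groups`, `km_logrank`, `cox_fit`, `compare_models` (adequacy index), `group_compare` |
| `clearscore.heterogeneity` | `rss_stability` (bootstrap-resampled references), `multiregion_heterogeneity`, `mad` |
| `clearscore.synthetic`     | `generate_cohort`, `generate_multiregion` with latent ground truth     |
| `clearscore.cli`           | the `clear` command                                                    |

## CLI

```sh
clear simulate cohort --out-dir sim --seed 1
clear score --expr sim/expression.tsv --clin sim/clinical.tsv \
    --axis grade --seed 1 --out scores.tsv
clear derive-signature --expr sim/expression.tsv --clin sim/clinical.tsv \
    --n-common 50 --n-select 18 --seed 1 --out signature.tsv
clear survival --scores scores.tsv --clin sim/clinical.tsv \
    --groups 2,4,6,8 --out km.tsv
clear compare --scores scores.tsv --labels subtypes.tsv \
    --clin sim/clinical.tsv --out comparison.tsv
clear stability --expr sim/expression.tsv --clin sim/clinical.tsv \
    --replicates 500 --seed 1 --out stab.tsv
clear heterogeneity --scores region_scores.tsv --clin clinical.tsv --out het.tsv
```

Every successful run writes `<out>.manifest.json` with the resolved config,
input digests, seed, and version. Algorithm knobs (bootstrap draws, subset
fraction, correlation flavor, distance kind, centroid statistic) live in a
TOML config passed via `--config`; CLI flags override it.

Expression input is tab- or comma-delimited, genes in rows, first column the
gene id. Clinical input needs a `sample_id` column; recognized columns are
`grade` (1–4), `stage`, `size` (cm), `time` (months), `event` (0/1),
`tumor_id`, `group_label`; extra columns pass through.

### Notes on defaults

- Genes are filtered to those with log expression > 8 in at least 10% of
  samples before anything else.
- Distance defaults to `1 - Pearson r`, so high scores mean proximity to the
  aggressive (high-grade) centroid; `raw_corr` is available as a config
  option.
- Bootstrap defaults: 100 draws of half the filtered genes each; both knobs
  are unanchored conventions and fully configurable.
- Scaling is min-max onto [1, 100], fitted per cohort; projection of new
  samples reuses frozen bounds and clamps.

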