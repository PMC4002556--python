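# ordagree

Agreement and disagreement analysis for **paired ordinal rating-scale
data** — e.g. the same subjects rated on a five-point problem scale by two
questionnaires, or by a patient and a professional observer.

The suite separates the two sources of observed disagreement:

| measure | what it captures | range |
|---|---|---|
| `PA`  | percentage agreement: share of pairs on the agreement diagonal | [0, 1] |
| `RP`  | relative position: systematic marginal shift, `P(A<B) − P(B<A)`; positive ⇒ the second source uses higher categories | [−1, 1] |
| `RV`  | relative rank variance: subject-level variability from augmented mean ranks, `(6/n³) Σ n_ij (Rx_ij − Ry_ij)²` | ≥ 0 (≈[0, 1]; the 5-category uniform-table maximum is 0.61) |
| `D`   | disorder: proportion of discordantly ordered subject pairs out of C(n, 2) | [0, 1] |
| `r_s` | Spearman rank correlation (mid-ranks for ties) | [−1, 1] |

Confidence intervals come from a subject-level percentile bootstrap
(default B = 2000, explicit seed) or a leave-one-out jackknife. A
latent-trait threshold generator produces synthetic multi-item studies
(source bias → RP, source noise → RV/D, observer heterogeneity,
item-wise missingness) so the whole pipeline is testable without any
external data.

## Library use

```python
import ordagree as og

pairs = og.PairedAssessments.from_tuples([(1, 3), (2, 2), (3, 4), (2, 3)])
table = og.contingency_from_pairs(pairs)

og.percentage_agreement(table)      # PA
og.relative_position(table)         # RP (positive = second source higher)
og.relative_rank_variance(table)    # RV via augmented mean ranks
og.disorder_measure(pairs)          # D
og.spearman_rho(pairs)              # r_s

plan = og.ResamplingPlan("bootstrap", replicates=2000, seed=42)
rp = og.resample_ci(pairs, "RP", plan)      # percentile 95% CI
og.significant_shift(rp)                    # interval excludes 0?
```

Ordinal conventions are documented choices: the median/quartile category is
the smallest category whose cumulative proportion reaches the target
(`ordinal_summary`); RP uses all n² marginal cross-pairings; D's
denominator counts all C(n, 2) subject pairs with ties never disordered;
RV is reported unclipped (tiny-n reversal tables can exceed 1).

## CLI

```sh
# 1. simulate a study from a key-value scenario file
ordagree simulate --config scenario.yaml --out study.csv --seed 5

# 2. analyze: per-item measure bundles + CIs + summary + contingency grids
ordagree analyze --in study.csv --out report/ --mode inter-scale \
    --bootstrap 2000 --seed 9 [--scale no,slight,moderate,major,total] \
    [--spearman/--no-spearman]

# 3. print the formatted report
ordagree report --in report/
```

Input CSV: header `subject_id,item_id,response_a,response_b`; responses as
integer codes `1..m` or exact scale labels; blank/NA = missing. A record
missing either response is excluded from that item only (pairwise-complete
deletion), so n varies by item. Every report states the RP sign convention
in its header and logs skipped items and the seed in its footer.

Example `scenario.yaml`:

```yaml
n_subjects: 89
items: [walking, housework, sleep]
completion_prob: 0.95
n_observers: 11          # patient–observer mode; 0 = inter-scale
observer_bias_sd: 0.3
rater_a: {bias: 0.0, noise: 0.4}
rater_b: {bias: 0.3, noise: 0.4}
```

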