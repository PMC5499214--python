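# enhancerenrich

Test whether genome-wide-significant GWAS variants are enriched in sets of
genomic intervals (e.g. enhancer annotations), starting from two-cohort
summary statistics.

The package provides, as composable library modules and as a CLI:

- **Meta-analysis** (`enhancerenrich.meta`) — inverse-variance combination
  of per-cohort (β, P) summary statistics. For each cohort the standard
  error is reconstructed from the printed effect and P value,
  `se = |β / Φ⁻¹(1 − p/2)|`, each cohort gets weight `w = 1/se`
  (configurable to the conventional `1/se²`, see below), and the combined
  effect, dispersion and two-sided P are
  `β̃ = Σᵢ βᵢwᵢ / Σᵢ wᵢ`, `ṽ = √(n / Σᵢ wᵢ)`, `p̃ = 2(1 − Φ(|β̃/ṽ|))`.
  Variants with β = 0 or P = 1 in any cohort carry no information under
  this parameterisation and are filtered with full bookkeeping. Variants
  with `p̃ ≤ 10⁻⁸` are flagged significant.
- **Permutation enrichment test** (`enhancerenrich.permutation`) — observed
  count `n_s` of significant SNPs among the `N_E` SNPs inside a set,
  compared with counts `m_s` from 10,000 size-matched draws from the SNPs
  outside the set; reports the fold change `n_s / mean(m_s)` and the rank
  P value `#{m_s ≥ n_s} / (n_perm + 1)`, printed `<0.0001` when no draw
  reaches the observed count.
- **Running-sum (GSEA-style) test** (`enhancerenrich.gsea`) — SNPs ranked
  by `−log₁₀ p̃`; a weighted running sum increments by `score/N_R` at
  member SNPs and decrements by `1/(N − N_E)` otherwise; the maximal
  positive excursion `ES_max` is compared against 10,000 random
  reassignments of set membership, and the leading-edge ("core") SNPs up
  to the peak are reported for significant sets.
- **Interval algebra** (`enhancerenrich.intervals`) — merge, gap-based
  cluster-merge, intersection, subtraction, pairwise overlap-percentage
  matrices and SNP membership over BED-style half-open intervals.
- **Functional annotation** (`enhancerenrich.annotation`) — a simplified
  classifier assigning each variant one of ten functional classes
  (splicing, stop, UTRs, exonic, intronic, flanks, intergenic) from a
  minimal GFF3 gene model.
- **Synthetic data** (`enhancerenrich.simulate`) — a generator producing
  SNP maps, enhancer sets with planted enrichment, gene models and
  two-cohort summary statistics with known ground truth, so the whole
  analysis is testable end to end without external data.
- **Pipeline + CLI** (`enhancerenrich.pipeline`, `enhancerenrich.cli`) —
  orchestration over traits × sets with deterministic per-analysis seeds,
  derived set rows (A-specific, B-specific, A∩B), TSV/JSON reports and a
  run manifest.

## Worked example

Two cohorts measured the same variant: bulls β = 0.4, P = 0.04550026
(z = 2) and cows β = 0.2, P = 0.317311 (z = 1). Both cohorts reconstruct
se = 0.2, so w = (5, 5), β̃ = 0.3, ṽ = √(2/10) = 0.4472136 and
p̃ ≈ 0.5023:

```python
from enhancerenrich.meta import CohortSnpStat, combine_cohorts, meta_p_value

res = combine_cohorts([
    CohortSnpStat("rs1", "1", 100, "bulls", 0.4, 0.04550026),
    CohortSnpStat("rs1", "1", 100, "cows", 0.2, 0.317311),
])
print(res.tilde_beta, res.tilde_v)          # 0.3  0.4472137
print(meta_p_value(res.tilde_beta, res.tilde_v))  # 0.50233...
```

End-to-end on synthetic data:

```sh
enhancerenrich simulate --seed 0 --out-dir study/
enhancerenrich run-all \
    --trait FY:bulls=study/cohort_bulls.tsv --trait FY:cows=study/cohort_cows.tsv \
    --set enriched=study/enriched.bed --set decoy=study/decoy.bed \
    --derive-pair enriched,decoy --n-perm 10000 --seed 0 --out-dir results/
```

`run-all` also accepts a TOML config (`--config run.toml`) mirroring every
flag; explicit flags override the config.

## On the weighting convention

The estimator is implemented with weights `w = 1/se` by default and a
`weight_exponent` option selecting the conventional inverse-variance
`w = 1/se²`. The two conventions are genuinely different: the worked
example above (w = 5, ṽ = 0.4472136) holds only under `1/se`, while the
exact identities "meta-analysing a single cohort returns its P value" and
"rescaling all effect sizes leaves p̃ unchanged" hold only under `1/se²`.
Both behaviours are tested under the exponent where each holds; see
`docs/methods.md` for the full discussion.

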