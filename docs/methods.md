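# Methods

## Problem and scope

Relative quantification by qRT-PCR divides a target gene's signal by that of
a reference (housekeeping) gene assumed stable across samples. When no
validated reference exists for a sample type — fecal/intestinal miRNA being a
prominent case — candidates must be screened empirically. `refstab`
implements the de-facto standard screen: three independent stability
statistics (geNorm, NormFinder, BestKeeper) computed from a candidate Ct
panel, aggregated into a consensus ranking, followed by `2^-dCt` relative
quantification of targets against the selected normalizer with a two-group
Student's t-test.

## Preprocessing

Raw input is a wide Ct table (genes x samples, cycles). Non-detects
(`""`, `NA`, `Undetermined`) become missing cells; any non-missing Ct must
lie strictly inside (0, 45) cycles. geNorm and NormFinder require complete
per-gene vectors, so genes with any missing cell are excluded from those two
methods (logged); BestKeeper keeps each gene's non-missing samples.

Relative quantities are `Q(g,s) = 2^-(Ct(g,s) - min_s Ct(g,.))`, with the
per-gene minimum taken within the analysed matrix. Each gene's most abundant
sample maps to Q = 1; `log2 Q = -(Ct - Ct_min)`, so log-scale noise equals
Ct-scale noise in cycles. No amplification-efficiency correction is applied
(the screen this emulates reported efficiencies of 93–116% and applied none).
Ct distribution summaries use linear interpolation between order statistics
for quartiles so box-summary output is bit-reproducible.

## geNorm

Pairwise variation `V_jk` is the sample standard deviation (n−1 denominator)
of `log2(q_j/q_k)`; `M_j` is the mean of `V_jk` over the other active genes.
Per-sample loading effects cancel in the within-sample ratios, and scaling
any gene's quantity vector changes nothing. The gene with the highest M is
excluded and M recomputed until two genes remain; being defined only through
their mutual ratio, the final two are indistinguishable and share rank 1,
with remaining ranks 3, 4, … in reverse exclusion order (the competition-rank
convention visible in published screens). Ties in "highest M" break by input
order (logged). First-pass M values above the conventional threshold of 1.5
flag a candidate as unstable; both first-pass and at-exclusion M values are
reported, since published bar charts do not state which is shown. The
V(n/n+1) normalization-factor analysis is available as a diagnostic but does
not enter the consensus.

Known pull: adding a co-regulated (proportional) partner lowers a gene's M —
inherent to the pairwise definition, and covered by a test.

## NormFinder (single group)

Model: `y_ij = log2 Q_ij = alpha_i + beta_j + eps_ij`, `eps_ij ~ (0, sigma_i^2)`.
Sample-centering `d_ij = y_ij − mean_i y_ij` removes `beta_j` but leaks a
share of every gene's noise into each `u_i = var_j(d_ij)`; the unbiased
reconstruction with k genes is

```
sigma2_i = max(0, (k/(k-2)) * (u_i - mean(u)/(k-1)));   rho_i = sqrt(sigma2_i)
```

(`E[sigma2_i] = sigma_i^2` under the model). The max(0, ·) floor handles
small-n sampling pushing the corrected estimate negative. Requires k ≥ 3
(the correction is undefined at k = 2) and n ≥ 3. Only the ungrouped form is
implemented: a reference screen run on a single condition has no
between-group component. Log base 2 throughout, matching the Q transform.

## BestKeeper

Descriptive dispersion of raw Ct per gene: n, geometric and arithmetic mean,
min, max, SD and CV = 100·SD/mean. SD defaults to the mean absolute
deviation from the arithmetic mean — the original applet's convention —
with `sd="classic"` switching to the n−1 sample SD (published reports often
say only "standard deviation"; both are exposed). SD > 1 cycle flags
instability. Ranking is by ascending CV with SD as tie-breaker, since CV is
what the method's published charts plot. The BestKeeper index (per-sample
geometric mean) and gene-vs-index Pearson correlations are optional
diagnostics, excluded from ranking.

Because BestKeeper works on raw Ct, a shared per-sample loading effect of SD
τ contributes to every gene's dispersion (≈ √(τ²+σ²) for gene noise σ): the
method cannot resolve noise differences well below τ. This is a property of
the statistic, not of this implementation, and shapes the recovery
experiments below.

## Consensus

Each method's per-gene rank is averaged arithmetically and genes are ordered
by ascending average. The arithmetic mean matches the published worked
example this package reproduces (1,1,6 → 2.667; a geometric mean would give
1.817); `mean="geometric"` exists for completeness. Ties in the average
break by the smallest single-method rank, then input order — this rule
reproduces the published order of the one tied pair (averages of 15 with
best single ranks 12 vs 13) but is a convention, not a published rule.

## Differential expression

`rel(g,s) = 2^-(Ct_g,s - Ct_ref,s)`; the per-sample subtraction cancels any
global loading shift exactly. Two-sided unpaired Student's t-test (equal
variances; Welch by flag) on the linear-scale levels, matching the
mean ± SEM bar convention; `on_dct=True` tests the log scale instead. Group
means/SEMs are rescaled so the control mean is exactly 1. If both groups
have zero variance and equal means, p = 1 is reported. Significance is
flagged on raw p < α (default 0.05) to mirror common qPCR practice;
Benjamini–Hochberg q-values are emitted as an extra column.

## Synthetic data generator

`Ct(g,s) = mu_g + b_s + delta_g·[s in case] + e_gs`, with loading
`b_s ~ N(0, tau²)`, gene noise `e_gs ~ N(0, sigma_g²)` — Gaussian on the Ct
(log2) scale, the standard qPCR error model — clipped (not rejected, to
preserve seed-for-seed reproducibility; clips logged) to a (0.5, 40) cycle
window. The default panel emulates the screen's design: 22 candidates (4
housekeeping genes + 18 miRNAs), baselines spanning 11–37 cycles with the
5S-like gene most abundant (~12.5) and the mir-15a-like gene least (~35),
5 control + 5 case samples, τ = 0.5 cycles, gene noise from 0.08 (the
planted stable trio mir-23a/GAPDH/let-7i) to 1.2 cycles, and a +2-cycle
(4-fold decrease) case shift planted in the 11 miRNAs the emulated screen
found down-regulated. The generator does not model amplification-efficiency
differences, PCR inhibitors, or non-detect dropout — passing recovery tests
therefore show correct inference under an additive Gaussian Ct model, not
robustness to those real-data features.

## Recovery experiments (test suite / acceptance script)

Problem sizes were chosen to keep the full suite fast while leaving the
statistics well-resolved: 22 genes × 10 samples per replicate, 50 seeds for
rank-correlation medians, 200 replicates for top-3 recovery, 1000/100
replicates for t-test type-I error and power.

- Spearman recovery uses a linear σ grid 0.05–1.5 cycles, τ = 0.5, and a
  constant baseline (Ct 20): with baselines spread over 11–37 the BestKeeper
  CV denominator would confound the planted noise order with abundance,
  which is not the property under test. Median Spearman vs the planted order
  is ≈ 0.92/0.92/0.86 (geNorm/NormFinder/BestKeeper).
- Top-3 consensus recovery plants a stable trio at σ = 0.05 against
  competitors spanning 0.5–1.5 (a 10× separation, the same used in the
  4-gene worked example); the trio takes the top-3 comprehensive ranks in
  ≈ 96–97% of 200 replicates. At the minimal 4× separation (competitors
  from 0.2) the rate drops to ≈ 0.80–0.87: under τ = 0.5 the BestKeeper
  dispersion floor makes σ = 0.05 and σ = 0.2 nearly indistinguishable at
  n = 10, and its rank noise drags the consensus average. Both rates are
  reported by `scripts/acceptance.py`.

## Numerical conventions

- All SDs use the n−1 denominator unless stated (BestKeeper MAD default).
- Competition ranking throughout: ties share the smaller rank, next skips.
- Deterministic tie-breaks (input order) wherever a total order is needed;
  all are logged at INFO level.
- Oracle-equivalence tolerances are 1e-12 absolute; invariances that are
  exact in real arithmetic are asserted at 1e-9–1e-12 to absorb float
  rounding.
- Seeding: `numpy.random.default_rng`; identical config + seed gives
  byte-identical CSV output.

## Known limitations

- Single-condition NormFinder only; no grouped intra/inter-group variant.
- BestKeeper cannot resolve gene noise below the shared loading SD (above).
- No technical-replicate collapsing: one Ct per gene-sample cell is assumed.
- No instrument-native input formats (no .eds / RDML).
- The consensus tie rule beyond the average is a convention chosen to match
  one published tied pair; other software may order ties differently.
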