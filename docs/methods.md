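# Methods

This note records the statistical models implemented in `refstab`, the
estimator and tie-break conventions they use, what the synthetic-data
generator does and does not emulate, and the design choices made where
the underlying methods are commonly described only informally.

## Data model and preprocessing

The universal input is a tidy table of quantification-cycle (Cq)
measurements keyed by (sample, gene, technical replicate), with a sample
annotation carrying treatment group, timepoint and biological replicate.
Technical replicates are collapsed by the **arithmetic mean of Cq**
before any stability analysis; since Cq is a log-scale measurement,
this equals the geometric mean of the underlying template quantities. No
outlier rejection is applied. The collapsing convention is a package
decision: the combination rule is rarely stated explicitly in
applications, and the arithmetic mean is the least surprising choice.

geNorm and NormFinder assume a complete genes × samples matrix. Missing
cells are a **hard error** (`IncompleteMatrixError`), never imputed:
silent imputation would change the statistics irreproducibly.
`validate_complete_matrix` reports the exact missing cells.

No-template-control wells are flagged as potential contamination only
when their Cq is fewer than `margin` cycles above the earliest template
Cq. The default margin is 9.4 cycles, so a signal ~9.5 cycles late is
treated as background, matching the common practice of ignoring NTC
amplification roughly ten cycles beyond template; the margin is
configurable.

Delimited text uses a comma by default; tab and semicolon are accepted.
Decimal separator is always `.`.

## Screening

CV is computed per gene over **all replicate values of all treatments**
as 100·s/x̄ with the sample (n−1) standard deviation. The low-expression
filter keeps a gene iff its **mean** RPKM across samples is ≥ 3
(boundary inclusive); the aggregation rule (mean vs minimum vs
any-sample) is underdetermined in common usage, so the least surprising
aggregate was chosen and is documented here. CV ties break by
lexicographic gene id for determinism. The Cq admissibility rule keeps
genes with mean Cq strictly inside (15, 30).

## geNorm

Relative quantities anchor each gene's lowest Cq at 1:
Q_ij = E_i^(min_j' Cq_ij' − Cq_ij), with per-gene amplification factor
E_i (default 2.0 when no efficiency table is supplied, the original
tool's convention). Pairwise variation V_ik is the sample SD over
samples of log₂(Q_ij/Q_kj) — log base 2 throughout — and
M_i = Σ_{k≠i} V_ik/(n−1). Because log-ratios cancel any per-sample
loading shift, M is invariant to loading; with E = 2 it is also
invariant to per-gene Cq offsets.

Ranking is by stepwise exclusion of the highest-M gene, recomputing M on
the remaining set; ties remove the lexicographically later gene id
first. The final two genes cannot be separated (their M values are
identical by construction) and share rank 1 competition-style, with the
next gene at rank 3. Genes whose M at exclusion exceeds 0.5 are flagged
unstable (conventional cut-off).

Normalization factors NF_n are per-sample geometric means of the top-n
genes' Q values; V_{n,n+1} is the sample SD of log₂(NF_n/NF_{n+1}), and
the minimal reference count n\* is the smallest n with V ≤ 0.15. Subset
analyses (e.g. per immune response or per timepoint) re-anchor Q within
the subset — equivalent to running the analysis independently on the
subset's Cq values.

## NormFinder

Model: y_igj = α_ig + μ_gj + ε_igj with ε ~ N(0, σ²_ig), where y = −Cq
(the sign convention makes larger y mean more transcript and is
irrelevant to every variance-based quantity), μ_gj a shared per-sample
effect and α_ig the gene level including a gene-by-group deviation d_ig.
Default grouping is treatment × timepoint; any annotation columns can be
used instead, and the grouping is recorded in the output.

Estimation is by the method of moments:

* Within each group, two-way centering (gene means, sample means, grand
  mean) gives residual mean squares v_ig = Σ_j r²_igj/(n_g−1). Centering
  across k genes leaks a 1/k share of every gene's variance into each
  residual: E[v_ig] = σ²_ig(1 − 2/k) + Σ_i σ²_ig/k², derived
  analytically and verified by Monte-Carlo in the test suite. The
  unbiased estimate is σ̂²_ig = (v_ig − v̄_g/(k−1))·k/(k−2), requiring
  k ≥ 3. For downstream use negative estimates truncate to zero
  (standard moment-estimator practice; it keeps the shrinkage weights
  real but introduces an upward bias for genes with near-zero true
  variance, so bias checks run untruncated).
* Group deviations d_ig are centered across genes within each group and
  across groups within each gene (Σ_i d_ig = 0 per group). The
  interaction variance γ̂² = max(0, Σd²/((k−1)(L−1)) − mean(σ̂²/n_g))
  shrinks each deviation linearly: d̃ = d·γ̂²/(γ̂² + σ̂²_ig/n_g).
* Stability: ρ_i = L⁻¹ Σ_g (|d̃_ig| + s_ig), where
  s_ig = √(γ̂²·(σ̂²_ig/n_g)/(γ̂² + σ̂²_ig/n_g)) is the posterior spread of
  d. With a single group ρ_i = σ̂_i. When γ̂² estimates to zero all
  ρ vanish — the moment estimator cannot distinguish genes without
  evidence of group-level structure, which is why recovery simulations
  plant group effects.

## BestKeeper

Per gene on the raw Cq scale: geometric and arithmetic mean, extremes,
dispersion SD[±Cq] — by default the **mean absolute deviation** around
the arithmetic mean, the original tool's definition, with the classical
sample SD as a config option (the choice is recorded in the output
metadata) — and CV[%Cq] = 100·SD/mean. x-fold transforms use the
per-gene amplification factor (default 2.0, always recorded):
SD[±x-fold] = E^SD, Max[x-fold] = E^(max − geomean), and Min[x-fold] is
reported as the negative reciprocal fold −E^(geomean − min). x-fold
deviations anchor at the geometric mean Cq. The BestKeeper index is the
per-sample geometric mean of all candidates' Cq; each gene's Pearson r
against the index carries a two-sided p from the exact t transform with
n−2 degrees of freedom (zero-variance genes yield NaN with a warning).
Ranking is by ascending (SD[±Cq], CV[%Cq], gene id) with
competition-style tied ranks; a candidate is conventionally acceptable
when SD[±Cq] < 1 and SD[±x-fold] < 2. p-values are reported as computed,
two-sided, with no floor.

**Structural limitation.** BestKeeper judges raw Cq dispersion, so a
loading effect shared by all genes of a sample inflates every gene's SD
equally and masks biological differences between genes; geNorm
(log-ratios) and NormFinder (sample-mean centering) cancel it exactly.
In simulations with loading SD twice the stable genes' biological SD,
BestKeeper's ability to pick the planted best pair collapses while the
other two algorithms are unaffected; a dedicated test asserts this
degradation, and the end-to-end recovery benchmark therefore runs the
planted scenario's own noise sources (biological noise and treatment
shifts) without a loading term.

## Consensus

Per-algorithm competition ranks (ties share the smaller rank; geNorm's
final pair is a forced tie at 1) are averaged arithmetically. The
reported mean is rounded half-up to 2 decimals; ordering uses the
full-precision mean, with exact ties broken by the NormFinder rank and
then the gene id — a reconstruction that reproduces the conventional
presentation of such tables, not a published rule. The minimal reference
count is re-derived from the geNorm V curve evaluated under the
consensus ordering.

## Quantification

Standard curves regress mean Cq per dilution level on log₁₀(amount) by
ordinary least squares; E = 10^(−1/slope), percent = (E−1)·100. Slopes
≥ 0 or shallower than −1 raise an error (not consistent with
exponential amplification). Relative expression follows
ratio = E_t^(−ΔCq_t)/E_r^(−ΔCq_r) with ΔCq = Cq(sample) −
Cq(calibrator); the calibrator's own ratio is exactly 1. For two
reference genes the default combines the **Cq values by geometric mean
and the efficiencies by arithmetic mean** (implemented literally as
commonly stated in methods sections); an alternative mode combines the
per-gene relative quantities by geometric mean. "Efficiency average" is
read as the arithmetic mean of amplification factors; averaging
percentages instead is numerically near-identical in the relevant range
and the mode is recorded in the result object. Group comparisons use the
classical equal-variance Student t-test on per-biological-replicate
ratios (Welch via flag), with `**`/`*` at p < 0.01/0.05.

## Synthetic data

The Cq generator draws
Cq = baseline_gene + shift(gene, treatment) + loading(sample) +
N(0, σ_bio,gene) + N(0, σ_tech), i.e. Gaussian noise on the Cq scale
(lognormal on quantities), matching the implicit assumptions of all
three algorithms. Defaults emulate the validation-experiment layout —
4 treatments × 2 timepoints × 3 biological × 3 technical replicates
(24 samples, 72 wells per gene) — with baselines uniform in [15, 30]
cycles. The default planted panel has two near-perfect genes
(σ = 0.05), six stable genes (σ = 0.15), one gene shifted 1.0 cycle by
two treatments and one noisy gene (σ = 0.8); loading SD is 0.3 cycles
(sample-to-sample input differences of a few tenths of a cycle are
typical even with normalized RNA input) and technical SD 0.1. Zero SDs
are valid (exact null datasets); negative SDs are config errors.

The expression generator produces RPKM-like matrices over 4 treatments
× 3 replicates (12 samples, matching the condition panel) with
lognormal baselines (median ≈ 50 RPKM), nine planted ultra-stable genes
(replicate CV 2%, baselines kept ≥ 10 RPKM — reference-gene candidates
are expressed by construction), 10% planted sub-threshold genes, 30%
differentially expressed genes with fold changes in [2, 8] on random
treatment subsets, and 25% replicate CV for the background. With only
six samples the sampling noise of a per-gene CV estimate (χ² left tail
across ~450 background genes) would make reliable recovery of the
planted set impossible at any realistic dispersion separation, which is
why the 12-sample design is the default.

The dilution-series generator follows Cq = intercept − log(a)/log(E)
with optional Gaussian noise, at the conventional 1:5/1:10/1:100/1:1000
levels.

What the generators do **not** emulate: amplification-curve
(fluorescence) shapes, plate/run effects and inter-run calibration,
PCR inhibition or efficiency drift across the dynamic range, RNA-seq
count noise (RPKM values are drawn directly, not from read counts), and
gene–gene expression correlation. Passing recovery tests therefore
demonstrates correctness of the estimators under their own model
assumptions, not robustness to these real-data artifacts.

## Test-design notes and problem sizes

* Oracle-equivalence tests compare geNorm V/M, normalization-factor
  geometric means and BestKeeper index/correlations with independent
  brute-force evaluations on 100 random 5 × 12 matrices (1e−9
  relative).
* The NormFinder de-biasing correction is verified by a 2000-replicate
  Monte-Carlo (k = 10, n = 12, σ ∈ [0.2, 0.8], untruncated, |bias| <
  5%).
* The rank-recovery simulation (k = 10, L = 2, n_g = 12) plants group
  shifts of 2σ with alternating sign so that the population stability
  values are strictly ordered — at smaller shifts adjacent genes'
  population values overlap and a "true ranking" ceases to exist — and
  requires mean Spearman ≥ 0.9 between estimated and planted order.
* Recovery suites use 200 seeds (40 in the faster per-module variants);
  the end-to-end benchmark measures ~92% joint recovery of the planted
  pair and n\* = 2 over 600 seeds, so individual 200-seed streams
  fluctuate by roughly ±2 percentage points.
* The t-test calibration runs 5000 null replicates (two groups of 3,
  lognormal with 10% spread) and expects a type-I error of 0.05 ± 0.02.

## Known limitations

* BestKeeper's loading sensitivity (above) is inherent to the method.
* NormFinder's moment estimator is noisy at n_g = 3 (the common
  three-replicate design): with eight groups of three, discrimination
  between σ = 0.05 and σ = 0.15 genes succeeds only ~50% of the time on
  its own; the consensus compensates.
* The geNorm final pair is reported in lexicographic order and shares
  one M value; the procedure cannot rank within the pair.
* Efficiency estimation assumes a single global efficiency per gene
  across the dilution range.
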