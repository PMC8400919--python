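# Methods

This note documents the models, conventions and numerical choices behind
`metabrobust`, and what its synthetic benchmarks do and do not show about
real instrument data.

## Screening designs

Plackett–Burman (PB) matrices are built by cyclic rotation of the classical
generating rows (orders 4, 8, 12, 16, 20) plus an all-minus row, truncated
to the requested number of factors; the run count is the smallest multiple
of 4 strictly greater than the factor count. Balance (equal counts of −1
and +1 per column) and pairwise orthogonality (zero column dot products)
are checked by brute force over the factorial runs; centre runs contribute
zero to both and are ignored by the checks. PB designs estimate main
effects only — all interactions are assumed negligible, which is the
standard assumption for robustness screening.

The packaged 15-run worksheet (10 protocol factors + 1 dummy, 3 centre
runs) is a transcription of a published robustness worksheet. Its row 12 is
the all-plus run rather than the all-minus row of the textbook generator;
the two forms are equivalent up to row/column permutation and column sign
flips. Rather than attempting a cell-by-cell match, the equivalence test
extends both matrices with an all-ones column and verifies `H·Hᵀ = 12·I`:
both are then Hadamard matrices of order 12, which are unique up to exactly
those operations.

Centre-point placement: the worksheet interleaves its three centre runs at
ordinal positions 6, 10 and 15, which no even-spacing formula reproduces
(factorial blocks of 5, 3 and 4). The `interleaved` policy therefore pins
the canonical (12 factorial, k = 3) layout to 6/10/15 and falls back to
even spacing (last centre closing the batch) for other shapes; explicit
positions are always accepted. Execution-order randomization exists behind
an explicit seed but is off by default, since the worksheet order is fixed.

One worksheet column is labelled `vortex1 [min]` with levels 165–195; those
numbers are consistent with a 3-minute vortexing step only if the true unit
is seconds. The fixture preserves the printed numbers and label verbatim,
with a comment noting the suspected discrepancy.

## Alignment

Cross-sample alignment is greedy centroid clustering: peaks are visited in
descending abundance (ties broken on m/z, RT, then sample id, making the
result deterministic); a peak joins the feature with the nearest consensus
within 15 ppm and 0.15 min — smallest ppm distance first, then smallest RT
distance, then lowest feature id — unless the feature already holds a peak
from that sample, in which case the peak seeds a new feature. Consensus
m/z and RT are abundance-weighted means of the members, a choice that is
robust to low-signal stragglers; tolerance tests are against the consensus,
not member-vs-member (the vendor tools this replaces do not document their
convention, so one had to be fixed). Results are not expected to match any
vendor tool cell-for-cell, only to honour the stated tolerances.

Adduct grouping links co-eluting features (ΔRT ≤ 0.15 min) whose m/z gap
matches a pairwise difference of the mode's ion offsets (positive: +H, +Na,
+K, +NH4 and water loss; negative: −H, +HCOO, +Cl and water loss; standard
monoisotopic masses, electron mass included) within the ppm tolerance of
the larger m/z, then takes the transitive closure. Grouping is
informational; abundances are never merged, because the collapsing rule of
the original deconvolution software is unknown.

Missing abundances are explicit NA everywhere, never zeros.

## Filter cascade

Blank exclusion removes any feature with a non-missing abundance in any
blank — an outright discard, with no fold-change ratio, as is common when
blanks are solvent-only extractions. Replicate presence requires detection
in all replicates of a group. CV is the percent sample standard deviation
(n − 1 denominator, appropriate for three replicates) over the raw (not
log) abundances, undefined below two values or at zero mean; the
reproducibility threshold is strict (`cv < 20%`). Stage counts are
asserted monotone on every run. Mean CV per method averages over the
extracted (all-replicate-present) features with a defined CV, not over
reproducible features only.

Exclusive intersection counts use UpSet semantics: each feature counts
toward exactly the subset of methods that detected it, so the counts sum
to the union size — an invariant asserted against a per-feature membership
oracle.

## Robustness model

Abundances enter the model as natural logarithms; features missing in any
run are excluded rather than imputed (15 runs cannot support a missingness
model; exclusions are reported). Natural log makes the percent reading of
a coefficient the small-x linearization of `e^β − 1`, so `β = 0.1` ≈ +10%.
Coded levels −1/0/+1 are used as regressors exactly as designed, not
rescaled physical units, so a coefficient is "per coded step".

**Pooled variant.** `y[m,i] = α[m] + Σ_f β[f]·x[i,f] + ε`. The
per-metabolite intercepts are profiled out exactly (flat prior), reducing
the problem to ridge-penalized least squares on centred data: the MAP for
`β` under a `N(0, s_β²)` prior (default scale 1 on the log scale — weakly
informative, since protocol effects beyond ±100% are implausible) is
closed-form given σ, and σ is iterated to its stationary point using a
REML-flavoured denominator `m(n−1) − f`. Uncertainties are posterior
(Laplace) standard deviations. An optional MCMC backend (emcee ensemble
sampler over `(β, log σ)` with the intercepts marginalized, half-normal
prior scale 1 on σ) gives full posteriors; both backends are deterministic
under a fixed seed and agree with the analytic least-squares projection to
10⁻⁶ as the priors flatten — a test asserts this oracle equivalence.

**Partial-pooling variant.** `β[m,f] ~ N(β[f], τ[f])`. Because the coded
design is orthogonal and shared by all metabolites, per-metabolite OLS
coefficients with equal sampling variance `v_f = σ²(X̃ᵀX̃)⁻¹_ff` are
sufficient, and the problem factorizes per factor into a standard
random-effects combination: `τ[f]` maximizes the marginal likelihood of
the per-metabolite coefficients under a half-normal prior (default scale
1), `β[f]` is their precision-weighted mean, and per-metabolite
coefficients are shrunk toward it by `τ²/(τ² + v)`. As `τ → 0` the
population estimates coincide with the pooled fit (tested); a statsmodels
MixedLM fit serves as an independent cross-check in the test suite, never
as the implementation. The four chromatography/ionization modes of a real
study are fitted separately, one dataset per mode; no QC normalization is
applied by default.

The dummy factor is fitted exactly like real factors; under a null
simulation its coefficient distribution matches theirs, which is what
makes it an error estimate.

**QC drift.** Per feature, the least-squares slope of log abundance
against injection order over the repeated QC injections (≥ 3 required);
the batch is flagged when the median absolute slope exceeds 0.01 per
injection (~1% drift). With only three QC injections this check is
deliberately conservative: pure replicate noise of 15% already produces
slope estimates around 0.02, so small batches can be flagged without true
drift; more QC injections sharpen it.

## Synthetic data

The generator emulates: log-normal baselines (default mean 9.2, sd 1.5 on
the natural-log scale — a median near 10⁴ counts spanning ~3 decades,
typical of TOF tissue profiles and comfortably above the 200-count floor),
multiplicative replicate noise with log-sd `sqrt(ln(1 + (CV/100)²))` so
the target percent CV is exact in expectation (default 15%, a realistic
replicate-extraction CV), design-driven effects `exp(Σ β·x)` applied to
non-contaminant features, solvent contaminants present in every sample
including blanks, Bernoulli dropout (default 5%), and m/z/RT jitter drawn
*uniformly* within ±5 ppm / ±0.05 min — bounded jitter, so "within half
the alignment tolerances" is a hard guarantee and alignment recovery of
the planted feature count is exact rather than probabilistic. QC samples
are drawn from one fixed pool (injected after every 4 study samples, with
an optional exponential drift per injection to exercise the drift check).
All randomness flows from one seed; identical seeds give bit-identical
outputs.

What this does **not** emulate: chromatographic peak shapes, isotope
patterns, correlated (batch/drift) noise in study samples, heteroscedastic
low-signal variance, adduct relationships between generated features, or
realistic metabolite identities. Passing recovery tests therefore shows
the pipeline's logic is correct under its stated assumptions, not that a
particular real dataset's counts would be reproduced — real vendor
alignment and deconvolution differ in undocumented ways.

## Problem sizes and determinism

The test suite and examples use 50–1000 features, 15-run designs and 3–4
method groups with 3 replicates — sizes chosen so each statistical check
(e.g. parameter recovery of a −0.15 effect at 300 features and residual
sd 0.2, within ±0.05) has comfortable power while the whole suite runs in
seconds. All stochastic tests fix seeds; hypothesis-based property tests
run derandomized.

## Known limitations

- Greedy consensus alignment can, in principle, let a consensus drift so a
  early member ends slightly outside tolerance of the final consensus;
  with bounded jitter this cannot happen, but heavy-tailed real jitter
  could produce occasional splits.
- The MAP sigma is a stationary-point plug-in, not a marginal posterior
  mean; for the small-n/large-m regimes here the difference is negligible
  (the MCMC backend is available when it is not).
- `add_centre_points` treats the canonical 6/10/15 layout as a special
  case; other run counts get even spacing, which is a convention, not a
  statistical requirement.
- The per-metabolite variant assumes a shared residual σ across
  metabolites; strongly heteroscedastic features would need per-feature
  variances.
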