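# metabrobust

Tools for the computational half of developing a sample-preparation method
for untargeted LC-MS metabolomics: comparing liquid–liquid extraction
protocols on feature counts and reproducibility, and testing the winning
protocol's robustness with a Plackett–Burman screening design analysed by
hierarchical linear modelling.

It is written for analytical chemists and bioinformaticians who have
per-sample peak lists (m/z, retention time, abundance) from replicate
extractions — for example of tumour tissue homogenates — and want a
scripted, reproducible version of the usual manual workflow: noise
filtering, cross-sample alignment, blank subtraction, replicate-presence
and CV filtering, method comparison with UpSet-style overlap counts, and
design-based robustness analysis with QC drift checks. A seeded synthetic
data generator with full ground truth makes every stage testable without
instrument data.

## The model at the core

Protocol robustness is screened with a Plackett–Burman design: `n` runs
(a multiple of 4) screen up to `n − 1` two-level factors, so 10 protocol
factors plus one *dummy* factor (tied to no real change; its apparent
effect estimates error) need 12 factorial runs, plus replicated
centre-point runs — 15 samples in all. Factor effects on the measured
features are estimated jointly across metabolites on the natural-log scale:

    y[m, i] = α[m] + Σ_f β[f] · x[i, f] + ε,    ε ~ N(0, σ)

with `y[m, i]` the log abundance of metabolite `m` in run `i` and
`x[i, f] ∈ {−1, 0, +1}` the coded level of factor `f`. The pooled variant
shares one `β[f]` across metabolites; the partial-pooling variant lets
`β[m, f] ~ N(β[f], τ[f])`. Modelling all metabolites in one hierarchical
regression shares information across analytes and avoids the multiple
comparisons of per-feature tests. A coefficient is read as a percent
change per unit coded step: `β = 0.1` ≈ +10% abundance (exactly
`(e^β − 1)·100%`).

Feature quality follows the standard cascade: signals under 200 counts are
noise; peaks align across samples within 15 ppm and 0.15 min; features seen
in any solvent blank are contamination; a feature counts as extracted by a
method only when detected in **all** replicates; reproducible means CV
(sample SD / mean) strictly below 20%.

## Worked example

`examples/03_robustness_modelling.py` simulates the 15-run batch with a
known −0.15 log-scale effect of factor F4 (an MTBE-volume-like
perturbation, replicate CV 15%, 30 blank contaminants), runs the full
pipeline and fits the pooled model:

```
modelling 221 features over 15 runs (79 excluded for missingness)
          beta      sd  percent_change
factor
F1     -0.0009  0.0029         -0.0852
F2     -0.0025  0.0029         -0.2494
F3      0.0067  0.0029          0.6749
F4     -0.1567  0.0029        -15.6710
...
F11    -0.0016  0.0029         -0.1600

F4 coefficient -0.157 -> -15.7% abundance change per coded step (true effect was -15%).
```

The planted factor is recovered at −15.7% (truth −15%); every unperturbed
factor, including the dummy (F11), stays near zero — the simulated
procedure is robust to those fluctuations. The other examples build and
decode the packaged 15-run worksheet (`examples/01_build_and_decode_design.py`)
and compare four simulated extraction methods on counts, CV and exclusive
overlaps (`examples/02_method_comparison.py`).

The same workflows are scriptable from the shell:

```
metabrobust design generate --n-factors 11 --centre 3 --out design.csv
metabrobust simulate robustness --seed 2 --out simdir
metabrobust robustness --config config.yaml
metabrobust compare --config config.yaml
```

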