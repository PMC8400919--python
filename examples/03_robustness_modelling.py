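"""Fit the hierarchical factor-effect model on a simulated screening batch.

Simulates the 15-run screening batch with a known -0.15 log-scale effect of
one factor (an MTBE-volume-like perturbation), runs alignment and blank
filtering, fits the pooled hierarchical model on log abundances, and reads
the coefficients as percent changes.  Also checks QC signal drift.
"""

from metabrobust import (
    ModelConfig,
    SimulationConfig,
    add_centre_points,
    align_features,
    assemble_robustness_dataset,
    drop_blank_features,
    fit_pooled_model,
    generate_pb_matrix,
    interpret_coefficient,
    qc_drift_check,
    simulate_robustness_experiment,
)

design = add_centre_points(generate_pb_matrix(11), 3)  # 12 factorial + 3 centre
config = SimulationConfig(
    n_features=300, cv_pct=15.0, dropout=0.02, n_blank_contaminants=30,
    betas={"F4": -0.15}, seed=7,
)
peaklists, truth = simulate_robustness_experiment(design, config)
table = align_features(peaklists)
clean = drop_blank_features(table)
dataset = assemble_robustness_dataset(clean, design)
print(f"modelling {dataset.n_metabolites} features over {dataset.n_runs} runs "
      f"({len(dataset.excluded)} excluded for missingness)")

estimates = fit_pooled_model(dataset, ModelConfig(seed=7))
frame = estimates.to_frame().round(4)
print(frame)
print()
beta = estimates.beta["F4"]
print(f"F4 coefficient {beta:.3f} -> {interpret_coefficient(beta):+.1f}% abundance "
      "change per coded step (true effect was -15%).")
print("All other coefficients hover near 0 within ~2 sd: the procedure is")
print("robust to those perturbations; the dummy factor gauges pure error.")

drift = qc_drift_check(table)
print(f"\nQC drift: median |slope| {drift.median_abs_slope:.4f} log-units/injection "
      f"over {drift.n_injections} injections -> {'PASS' if drift.passed else 'FAIL'}")
print("With only three QC injections, replicate noise alone puts per-feature")
print("slope estimates around 0.02, so the strict 0.01 default flags this")
print("noisy-but-driftless batch; more QC injections sharpen the check.")
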