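"""Compare simulated extraction methods on feature counts and reproducibility.

Simulates four extraction methods drawing from a shared feature universe
with different noise levels, aligns the replicate peak lists, removes
blank-borne contaminants, and summarises each method by extracted features,
reproducible (CV < 20%) features and mean CV — plus the exclusive overlap
counts an UpSet plot would show.
"""

from metabrobust import (
    SimulationConfig,
    align_features,
    drop_blank_features,
    intersection_counts,
    noise_filter,
    simulate_method_comparison,
    summarize_methods,
)

configs = {
    "A": SimulationConfig(n_features=260, cv_pct=18.0, dropout=0.03, seed=1),
    "B": SimulationConfig(n_features=240, cv_pct=8.0, dropout=0.01, seed=1),
    "C": SimulationConfig(n_features=250, cv_pct=15.0, dropout=0.03, seed=1),
    "D": SimulationConfig(n_features=150, cv_pct=30.0, dropout=0.10, seed=1),
}
peaklists, truth = simulate_method_comparison(configs, n_replicates=3,
                                              universe_size=300, seed=1)
peaklists = [noise_filter(pl, 200.0) for pl in peaklists]
table = align_features(peaklists, ppm_tol=15.0, rt_tol_min=0.15)
clean = drop_blank_features(table)

summary = summarize_methods(clean)
print(summary.to_frame().round(2))
print()
print("A feature counts for a method only when seen in all 3 replicates;")
print("'reproducible' additionally needs CV < 20% — the low-CV method keeps")
print("nearly everything, the noisy one loses half despite extracting plenty.")

ic = intersection_counts(summary.feature_sets)
top = ic.to_frame().sort_values("count", ascending=False).head(5)
print()
print(top.to_string(index=False))
print(f"exclusive counts sum to the union of all sets: {ic.union_size}")
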