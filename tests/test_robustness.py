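"""Hierarchical factor-effect model: assembly, fitting, interpretation, QC drift."""

import math

import numpy as np
import pandas as pd
import pytest

from metabrobust.design import add_centre_points, generate_pb_matrix
from metabrobust.robustness import (
    ModelConfig,
    RobustnessDataset,
    assemble_robustness_dataset,
    fit_per_metabolite_model,
    fit_pooled_model,
    interpret_coefficient,
    qc_drift_check,
)
from conftest import make_feature_table

FLAT = 1e6  # prior scale wide enough to make MAP coincide with least squares


def synthetic_dataset(design, betas, m=20, sigma=0.0, rng=None, baseline=10.0):
    """Build a RobustnessDataset directly from the model equation."""
    X = design.coded_array().astype(float)
    n, f = X.shape
    rng = rng or np.random.default_rng(0)
    alpha = baseline + rng.normal(0, 1, m)
    beta = np.asarray(betas, dtype=float)
    Y = alpha[:, None] + (X @ beta)[None, :] + rng.normal(0, sigma, (m, n))
    return RobustnessDataset(
        y=Y,
        x=X,
        metabolite_ids=[f"m{i}" for i in range(m)],
        run_ids=[r.run_id for r in design.runs],
        factor_names=list(design.factor_names),
    )


def ls_projection(dataset):
    """Independent analytic oracle: least-squares on centred data."""
    Xc = dataset.x - dataset.x.mean(axis=0)
    Yc = dataset.y - dataset.y.mean(axis=1, keepdims=True)
    return np.linalg.lstsq(Xc, Yc.mean(axis=0), rcond=None)[0]


class TestAssembly:
    def _table(self):
        return make_feature_table(
            {
                "f1": {"s1": 100.0, "s2": 150.0, "s3": 120.0, "s4": 130.0},
                "f2": {"s1": 50.0, "s2": None, "s3": 60.0, "s4": 70.0},
            },
            design_runs={"s1": "1", "s2": "2", "s3": "3", "s4": "4"},
        )

    def test_natural_log_and_missingness_exclusion(self):
        design = generate_pb_matrix(3)
        ds = assemble_robustness_dataset(self._table(), design)
        assert ds.metabolite_ids == ["f1"]
        assert ds.excluded == ["f2"]
        assert ds.y[0, 0] == pytest.approx(math.log(100.0))
        assert ds.y[0, 0] == pytest.approx(4.60517, abs=1e-5)

    def test_zero_abundance_rejected(self):
        t = make_feature_table(
            {"f1": {"s1": 0.0, "s2": 5.0}},
            design_runs={"s1": "1", "s2": "2"},
        )
        with pytest.raises(ValueError, match="log"):
            assemble_robustness_dataset(t, generate_pb_matrix(3))

    def test_unmapped_sample_rejected(self):
        t = make_feature_table({"f1": {"s1": 1.0, "s2": 2.0}})
        with pytest.raises(ValueError, match="no design_run"):
            assemble_robustness_dataset(t, generate_pb_matrix(3))

    def test_rows_ordered_by_design_run(self):
        t = self._table()
        ds = assemble_robustness_dataset(t, generate_pb_matrix(3))
        assert ds.run_ids == ["1", "2", "3", "4"]


class TestPooledModel:
    def test_noiseless_recovery_matches_truth_to_1e6(self):
        design = add_centre_points(generate_pb_matrix(11), 3)
        beta = np.zeros(11)
        beta[3] = 0.1
        ds = synthetic_dataset(design, beta)
        est = fit_pooled_model(ds, ModelConfig(prior_scale_beta=FLAT))
        assert est.beta[ds.factor_names[3]] == pytest.approx(0.1, abs=1e-6)
        for j, name in enumerate(ds.factor_names):
            if j != 3:
                assert est.beta[name] == pytest.approx(0.0, abs=1e-6)

    def test_flat_prior_map_equals_least_squares_oracle(self, rng):
        design = add_centre_points(generate_pb_matrix(11), 3)
        beta = rng.normal(0, 0.1, 11)
        ds = synthetic_dataset(design, beta, m=30, sigma=0.3, rng=rng)
        est = fit_pooled_model(ds, ModelConfig(prior_scale_beta=FLAT))
        expected = ls_projection(ds)
        got = np.array([est.beta[n] for n in ds.factor_names])
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_mcmc_backend_agrees_with_oracle_within_posterior_sd(self, rng):
        design = generate_pb_matrix(7)
        beta = rng.normal(0, 0.1, 7)
        ds = synthetic_dataset(design, beta, m=15, sigma=0.2, rng=rng)
        cfg = ModelConfig(backend="mcmc", prior_scale_beta=FLAT, seed=11, iterations=600)
        est = fit_pooled_model(ds, cfg)
        expected = ls_projection(ds)
        for j, name in enumerate(ds.factor_names):
            assert abs(est.beta[name] - expected[j]) < 4 * est.beta_sd[name]
        # fixed seed -> identical estimates
        est2 = fit_pooled_model(ds, cfg)
        assert est.beta == est2.beta

    def test_null_simulation_keeps_betas_within_two_sd_usually(self):
        # pure-noise simulations: per factor, |beta| < 2 sd in >= 95% of runs
        design = add_centre_points(generate_pb_matrix(11), 3)
        hits, total = 0, 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            ds = synthetic_dataset(design, np.zeros(11), m=100, sigma=0.2, rng=rng)
            est = fit_pooled_model(ds)
            for name in ds.factor_names:
                total += 1
                hits += abs(est.beta[name]) < 2 * est.beta_sd[name]
        assert hits / total >= 0.92

    def test_duplicated_metabolites_same_beta_smaller_sd(self, rng):
        design = generate_pb_matrix(7)
        ds = synthetic_dataset(design, rng.normal(0, 0.1, 7), m=10, sigma=0.2, rng=rng)
        dup = RobustnessDataset(
            y=np.vstack([ds.y] * 4),
            x=ds.x,
            metabolite_ids=[f"{m}_{k}" for k in range(4) for m in ds.metabolite_ids],
            run_ids=ds.run_ids,
            factor_names=ds.factor_names,
        )
        a = fit_pooled_model(ds, ModelConfig(prior_scale_beta=FLAT))
        b = fit_pooled_model(dup, ModelConfig(prior_scale_beta=FLAT))
        for name in ds.factor_names:
            assert a.beta[name] == pytest.approx(b.beta[name], abs=1e-9)
            assert b.beta_sd[name] < a.beta_sd[name]

    def test_centre_points_leave_noiseless_betas_unchanged(self):
        base = generate_pb_matrix(11)
        with_centres = add_centre_points(base, 3)
        beta = np.zeros(11)
        beta[0] = -0.15
        a = fit_pooled_model(synthetic_dataset(base, beta), ModelConfig(prior_scale_beta=FLAT))
        b = fit_pooled_model(
            synthetic_dataset(with_centres, beta), ModelConfig(prior_scale_beta=FLAT)
        )
        for name in a.factor_names:
            assert a.beta[name] == pytest.approx(b.beta[name], abs=1e-9)

    def test_degenerate_design_rejected(self):
        design = generate_pb_matrix(3)
        ds = synthetic_dataset(design, np.zeros(3), m=5)
        ds.x[:, 1] = 1.0  # constant column
        with pytest.raises(ValueError, match="degenerate"):
            fit_pooled_model(ds)


class TestPerMetaboliteModel:
    def test_population_parameters_recovered(self):
        design = add_centre_points(generate_pb_matrix(11), 3)
        rng = np.random.default_rng(42)
        m = 200
        X = design.coded_array().astype(float)
        betas_m = rng.normal(0.1, 0.05, (m, 11)) * 0  # start at zero
        betas_m[:, 2] = rng.normal(0.1, 0.05, m)      # one heterogeneous factor
        alpha = 10 + rng.normal(0, 1, m)
        Y = alpha[:, None] + np.einsum("mf,nf->mn", betas_m, X) + rng.normal(0, 0.1, (m, X.shape[0]))
        ds = RobustnessDataset(
            y=Y, x=X,
            metabolite_ids=[f"m{i}" for i in range(m)],
            run_ids=[r.run_id for r in design.runs],
            factor_names=list(design.factor_names),
        )
        est = fit_per_metabolite_model(ds, ModelConfig(variant="per_metabolite"))
        name = ds.factor_names[2]
        assert abs(est.beta[name] - 0.1) < 2 * est.beta_sd[name] + 1e-9
        assert est.tau[name] == pytest.approx(0.05, abs=0.02)

    def test_tau_prior_near_zero_reduces_to_pooled(self, rng):
        design = add_centre_points(generate_pb_matrix(7), 2)
        ds = synthetic_dataset(design, rng.normal(0, 0.1, 7), m=20, sigma=0.2, rng=rng)
        hier = fit_per_metabolite_model(
            ds, ModelConfig(variant="per_metabolite", prior_scale_tau=1e-8)
        )
        pooled = fit_pooled_model(ds, ModelConfig(prior_scale_beta=FLAT))
        for name in ds.factor_names:
            assert hier.beta[name] == pytest.approx(pooled.beta[name], abs=1e-6)
            assert hier.tau[name] == pytest.approx(0.0, abs=1e-6)

    def test_shared_response_concentrates_tau_near_zero(self, rng):
        design = add_centre_points(generate_pb_matrix(11), 3)
        beta = np.zeros(11)
        beta[4] = 0.2
        ds = synthetic_dataset(design, beta, m=100, sigma=0.05, rng=rng)
        est = fit_per_metabolite_model(ds, ModelConfig(variant="per_metabolite"))
        # every metabolite responds identically, so the between-metabolite
        # spread should be small relative to its sampling noise
        v = est.sigma**2 / 12  # sampling variance of a per-metabolite slope
        assert est.tau[ds.factor_names[4]] < 2 * math.sqrt(v)

    def test_cross_check_against_mixed_model(self, rng):
        # independent route: statsmodels MixedLM with random slopes
        import statsmodels.formula.api as smf

        design = add_centre_points(generate_pb_matrix(3), 3)
        m = 30
        X = design.coded_array().astype(float)
        n = X.shape[0]
        betas_m = rng.normal(0.15, 0.05, (m, 1))
        alpha = 8 + rng.normal(0, 0.5, m)
        Y = alpha[:, None] + betas_m @ X[:, :1].T + rng.normal(0, 0.1, (m, n))
        ds = RobustnessDataset(
            y=Y, x=X, metabolite_ids=[f"m{i}" for i in range(m)],
            run_ids=[r.run_id for r in design.runs],
            factor_names=list(design.factor_names),
        )
        est = fit_per_metabolite_model(ds, ModelConfig(variant="per_metabolite"))
        long = pd.DataFrame({
            "y": Y.ravel(),
            "x1": np.tile(X[:, 0], m),
            "met": np.repeat([f"m{i}" for i in range(m)], n),
        })
        fit = smf.mixedlm("y ~ x1", long, groups="met", re_formula="~x1").fit(reml=True)
        assert est.beta[ds.factor_names[0]] == pytest.approx(fit.params["x1"], abs=0.02)


class TestInterpretation:
    @pytest.mark.parametrize("beta,pct", [(0.1, 10.0), (-0.15, -15.0), (0.0, 0.0)])
    def test_percent_change_linearization(self, beta, pct):
        assert interpret_coefficient(beta) == pytest.approx(pct)


class TestQCDrift:
    def _qc_table(self, values_by_order):
        abundance = {
            f"f{i}": {f"q{o}": v[i] for o, v in values_by_order.items()}
            for i in range(len(next(iter(values_by_order.values()))))
        }
        roles = {f"q{o}": "qc" for o in values_by_order}
        inj = {f"q{o}": o for o in values_by_order}
        return make_feature_table(abundance, roles=roles, injection_order=inj)

    def test_constant_qc_passes_with_zero_slopes(self):
        t = self._qc_table({1: [100.0, 200.0], 2: [100.0, 200.0], 3: [100.0, 200.0]})
        report = qc_drift_check(t)
        assert report.median_abs_slope == pytest.approx(0.0, abs=1e-12)
        assert report.passed

    def test_five_percent_growth_gives_log_slope(self):
        vals = {o: [100.0 * 1.05 ** o] for o in (1, 2, 3, 4)}
        report = qc_drift_check(self._qc_table(vals))
        assert report.slopes.iloc[0] == pytest.approx(math.log(1.05), abs=1e-9)
        assert report.slopes.iloc[0] == pytest.approx(0.04879, abs=1e-5)
        assert not report.passed

    def test_fewer_than_three_injections_rejected(self):
        t = self._qc_table({1: [100.0], 2: [100.0]})
        with pytest.raises(ValueError, match="3 QC"):
            qc_drift_check(t)
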