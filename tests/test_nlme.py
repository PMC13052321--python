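"""NLME estimation: quadrature oracle for the Laplace approximation,
degenerate limits, recovery on noise-free data, mixes, bootstrap, VPC."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from pkgan.nlme import (
    NlmePkModel,
    StructuralModelSpec,
    TABLE_MIXES,
    _Design,
    _Likelihood,
    bootstrap,
    build_mixes,
    fit,
    marginal_negloglik,
    vpc,
)
from pkgan.popsim import (
    GroundTruthParameters,
    PopulationSpec,
    concentration,
    simulate_dataset,
)

TRUTH = dict(
    ka_pop=0.5, v_pop=14.0, cl_pop=5.0, beta_wt_v=0.75,
    omega_ka=0.2, omega_v=0.3, omega_cl=0.2, a=0.2, b=0.1,
)


def quad_negloglik(params, long_df, spec):
    """Exact 1-D marginal likelihood oracle (only eta_ka active)."""
    d = _Design(long_df, spec)
    total = 0.0
    om = params["omega_ka"]
    for i in range(d.n_subjects):
        t = d.t[i][d.mask[i]]
        y = d.y[i][d.mask[i]]
        v = params["v_pop"] * (d.wt[i] / spec.w_ref) ** params["beta_wt_v"]

        def integrand(eta):
            ka = params["ka_pop"] * np.exp(eta)
            c = np.maximum(concentration(ka, v, params["cl_pop"], d.dose[i], t), 0.0)
            sig = params["a"] + params["b"] * c
            ll = (
                -0.5 * np.log(2 * np.pi) * len(t)
                - np.log(sig).sum()
                - 0.5 * (((y - c) / sig) ** 2).sum()
            )
            prior = -0.5 * np.log(2 * np.pi) - np.log(om) - 0.5 * (eta / om) ** 2
            return np.exp(ll + prior)

        val, _ = quad(integrand, -10 * om, 10 * om, limit=200, epsabs=1e-13, epsrel=1e-11)
        total += -np.log(val)
    return total


class TestMarginalLikelihood:
    def test_laplace_matches_quadrature_oracle(self):
        theta = GroundTruthParameters(omega_v=0.0, omega_cl=0.0)
        _, _, long_df = simulate_dataset(theta, PopulationSpec(n_female=1, n_male=1), seed=5)
        spec = StructuralModelSpec(fixed={"omega_v": 0, "omega_cl": 0})
        params = {**TRUTH, "omega_v": 0.0, "omega_cl": 0.0}
        lap = marginal_negloglik(params, long_df, spec)
        exact = quad_negloglik(params, long_df, spec)
        assert lap == pytest.approx(exact, rel=1e-3)

    def test_zero_variability_reduces_to_least_squares_likelihood(self):
        theta = GroundTruthParameters(omega_ka=0.0, omega_v=0.0, omega_cl=0.0)
        _, _, long_df = simulate_dataset(theta, PopulationSpec(n_female=2, n_male=0), seed=2)
        spec = StructuralModelSpec(fixed={"omega_ka": 0, "omega_v": 0, "omega_cl": 0})
        params = {**TRUTH, "omega_ka": 0.0, "omega_v": 0.0, "omega_cl": 0.0}
        got = marginal_negloglik(params, long_df, spec)
        # direct fixed-effects likelihood at eta = 0
        d = _Design(long_df, spec)
        expected = 0.0
        for i in range(d.n_subjects):
            t = d.t[i][d.mask[i]]
            y = d.y[i][d.mask[i]]
            v = 14.0 * (d.wt[i] / 70.0) ** 0.75
            c = concentration(0.5, v, 5.0, 300.0, t)
            sig = 0.2 + 0.1 * c
            expected += (
                0.5 * np.log(2 * np.pi) * len(t)
                + np.log(sig).sum()
                + 0.5 * (((y - c) / sig) ** 2).sum()
            )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_truth_beats_perturbed_parameters_on_large_dataset(self):
        _, _, long_df = simulate_dataset(seed=3, spec=PopulationSpec(n_female=50, n_male=50))
        at_truth = marginal_negloglik(TRUTH, long_df)
        doubled = {
            k: (v * 2 if k not in ("beta_wt_v",) else v * 2) for k, v in TRUTH.items()
        }
        assert at_truth < marginal_negloglik(doubled, long_df)

    def test_analytic_hessian_matches_complex_step(self, study):
        # dual route: hand-derived second derivatives of the concentration
        # curve vs complex-step differentiation of the analytic gradient
        from pkgan._kernels import hessian_analytic, hessian_complex_step

        spec = StructuralModelSpec()
        d = _Design(study["long"], spec)
        rng = np.random.default_rng(3)
        active = np.array([0, 1, 2], dtype=np.int64)
        for _ in range(30):
            i = int(rng.integers(d.n_subjects))
            e = rng.normal(scale=0.5, size=3)
            ka, v, cl = np.exp(rng.normal(np.log([0.5, 14.0, 5.0]), 0.5))
            a_, b_ = np.exp(rng.normal(np.log([0.2, 0.1]), 0.3))
            om = np.exp(rng.normal(np.log(0.25), 0.3, size=3))
            nobs = int(d.mask[i].sum())
            ha = hessian_analytic(e, d.t, d.y, nobs, i, d.wt[i], d.dose[i],
                                  ka, v, cl, 0.75, 70.0, a_, b_, active, 3)
            hc = hessian_complex_step(e, d.t, d.y, nobs, i, d.wt[i], d.dose[i],
                                      ka, v, cl, 0.75, 70.0, a_, b_, om, active, 3)
            scale = max(1.0, np.abs(hc).max())
            assert np.abs(ha - hc).max() / scale < 1e-8

    def test_numba_and_numpy_engines_agree(self, study):
        spec = StructuralModelSpec()
        lik = _Likelihood(_Design(study["long"], spec), spec)
        for params in (TRUTH, {**TRUTH, "ka_pop": 1.2, "omega_v": 0.5, "b": 0.02}):
            va = lik.value(params, engine="numba")
            lik._eta_ws = np.zeros_like(lik._eta_ws)
            vb = lik.value(params, engine="numpy")
            assert va == pytest.approx(vb, abs=1e-6)


class TestFit:
    def test_recovers_truth_from_noise_free_zero_iiv_data(self):
        theta = GroundTruthParameters(
            a=1e-4, b=0.0, omega_ka=0.0, omega_v=0.0, omega_cl=0.0
        )
        _, _, long_df = simulate_dataset(theta, PopulationSpec(n_female=3, n_male=3), seed=4)
        spec = StructuralModelSpec(
            fixed={"omega_ka": 0, "omega_v": 0, "omega_cl": 0, "a": 1e-4, "b": 1e-6}
        )
        m = NlmePkModel(spec=spec, n_starts=2, random_state=0).fit(long_df)
        assert m.ka_pop_ == pytest.approx(0.5, rel=1e-3)
        assert m.v_pop_ == pytest.approx(14.0, rel=1e-3)
        assert m.cl_pop_ == pytest.approx(5.0, rel=1e-3)
        assert m.beta_wt_v_ == pytest.approx(0.75, abs=5e-3)

    def test_estimates_invariant_to_subject_relabeling_and_row_order(self, study):
        # re-keying subjects only reorders the per-subject likelihood sums,
        # so estimates agree up to optimizer tolerance
        long_df = study["long"]
        m1 = NlmePkModel(n_starts=1, random_state=0).fit(long_df)
        relabeled = long_df.copy()
        relabeled["ID"] = 1000 - relabeled["ID"]
        shuffled = relabeled.sample(frac=1.0, random_state=1)
        m2 = NlmePkModel(n_starts=1, random_state=0).fit(shuffled)
        assert m1.loglik_ == pytest.approx(m2.loglik_, rel=1e-4)
        for p in ("ka_pop_", "v_pop_", "cl_pop_"):
            assert getattr(m1, p) == pytest.approx(getattr(m2, p), rel=0.01)
        # the weight exponent is weakly identified at n=20, so optimizer
        # tolerance shows up more strongly there
        assert m1.beta_wt_v_ == pytest.approx(m2.beta_wt_v_, abs=0.1)

    def test_needs_distinct_weights_for_allometric_exponent(self):
        theta = GroundTruthParameters()
        cov = pd.DataFrame(
            {
                "id": [1, 2], "sex": ["female"] * 2, "age": [30.0, 40.0],
                "weight": [70.0, 70.0], "height": [160.0, 165.0],
            }
        )
        from pkgan.popsim import simulate_observations, to_nonmem, censor_blq

        obs = censor_blq(simulate_observations(theta, cov, seed=0), 0.5, "drop")
        long_df = to_nonmem(cov, obs, 300.0)
        with pytest.raises(ValueError, match="distinct weights"):
            NlmePkModel(n_starts=1).fit(long_df)

    def test_fitted_attributes_follow_sklearn_convention(self, study):
        m = fit(study["long"], n_starts=1, random_state=0)
        assert m.converged_
        assert m.n_subjects_ == 20
        assert m.eta_modes_.shape == (20, 3)
        assert set(m.to_dict()) >= {"ka_pop", "cl_pop", "loglik", "converged"}


class TestMixes:
    @pytest.fixture(scope="class")
    def artificial_long(self, study):
        # clone the original subjects as stand-in artificial patients
        art = study["long"].copy()
        art["ID"] = art["ID"] + 1000
        art["SRC"] = "artificial"
        return pd.concat([art, art.assign(ID=art["ID"] + 1000), art.assign(ID=art["ID"] + 2000)])

    def test_mix_compositions_follow_study_design(self, study, artificial_long):
        mixes = build_mixes(study["long"], artificial_long)
        sizes = {name: df.loc[df["EVID"] == 1, "ID"].nunique() for name, df in mixes.items()}
        assert sizes == {
            "original": 20, "artificial": 60, "combined-low": 30,
            "combined-equal": 40, "combined-high": 60,
        }
        for name, df in mixes.items():
            mix = next(m for m in TABLE_MIXES if m.name == name)
            srcs = df.groupby("ID")["SRC"].first().value_counts().to_dict()
            assert srcs.get("original", 0) == mix.n_original
            assert srcs.get("artificial", 0) == mix.n_artificial

    def test_original_mix_preserves_input_data(self, study, artificial_long):
        mixes = build_mixes(study["long"], artificial_long)
        orig = mixes["original"]
        assert orig.loc[orig["EVID"] == 0, "DV"].sum() == pytest.approx(
            study["long"].loc[study["long"]["EVID"] == 0, "DV"].sum()
        )

    def test_all_mixes_share_the_same_original_subjects(self, study, artificial_long):
        mixes = build_mixes(study["long"], artificial_long)
        ref = mixes["original"].loc[mixes["original"]["EVID"] == 0, "DV"].sum()
        for name in ("combined-low", "combined-equal", "combined-high"):
            df = mixes[name]
            orig_ids = df.groupby("ID")["SRC"].first()
            orig_ids = orig_ids[orig_ids == "original"].index
            got = df[(df["EVID"] == 0) & df["ID"].isin(orig_ids)]["DV"].sum()
            assert got == pytest.approx(ref)

    def test_shortfall_rejected(self, study):
        with pytest.raises(ValueError, match="needs"):
            build_mixes(study["long"], study["long"].head(0))


class TestBootstrap:
    def test_cloned_subjects_give_degenerate_intervals(self):
        # every subject identical -> any resample yields the same weighted
        # likelihood up to scale, hence identical estimates
        theta = GroundTruthParameters(omega_ka=0.0, omega_v=0.0, omega_cl=0.0)
        cov1 = pd.DataFrame(
            {"id": [1], "sex": ["female"], "age": [40.0], "weight": [70.0], "height": [165.0]}
        )
        from pkgan.popsim import simulate_observations, to_nonmem

        obs1 = simulate_observations(theta, cov1, seed=0)
        frames_cov, frames_obs = [], []
        for rep in range(6):
            frames_cov.append(cov1.assign(id=rep + 1))
            frames_obs.append(obs1.assign(id=rep + 1))
        long_df = to_nonmem(pd.concat(frames_cov), pd.concat(frames_obs), 300.0)
        spec = StructuralModelSpec(
            fixed={"omega_ka": 0.01, "omega_v": 0.01, "omega_cl": 0.01, "beta_wt_v": 0.0}
        )
        m = NlmePkModel(spec=spec, n_starts=3, random_state=0).fit(long_df)
        bs = bootstrap(long_df, spec=spec, n_replicates=8, seed=1, fitted=m)
        width = bs.summary.loc["cl_pop", "hi"] - bs.summary.loc["cl_pop", "lo"]
        assert width == pytest.approx(0.0, abs=1e-4)

    def test_replicate_count_echoed_and_summary_ordered(self, study):
        m = NlmePkModel(n_starts=1, random_state=0).fit(study["long"])
        bs = bootstrap(study["long"], n_replicates=20, seed=2, fitted=m)
        assert bs.n_replicates == 20
        assert len(bs.replicates) + bs.n_failed == 20
        assert (bs.summary["lo"] <= bs.summary["median"]).all()
        assert (bs.summary["median"] <= bs.summary["hi"]).all()


class TestVpc:
    def test_bands_collapse_without_variability(self):
        theta = GroundTruthParameters(a=0.0, b=0.0, omega_ka=0.0, omega_v=0.0, omega_cl=0.0)
        _, _, long_df = simulate_dataset(theta, PopulationSpec(n_female=3, n_male=0), seed=6, blq="keep")
        params = {**TRUTH, "a": 1e-9, "b": 0.0, "omega_ka": 1e-9, "omega_v": 1e-9, "omega_cl": 1e-9}
        table = vpc(params, long_df, n_sim=50, seed=0)
        assert np.allclose(table["sim_lo"], table["sim_hi"], rtol=1e-4, atol=1e-6)

    def test_self_simulated_data_covered_by_bands(self):
        # data simulated under the evaluated parameters must sit inside the
        # simulation bands at nearly all time/percentile combinations
        theta = GroundTruthParameters()
        _, _, long_df = simulate_dataset(theta, seed=11, blq="keep")
        spec = StructuralModelSpec(blq="keep")
        table = vpc(TRUTH, long_df, n_sim=200, seed=3, spec=spec)
        inside = (
            (table["observed"] >= table["sim_lo"]) & (table["observed"] <= table["sim_hi"])
        )
        assert inside.mean() >= 0.9
        assert set(table["percentile"]) == {10, 50, 90}
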