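import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from plggvol.growth import (
    CohortGrowthModel,
    GrowthParams,
    TumorGrowthModel,
    compare_responders,
    model_volume,
    time_of_minimum,
)
from plggvol.measurements import Measure
from plggvol.simulate import simulate_trajectory
from tests.conftest import make_series


def ode_volume(t, p, rtol=1e-10):
    """Independent oracle: adaptive Runge-Kutta integration of the growth ODE."""
    sol = solve_ivp(
        lambda tt, v: (p.lam - p.gamma0 * math.exp(-p.eps * tt)) * v,
        (0.0, t),
        [p.V_b],
        rtol=rtol,
        atol=1e-12,
        dense_output=True,
    )
    return float(sol.y[0, -1])


class TestModelVolume:
    def test_no_treatment_limit(self):
        p = GrowthParams(lam=0.005, gamma0=0.0, eps=0.01, V_b=10.0)
        for t in (0.0, 50.0, 300.0):
            assert model_volume(t, p) == pytest.approx(10.0 * math.exp(0.005 * t))

    def test_baseline_value(self):
        p = GrowthParams(lam=0.004, gamma0=0.02, eps=0.01, V_b=7.7)
        assert model_volume(0.0, p) == 7.7

    def test_matches_ode_oracle_reference_point(self):
        p = GrowthParams(lam=0.004, gamma0=0.02, eps=0.01, V_b=10.0)
        assert model_volume(100.0, p) == pytest.approx(
            ode_volume(100.0, p), rel=1e-8
        )

    def test_eps_zero_limit(self):
        p = GrowthParams(lam=0.004, gamma0=0.002, eps=1e-15, V_b=10.0)
        assert model_volume(200.0, p) == pytest.approx(
            10.0 * math.exp((0.004 - 0.002) * 200.0), rel=1e-9
        )

    def test_vectorized_and_positive(self):
        p = GrowthParams(lam=0.003, gamma0=0.03, eps=0.005, V_b=5.0)
        t = np.linspace(0, 700, 64)
        v = model_volume(t, p)
        assert v.shape == t.shape
        assert np.all(v > 0)


class TestTimeOfMinimum:
    def test_closed_form_example(self):
        p = GrowthParams(lam=0.01, gamma0=0.04, eps=0.01, V_b=10.0)
        assert time_of_minimum(p) == pytest.approx(math.log(4.0) / 0.01)

    def test_no_shrinkage_phase(self):
        p = GrowthParams(lam=0.01, gamma0=0.01, eps=0.01, V_b=10.0)
        assert time_of_minimum(p) == 0.0

    def test_monotone_decrease_sentinel(self):
        p = GrowthParams(lam=0.0, gamma0=0.02, eps=0.01, V_b=10.0)
        assert time_of_minimum(p) == math.inf

    def test_is_global_minimum_on_grid(self):
        rng = np.random.default_rng(2)
        grid = np.linspace(0.0, 1000.0, 4001)
        for _ in range(50):
            p = GrowthParams(
                lam=rng.uniform(1e-4, 0.01),
                gamma0=rng.uniform(0.0, 0.05),
                eps=rng.uniform(1e-3, 0.05),
                V_b=rng.uniform(1.0, 50.0),
            )
            tv = time_of_minimum(p)
            if not math.isfinite(tv):
                continue
            v_min = model_volume(min(tv, grid[-1]), p)
            assert v_min <= np.min(model_volume(grid, p)) * (1 + 1e-12)

    def test_net_growth_rate_crosses_zero_at_tvmin(self):
        p = GrowthParams(lam=0.002, gamma0=0.02, eps=0.008, V_b=10.0)
        tv = time_of_minimum(p)
        rate = lambda t: p.lam - p.gamma0 * math.exp(-p.eps * t)
        assert rate(tv) == pytest.approx(0.0, abs=1e-15)
        assert rate(tv - 10) < 0 < rate(tv + 10)


class TestLogPosterior:
    def _model(self, p, noise_cv=0.05, seed=0, **kw):
        s = simulate_trajectory(p, cadence=61, horizon=610, noise_cv=0.0,
                                seed=seed)
        return TumorGrowthModel(s, noise_cv=noise_cv, **kw)

    def _theta(self, p):
        return np.array([math.log(p.lam), p.gamma0, math.log(p.eps),
                         math.log(p.V_b)])

    def test_noiseless_data_maximized_at_truth(self, dip_regrow_params):
        p = dip_regrow_params
        m = self._model(p, noise_cv=0.01)
        lp0 = m.log_posterior(self._theta(p))
        rng = np.random.default_rng(0)
        for _ in range(30):
            q = GrowthParams(
                lam=p.lam * rng.uniform(0.7, 1.4),
                gamma0=p.gamma0 * rng.uniform(0.7, 1.4),
                eps=p.eps * rng.uniform(0.7, 1.4),
                V_b=p.V_b * rng.uniform(0.9, 1.1),
            )
            assert m.log_posterior(self._theta(q)) <= lp0 + 1e-9

    def test_scale_equivariance(self, dip_regrow_params):
        """Doubling all volumes and V_b leaves the likelihood unchanged."""
        p = dip_regrow_params
        m1 = self._model(p)
        p2 = GrowthParams(p.lam, p.gamma0, p.eps, 2 * p.V_b)
        m2 = TumorGrowthModel(
            make_series(
                [2 * v for v in m1.v], times=list(m1.t), pid="P2"
            ),
            noise_cv=0.05,
        )
        assert m2.log_likelihood(self._theta(p2)) == pytest.approx(
            m1.log_likelihood(self._theta(p)), rel=1e-12
        )

    def test_stationary_at_noiseless_optimum(self, dip_regrow_params):
        """Central-difference gradient vanishes at the noiseless optimum
        for the likelihood part (the V_b prior adds no slope at its centre)."""
        p = dip_regrow_params
        m = self._model(p, noise_cv=0.05)
        th = self._theta(p)
        h = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            g = (m.log_likelihood(th + e) - m.log_likelihood(th - e)) / (2 * h)
            assert abs(g) < 1e-4

    def test_rejects_nonpositive_volume(self):
        import warnings

        from plggvol.measurements import LesionMeasurement, TimePoint
        from plggvol.measurements import ParticipantSeries

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tps = [
                TimePoint("P1", t, lesions=(
                    LesionMeasurement("L1", base_volume=v, intratumoral_cyst_volume=c),
                ))
                for t, v, c in [(0.0, 10.0, 0.0), (61.0, 5.0, 5.0)]
            ]
        s = ParticipantSeries("P1", tps)  # second image has zero solid volume
        with pytest.raises(ValueError, match="non-positive"):
            TumorGrowthModel(s)


class TestFitting:
    def test_seed_determinism(self, dip_regrow_params):
        s = simulate_trajectory(dip_regrow_params, noise_cv=0.05, seed=4)
        m = TumorGrowthModel(s, noise_cv=0.05)
        r1 = m.fit(n_walkers=12, n_steps=200, seed=3)
        r2 = m.fit(n_walkers=12, n_steps=200, seed=3)
        assert np.array_equal(r1.params, r2.params)
        assert np.array_equal(r1.t_vmin_samples, r2.t_vmin_samples)

    def test_prior_only_fit_recovers_prior_quantiles(self, dip_regrow_params):
        s = simulate_trajectory(dip_regrow_params, noise_cv=0.05, seed=4)
        m = TumorGrowthModel(s)
        r = m.fit(n_walkers=24, n_steps=1500, seed=8, prior_only=True)
        gamma0 = r.params[:, 1]
        # uniform prior on [0, 0.2]: median 0.1, quartiles 0.05 / 0.15
        assert np.median(gamma0) == pytest.approx(0.1, abs=0.02)
        assert np.percentile(gamma0, 25) == pytest.approx(0.05, abs=0.02)
        log_eps = np.log(r.params[:, 2])
        # log-uniform prior on [1e-4, 0.1]: median at the geometric midpoint
        assert np.median(log_eps) == pytest.approx(
            (math.log(1e-4) + math.log(0.1)) / 2, abs=0.35
        )

    def test_parameter_recovery_free_lambda(self, dip_regrow_params):
        p = dip_regrow_params
        s = simulate_trajectory(p, cadence=61, horizon=610, noise_cv=0.05,
                                seed=42)
        r = TumorGrowthModel(s, noise_cv=0.05).fit(
            n_walkers=16, n_steps=900, seed=7
        )
        mp = r.median_params()
        assert mp.gamma0 == pytest.approx(p.gamma0, rel=0.30)
        assert mp.eps == pytest.approx(p.eps, rel=0.30)

    def test_bootstrap_pooling_and_spread(self, dip_regrow_params):
        s = simulate_trajectory(dip_regrow_params, noise_cv=0.05, seed=5)
        m = TumorGrowthModel(s, noise_cv=0.10)
        single = m.fit(n_walkers=12, n_steps=400, seed=2)
        pooled = m.fit_bootstrap(n_boot=5, n_walkers=12, n_steps=400, seed=2)
        assert len(pooled.params) == 5 * len(single.params)
        # degenerate bootstrap (no perturbation) stays close to the single fit
        degen = m.fit_bootstrap(n_boot=3, noise_cv=0.0, n_walkers=12,
                                n_steps=400, seed=2)
        assert np.median(degen.t_vmin_samples) == pytest.approx(
            np.median(single.t_vmin_samples), rel=0.15
        )
        # measurement-noise bootstrap cannot shrink the t_Vmin spread
        assert np.std(pooled.t_vmin_samples) > 0.7 * np.std(
            single.t_vmin_samples
        )

    def test_fixed_lambda_mode(self, dip_regrow_params):
        s = simulate_trajectory(dip_regrow_params, noise_cv=0.05, seed=6)
        m = TumorGrowthModel(s, noise_cv=0.05, fix_lam=dip_regrow_params.lam)
        r = m.fit(n_walkers=12, n_steps=400, seed=1)
        assert np.all(r.params[:, 0] == dip_regrow_params.lam)

    def test_summary_table(self, dip_regrow_params):
        s = simulate_trajectory(dip_regrow_params, noise_cv=0.05, seed=4)
        r = TumorGrowthModel(s).fit(n_walkers=12, n_steps=200, seed=0)
        df = r.summary()
        assert set(df.index) == {"lam", "gamma0", "eps", "V_b", "t_vmin"}
        assert (df["q2.5"] <= df["median"]).all()
        assert (df["median"] <= df["q97.5"]).all()


class TestClassification:
    def _fit(self, volumes, times=None, noise_cv=0.10, seed=0):
        s = make_series(volumes, times=times)
        m = TumorGrowthModel(s, noise_cv=noise_cv)
        return m.fit(n_walkers=12, n_steps=400, seed=seed)

    def test_eval_past_minimum_is_pd(self):
        # deep dip with regrowth: posterior t_Vmin well under 400 d
        vols = [20.0, 12.0, 8.0, 7.0, 9.0, 14.0, 22.0]
        r = self._fit(vols)
        cls = r.classify(t_eval=400.0)
        assert cls.label == "PD"
        assert cls.t_vmin_q75 < 400.0

    def test_flat_series_is_sd(self):
        vols = [20.0, 20.5, 19.4, 20.2, 19.9, 20.8]
        r = self._fit(vols)
        t_eval = 183.0
        if t_eval <= r.t_vmin_percentile(75):
            assert r.classify(t_eval).label == "SD"

    def test_shrinking_series_is_pr(self):
        vols = [20.0, 16.0, 12.5, 10.0, 8.0, 6.5, 5.2, 4.4, 3.8]
        r = self._fit(vols)
        cls = r.classify(t_eval=244.0)
        if cls.t_vmin_q75 >= 244.0:
            assert cls.label == "PR"

    def test_scale_invariance(self):
        vols = [20.0, 16.0, 12.5, 10.0, 8.0, 6.5, 5.2, 4.4]
        r1 = self._fit(vols, seed=3)
        r2 = self._fit([v * 3.0 for v in vols], seed=3)
        for t_eval in (122.0, 305.0):
            assert r1.classify(t_eval).label == r2.classify(t_eval).label


class TestCohortModel:
    def test_shared_lambda_joint_fit(self, dip_regrow_params):
        p = dip_regrow_params
        series = [
            simulate_trajectory(p, noise_cv=0.05, seed=s, participant_id=f"P{s}")
            for s in range(3)
        ]
        cm = CohortGrowthModel(series, noise_cv=0.05)
        res = cm.fit(n_steps=600, seed=11)
        assert res.lam_median == pytest.approx(p.lam, rel=0.5)
        sub = res.participant_results(0)
        assert sub.params.shape[1] == 4
        # participant draws carry the shared growth rate
        assert np.array_equal(sub.params[:, 0], res.lam_samples)


class TestCompareResponders:
    def _fits(self, eps_values, seed=0):
        fits = []
        for i, eps in enumerate(eps_values):
            p = GrowthParams(lam=0.002, gamma0=0.015, eps=eps, V_b=20.0)
            s = simulate_trajectory(p, noise_cv=0.05, seed=seed + i,
                                    participant_id=f"P{i}")
            fits.append(
                TumorGrowthModel(s, noise_cv=0.05, fix_lam=0.002).fit(
                    n_walkers=12, n_steps=400, seed=seed + i
                )
            )
        return fits

    def test_three_fold_eps_separation_detected(self):
        # responders: slow resistance (t_Vmin >> 1 y); resistant: fast onset
        fits = self._fits([0.0015] * 6 + [0.012] * 6, seed=50)
        out = compare_responders(fits, cutoff=365.0)
        assert out.loc["eps", "n_responding"] >= 4
        assert out.loc["eps", "n_resistant"] >= 4
        assert out.loc["eps", "p_value"] < 0.05
        assert out.loc["lam", "p_value"] == 1.0  # identical by construction

    def test_single_group_skips_tests(self):
        fits = self._fits([0.0015] * 3, seed=80)
        out = compare_responders(fits, cutoff=-math.inf)
        assert out["n_resistant"].iloc[0] == 0
        assert math.isnan(out.loc["eps", "p_value"])
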