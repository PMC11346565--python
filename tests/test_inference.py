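import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatadapt.inference import (
    Priors,
    fit_hier_linear,
    fit_timecourse,
    pd_from_interval,
    split_rhat,
    summarize_posterior,
)


class TestSummarizePosterior:
    def test_degenerate_point_mass(self):
        s = summarize_posterior(np.full(2000, 3.5))
        assert (s.mean, s.ci_low, s.ci_high, s.pd) == (3.5, 3.5, 3.5, 100.0)

    def test_standard_normal_quantiles(self):
        d = np.random.default_rng(0).standard_normal(1_000_000)
        s = summarize_posterior(d)
        assert s.ci_low == pytest.approx(-1.645, abs=0.01)
        assert s.ci_high == pytest.approx(1.645, abs=0.01)
        assert s.pd == pytest.approx(50.0, abs=0.5)

    def test_shifted_normal_pd(self):
        # Normal(-0.22, 0.158^2): Pd = Phi(0.22/0.158) ~ 92%
        d = np.random.default_rng(1).normal(-0.22, 0.158, 1_000_000)
        s = summarize_posterior(d)
        assert s.pd == pytest.approx(100 * stats.norm.cdf(0.22 / 0.158), abs=0.3)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            summarize_posterior(np.ones(100))

    def test_level_monotonicity(self):
        d = np.random.default_rng(2).normal(1.0, 2.0, 50_000)
        s90 = summarize_posterior(d, level=0.90)
        s95 = summarize_posterior(d, level=0.95)
        assert s95.ci_low < s90.ci_low and s95.ci_high > s90.ci_high


class TestPdFromInterval:
    @pytest.mark.parametrize(
        "mean,lo,hi,expected",
        [
            (-0.22, -0.48, 0.04, 92),  # rise in core temperature
            (-0.2, -0.5, 0.1, 86),  # exercising mean skin temperature
            (-0.01, -0.02, -0.00, 95),  # sweating sensitivity
        ],
    )
    def test_published_summary_triples(self, mean, lo, hi, expected):
        assert round(pd_from_interval(mean, lo, hi)) == expected

    def test_degenerate_interval(self):
        with pytest.raises(ValueError):
            pd_from_interval(0.0, 1.0, 1.0)

    def test_agrees_with_draw_based_pd_on_normal_posterior(self):
        rng = np.random.default_rng(3)
        for mean, sd in [(-0.22, 0.158), (0.5, 1.0), (1.2, 1.0)]:
            d = rng.normal(mean, sd, 400_000)
            s = summarize_posterior(d)
            analytic = pd_from_interval(s.mean, s.ci_low, s.ci_high)
            assert abs(analytic - s.pd) < 1.0


def _toy_table(effect=-7.0, sigma=0.5, tau=1.0, n=3, seed=3):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        u = rng.normal(0, tau)
        for period in ("pre", "post"):
            rows.append(
                dict(
                    participant=f"P{i}",
                    period=period,
                    value=37.0 + (effect if period == "post" else 0.0) + u + rng.normal(0, sigma),
                )
            )
    return pd.DataFrame(rows)


class TestHierLinear:
    def test_near_noiseless_recovery(self):
        tab = _toy_table(effect=-7.0, sigma=1e-3, tau=0.0, n=15, seed=0)
        fit = fit_hier_linear(tab, chains=2, draws=1500, warmup=500, seed=1,
                              compute_diagnostics=False)
        assert fit.draws["period_effect"].mean() == pytest.approx(-7.0, abs=0.02)

    def test_row_order_invariance(self):
        tab = _toy_table(n=10)
        fit_a = fit_hier_linear(tab, chains=2, draws=500, warmup=200, seed=5,
                                compute_diagnostics=False)
        fit_b = fit_hier_linear(tab.sample(frac=1, random_state=42), chains=2, draws=500,
                                warmup=200, seed=5, compute_diagnostics=False)
        np.testing.assert_array_equal(
            fit_a.draws["period_effect"], fit_b.draws["period_effect"]
        )

    def test_single_period_not_identifiable(self):
        tab = _toy_table(n=5)
        with pytest.raises(ValueError):
            fit_hier_linear(tab[tab["period"] == "pre"])

    def test_matches_grid_posterior_oracle(self):
        """Gibbs posterior mean of the period effect equals a brute-force
        grid posterior (participant effects and coefficients marginalized
        analytically, scales integrated numerically) within 1%."""
        tab = _toy_table(n=3, seed=3)
        df = tab.sort_values(["participant", "period"], kind="mergesort").reset_index(drop=True)
        y = df["value"].to_numpy()
        post = (df["period"] == "post").to_numpy(float)
        X = np.column_stack([np.ones(6), post])
        pid, _ = pd.factorize(df["participant"], sort=True)
        Z = np.zeros((6, 3))
        Z[np.arange(6), pid] = 1.0
        pr = Priors.from_data(y, None)
        S0 = np.diag([pr.intercept_sd**2, pr.period_sd**2])

        taus = np.linspace(0.005, 40.0, 200)
        sigs = np.linspace(0.02, 25.0, 200)
        lps, ebs = [], []
        for tau in taus:
            for sig in sigs:
                V = sig**2 * np.eye(6) + tau**2 * (Z @ Z.T)
                M = V + X @ S0 @ X.T
                _, logdet = np.linalg.slogdet(M)
                Minv_y = np.linalg.solve(M, y)
                lps.append(
                    -0.5 * logdet
                    - 0.5 * y @ Minv_y
                    - tau**2 / (2 * pr.tau_scale**2)
                    - sig**2 / (2 * pr.sigma_scale**2)
                )
                ebs.append((S0 @ X.T @ Minv_y)[1])
        lps = np.asarray(lps)
        w = np.exp(lps - lps.max())
        oracle = float(np.sum(w * np.asarray(ebs)) / w.sum())

        fit = fit_hier_linear(tab, chains=4, draws=5000, warmup=1000, seed=9,
                              compute_diagnostics=False)
        gibbs = float(fit.draws["period_effect"].mean())
        assert abs(gibbs - oracle) < 0.01 * abs(oracle)

    def test_covariate_enters_centered(self):
        tab = _toy_table(n=10, seed=7)
        tab["vo2peak"] = np.repeat(np.random.default_rng(0).normal(60, 7, 10), 2)
        fit = fit_hier_linear(tab, chains=2, draws=1000, warmup=300, seed=2,
                              compute_diagnostics=False)
        assert "covariate_effect" in fit.draws

    def test_diagnostics_reported(self):
        tab = _toy_table(n=10, seed=8)
        fit = fit_hier_linear(tab, chains=4, draws=2500, warmup=500, seed=3)
        s = fit.summary("period_effect")
        assert s.rhat is not None and s.rhat < 1.05
        assert s.ess is not None and s.ess > 200


def test_split_rhat_detects_disagreeing_chains():
    rng = np.random.default_rng(0)
    good = rng.standard_normal((4, 1000))
    bad = good + np.array([[0.0], [0.0], [5.0], [5.0]])
    assert split_rhat(good) < 1.01
    assert split_rhat(bad) > 1.5


def _timecourse_table(curve, n_participants=8, sigma=0.1, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    times = np.arange(0.0, 46.0, 5.0)
    for i in range(n_participants):
        u = rng.normal(0, 0.2)
        for period in ("pre", "post"):
            for t in times:
                mu = curve(t) + (shift if period == "post" else 0.0)
                rows.append(
                    dict(participant=f"P{i}", period=period, time=t,
                         value=mu + u + rng.normal(0, sigma))
                )
    return pd.DataFrame(rows)


class TestTimecourse:
    def test_quadratic_recovery(self):
        curve = lambda t: 37.3 + 0.002 * t**2
        tab = _timecourse_table(curve, sigma=0.1, seed=1)
        fit = fit_timecourse(tab, seed=2)
        truth = curve(fit.grid)
        post_sd = (fit.pre_high - fit.pre_low) / (2 * 1.645)
        assert np.all(np.abs(fit.pre_mean - truth) < 2.0 * post_sd + 0.05)

    def test_identical_periods_contrast_covers_zero(self):
        tab = _timecourse_table(lambda t: 37.5 + 0.01 * t, shift=0.0, seed=3)
        fit = fit_timecourse(tab, seed=4)
        assert np.all(fit.contrast_low <= 0.0) and np.all(fit.contrast_high >= 0.0)

    def test_constant_data_flat_fit(self):
        tab = _timecourse_table(lambda t: 37.0, sigma=0.02, seed=5)
        fit = fit_timecourse(tab, seed=6)
        slope = np.diff(fit.pre_mean) / np.diff(fit.grid)
        assert np.all(np.abs(slope) < 0.01)

    def test_detects_period_shift(self):
        tab = _timecourse_table(lambda t: 37.3 + 0.02 * t, shift=-0.3, sigma=0.05, seed=7)
        fit = fit_timecourse(tab, seed=8)
        assert fit.contrast_mean.mean() == pytest.approx(-0.3, abs=0.1)

    def test_basis_larger_than_support_rejected(self):
        tab = _timecourse_table(lambda t: 37.0, seed=9)
        with pytest.raises(ValueError):
            fit_timecourse(tab, n_basis=30)

    def test_too_few_time_points_rejected(self):
        tab = _timecourse_table(lambda t: 37.0, seed=10)
        tab = tab[tab["time"].isin([0.0, 5.0, 10.0])]
        with pytest.raises(ValueError):
            fit_timecourse(tab)
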