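"""The variance-slope statistic: windows, V(L), Gamma fits, Fourier map."""

import numpy as np
import pytest
from scipy import stats

import varslope as vs


def brute_force_loglog_ols(sizes, V):
    """Independent OLS in log10-log10 space (oracle for fit_gamma)."""
    sizes = np.asarray(sizes, float)
    V = np.asarray(V, float)
    x, y = np.log10(sizes), np.log10(V)
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return slope


class TestWindowScheme:
    def test_defaults(self, scheme):
        assert len(scheme.sizes) == 11
        assert scheme.sizes[0] == 3 and scheme.sizes[-1] == 500
        assert all(b > a for a, b in zip(scheme.sizes, scheme.sizes[1:]))

    def test_endpoints_only(self):
        assert vs.make_window_scheme(3, 4, 2).sizes == (3, 4)

    def test_log_spacing_ratio(self):
        raw = np.geomspace(3, 500, 11)
        ratios = raw[1:] / raw[:-1]
        assert np.allclose(ratios, (500 / 3) ** 0.1)

    def test_infeasible(self):
        with pytest.raises(vs.ConfigurationError):
            vs.make_window_scheme(3, 5, 10)


class TestScaleVariance:
    def test_ramp_closed_form(self, scheme):
        """Population variance of a unit ramp block of w is (w^2 - 1) / 12."""
        x = np.arange(500.0)
        curve = vs.scale_variance(x, scheme, variance_ddof=0)
        expected = (np.array(scheme.sizes, float) ** 2 - 1.0) / 12.0
        np.testing.assert_allclose(curve.V, expected, rtol=1e-12)

    def test_constant_series_zero_curve(self, scheme):
        curve = vs.scale_variance(np.full(500, 2.5), scheme)
        assert (curve.V == 0).all()
        res = vs.fit_gamma(curve)
        assert not res.valid and "usable" in res.reason

    def test_alternating_series(self, scheme):
        """+1/-1 alternation: V(3) = 8/9 (population), V(even w) = 1."""
        x = np.tile([1.0, -1.0], 250)
        curve = vs.scale_variance(x, scheme, variance_ddof=0)
        sizes = np.array(scheme.sizes)
        assert curve.V[sizes == 3][0] == pytest.approx(8.0 / 9.0, rel=1e-12)
        even = sizes % 2 == 0
        np.testing.assert_allclose(curve.V[even], 1.0, rtol=1e-12)

    def test_block_accounting(self, scheme):
        curve = vs.scale_variance(np.random.default_rng(0).normal(size=500), scheme)
        np.testing.assert_array_equal(curve.n_blocks_used, 500 // np.array(scheme.sizes))

    def test_all_missing_raises(self, scheme):
        with pytest.raises(vs.ProcessingError):
            vs.scale_variance(np.full(500, np.nan), scheme)


class TestFitGamma:
    def test_exact_square_law(self, scheme):
        sizes = np.array(scheme.sizes, float)
        curve = vs.ScaleVarianceCurve(sizes.astype(int), sizes**2, np.ones(11, int))
        res = vs.fit_gamma(curve)
        assert res.gamma == pytest.approx(2.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_flat_curve_zero(self, scheme):
        sizes = np.array(scheme.sizes)
        curve = vs.ScaleVarianceCurve(sizes, np.full(11, 7.0), np.ones(11, int))
        assert vs.fit_gamma(curve).gamma == pytest.approx(0.0, abs=1e-12)

    def test_ramp_oracle(self, scheme):
        """Pipeline Gamma on the unit ramp equals brute-force OLS over the
        closed-form V(w) = (w^2 - 1)/12 points."""
        res = vs.leg_gamma(np.arange(500.0), scheme, variance_ddof=0)
        sizes = np.array(scheme.sizes, float)
        expected = brute_force_loglog_ols(sizes, (sizes**2 - 1.0) / 12.0)
        assert res.gamma == pytest.approx(expected, abs=1e-12)
        assert expected > 2.0  # slightly above 2: the -1/12 term bends small scales

    def test_too_few_scales_invalid(self):
        curve = vs.ScaleVarianceCurve(
            np.array([3, 5, 8]), np.array([np.nan, 4.0, np.nan]), np.array([1, 1, 1])
        )
        res = vs.fit_gamma(curve)
        assert not res.valid and np.isnan(res.gamma)


class TestLegGamma:
    def test_affine_invariance(self, scheme):
        rng = np.random.default_rng(5)
        for _ in range(10):
            cfg = vs.SyntheticTransectConfig(
                beta=rng.uniform(1, 3), n_samples=500,
                gap_fraction=0.1, seed=int(rng.integers(1 << 30)),
            )
            x = vs.gen_powerlaw_series(cfg)
            g0 = vs.leg_gamma(x, scheme).gamma
            for a, b in [(2.0, 0.0), (-1.5, 3.0), (0.01, -7.0)]:
                assert vs.leg_gamma(a * x + b, scheme).gamma == pytest.approx(g0, abs=1e-10)

    def test_white_noise_null(self, scheme):
        """i.i.d. legs have mean Gamma indistinguishable from 0."""
        rng = np.random.default_rng(11)
        g = np.array([vs.leg_gamma(rng.standard_normal(500), scheme).gamma
                      for _ in range(200)])
        assert abs(g.mean()) < 0.05

    def test_monotone_in_beta(self, scheme):
        means = []
        for beta in (1.0, 1.5, 2.0, 2.5, 3.0):
            g = [
                vs.leg_gamma(vs.gen_powerlaw_series(
                    vs.SyntheticTransectConfig(beta=beta, n_samples=500, seed=s)
                ), scheme).gamma
                for s in range(40)
            ]
            means.append(np.mean(g))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_gap_tolerance(self, scheme):
        """Median Gamma shift under 15% gaps stays within 0.1; 20% never fails."""
        import varslope.synthetic as syn

        for frac in (0.15, 0.20):
            deltas = []
            for seed in range(40):
                cfg = vs.SyntheticTransectConfig(beta=5 / 3, n_samples=500, seed=seed)
                x = vs.gen_powerlaw_series(cfg)
                g0 = vs.leg_gamma(x, scheme).gamma
                gap_cfg = vs.SyntheticTransectConfig(
                    beta=5 / 3, n_samples=500, seed=seed,
                    gap_fraction=frac, gap_pattern="random_blocks",
                )
                xg = syn._inject_gaps(x, gap_cfg, np.random.default_rng(900 + seed))
                res = vs.leg_gamma(xg, scheme)
                assert res.valid
                deltas.append(abs(res.gamma - g0))
            if frac <= 0.15:
                assert np.median(deltas) <= 0.1

    def test_log_transform_near_invariance(self, scheme):
        """Gamma of a chl-like lognormal field barely moves under log."""
        diffs = []
        for seed in range(60):
            cfg = vs.SyntheticTransectConfig(
                beta=5 / 3, n_samples=500, marginal="lognormal",
                mean_level=0.5, amplitude=0.2, seed=seed,
            )
            x = vs.gen_powerlaw_series(cfg)
            diffs.append(abs(vs.leg_gamma(x, scheme).gamma
                             - vs.leg_gamma(np.log(x), scheme).gamma))
        assert np.mean(diffs) < 0.05


class TestFourierSlope:
    def test_white_noise_flat(self, scheme):
        rng = np.random.default_rng(2)
        slopes = [vs.fourier_slope(rng.standard_normal(500)) for _ in range(100)]
        assert abs(np.mean(slopes)) < 0.1

    def test_red_spectrum_target(self, scheme):
        slopes = [
            vs.fourier_slope(vs.gen_powerlaw_series(
                vs.SyntheticTransectConfig(beta=2.0, n_samples=500, seed=s)))
            for s in range(60)
        ]
        assert np.mean(slopes) == pytest.approx(-2.0, abs=0.1)

    def test_gapped_input_rejected(self):
        x = np.random.default_rng(0).standard_normal(500)
        x[10] = np.nan
        with pytest.raises(vs.ProcessingError):
            vs.fourier_slope(x)

    def test_gamma_fourier_correlation(self, scheme):
        """Per-leg Gamma tracks the per-leg periodogram slope closely."""
        rng = np.random.default_rng(21)
        gs, ss = [], []
        for _ in range(100):
            cfg = vs.SyntheticTransectConfig(
                beta=rng.uniform(1, 3), n_samples=500, seed=int(rng.integers(1 << 30))
            )
            x = vs.gen_powerlaw_series(cfg)
            gs.append(vs.leg_gamma(x, scheme).gamma)
            ss.append(vs.fourier_slope(x))
        assert abs(stats.pearsonr(gs, ss)[0]) > 0.9


class TestGammaSlopeMap:
    def test_exact_linear_input(self):
        slopes = np.linspace(-3, -1, 30)
        gammas = slopes + 2.0
        m = vs.gamma_slope_map(gammas, slopes)
        assert m.predict(-1.0) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_spread(self):
        with pytest.raises(vs.ProcessingError):
            vs.gamma_slope_map(np.linspace(0, 1, 30), np.full(30, -2.0))

    def test_too_few_pairs(self):
        with pytest.raises(vs.ConfigurationError):
            vs.gamma_slope_map([1.0] * 5, [-2.0] * 5)

    def test_interpolation_consistency(self):
        """Prediction inside the fitted range stays within the ensemble spread
        of the Gammas whose slopes are nearest the query."""
        rng = np.random.default_rng(31)
        gs, ss = [], []
        for _ in range(150):
            beta = rng.uniform(1, 3)
            x = vs.gen_powerlaw_series(
                vs.SyntheticTransectConfig(beta=beta, n_samples=500,
                                           seed=int(rng.integers(1 << 30))))
            gs.append(vs.leg_gamma(x).gamma)
            ss.append(vs.fourier_slope(x))
        gs, ss = np.array(gs), np.array(ss)
        m = vs.gamma_slope_map(gs, ss)
        query = -2.0
        near = np.argsort(np.abs(ss - query))[:20]
        spread = gs[near].std()
        assert abs(m.predict(query) - gs[near].mean()) < 2 * spread


class TestPropertyBased:
    """Randomized invariants (derandomized hypothesis search)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_affine_invariance_property(self, a, b, seed):
        x = vs.gen_powerlaw_series(
            vs.SyntheticTransectConfig(beta=1.8, n_samples=500, seed=seed))
        assert vs.leg_gamma(a * x + b).gamma == pytest.approx(
            vs.leg_gamma(x).gamma, abs=1e-9)

    @given(
        lo=st.integers(min_value=2, max_value=10),
        hi=st.integers(min_value=50, max_value=1000),
        k=st.integers(min_value=2, max_value=20),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_window_scheme_invariants(self, lo, hi, k):
        s = vs.make_window_scheme(lo, hi, k)
        assert s.sizes[0] == lo and s.sizes[-1] == hi
        assert all(b > a for a, b in zip(s.sizes, s.sizes[1:]))
        assert len(s.sizes) <= k
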