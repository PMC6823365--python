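import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from groovekit.kinetics import (
    EPS_DEGENERATE,
    FluorescenceTrace,
    ScramblingParams,
    eigenstructure,
    fit_leak,
    fit_scrambling,
    flux_active_fraction,
    fold_change,
    ftot,
    simulate_trace,
)


def ode_oracle(t, f0, a, b, g, L):
    """Numerical integration of the two-leaflet quench/flip system.

    Outer-leaflet label is quenched at gamma and flips inward at beta;
    inner label flips outward at alpha.  The protein pool starts at flip
    equilibrium (outer a/(a+b)); total fluorescence mixes in the
    protein-free pool with weight f0.
    """

    def rhs(_, y):
        Fo, Fi = y
        return [-(g + b) * Fo + a * Fi, b * Fo - a * Fi]

    sol = solve_ivp(rhs, (0, t[-1]), [a / (a + b), b / (a + b)], t_eval=t,
                    rtol=1e-11, atol=1e-13)
    prot = sol.y.sum(axis=0)
    return f0 * (L + (1 - L) * np.exp(-g * t)) + (1 - f0) * prot


class TestEigenstructure:
    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(1e-6, 10.0), st.floats(1e-6, 10.0), st.floats(1e-3, 50.0)
    )
    def test_identities(self, a, b, g):
        eig = eigenstructure(a, b, g)
        assert eig.lambda1 <= 0 and eig.lambda2 <= 0
        assert eig.lambda1 * eig.lambda2 == pytest.approx(a * g, rel=1e-9)
        assert eig.lambda1 + eig.lambda2 == pytest.approx(-(a + b + g), rel=1e-9)

    def test_d_identity(self):
        eig = eigenstructure(0.2, 0.1, 2.0)
        direct = (eig.lambda1 + 0.2) * (eig.lambda2 + 0.1 + 2.0) - 0.2 * 0.1
        assert eig.D == pytest.approx(direct, rel=1e-9)


class TestFtot:
    def test_matches_ode_oracle_fig6_regime(self):
        # alpha = beta = 0.2/s is the saturating reference-condition value
        p = ScramblingParams(f0=0.3, alpha=0.2, beta=0.2, gamma=2.0, L_i_PF=0.5)
        t = np.linspace(0, 60, 500)
        np.testing.assert_allclose(
            ftot(t, p), ode_oracle(t, 0.3, 0.2, 0.2, 2.0, 0.5), atol=1e-7
        )

    def test_matches_ode_oracle_random_draws(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 600, 400)
        for _ in range(50):
            a, b = 10 ** rng.uniform(-5, 0.8, 2)
            g = 10 ** rng.uniform(-0.5, 1)
            f0, L = rng.uniform(0, 1, 2)
            p = ScramblingParams(f0=f0, alpha=a, beta=b, gamma=g, L_i_PF=L)
            np.testing.assert_allclose(
                ftot(t, p), ode_oracle(t, f0, a, b, g, L), atol=1e-7
            )

    def test_normalized_at_t0(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            p = ScramblingParams(
                f0=rng.uniform(0, 1),
                alpha=10 ** rng.uniform(-8, 1),
                beta=10 ** rng.uniform(-8, 1),
                gamma=10 ** rng.uniform(-2, 1),
                L_i_PF=rng.uniform(0, 1),
            )
            assert ftot(0.0, p) == pytest.approx(1.0, abs=1e-9)

    def test_long_time_plateau(self):
        p = ScramblingParams(f0=0.3, alpha=0.2, beta=0.1, gamma=2.0, L_i_PF=0.5)
        assert ftot(50.0 / 2.0 * 20, p) == pytest.approx(0.3 * 0.5, abs=1e-9)

    def test_all_protein_free(self):
        p = ScramblingParams(f0=1.0, alpha=0.1, beta=0.1, gamma=2.0, L_i_PF=0.4)
        t = np.linspace(0, 20, 100)
        np.testing.assert_allclose(
            ftot(t, p), 0.4 + 0.6 * np.exp(-2.0 * t), atol=1e-12
        )

    def test_degenerate_branch_continuity(self):
        t = np.linspace(0, 600, 2000)
        for b in (0.0, 0.005, 0.3):
            hi = ScramblingParams(f0=0.3, alpha=EPS_DEGENERATE * 1.001, beta=b,
                                  gamma=2.0, L_i_PF=0.5)
            lo = ScramblingParams(f0=0.3, alpha=EPS_DEGENERATE * 0.999, beta=b,
                                  gamma=2.0, L_i_PF=0.5)
            assert np.max(np.abs(ftot(t, hi) - ftot(t, lo))) < 1e-6

    def test_monotone_non_increasing_for_beta_zero(self):
        t = np.linspace(0, 300, 3000)
        for a in (0.001, 0.05, 1.0, 5.0):
            for g in (0.5, 2.0, 8.0):
                p = ScramblingParams(f0=0.3, alpha=a, beta=0.0, gamma=g,
                                     L_i_PF=0.5)
                assert np.all(np.diff(ftot(t, p)) <= 1e-12)

    def test_negative_time_errors(self):
        p = ScramblingParams(f0=0.3, alpha=0.1, beta=0.1, gamma=2.0)
        with pytest.raises(ValueError):
            ftot(-1.0, p)

    def test_gamma_from_gamma_prime(self):
        p = ScramblingParams(f0=0.3, alpha=0.1, beta=0.1,
                             gamma_prime=50.0, dithionite_conc=0.04)
        assert p.effective_gamma() == pytest.approx(2.0)


class TestSimulateTrace:
    def test_noiseless_equals_ftot(self):
        p = ScramblingParams(f0=0.3, alpha=0.01, beta=0.005, gamma=2.0)
        t = np.arange(0, 100, 1 / 3)
        tr = simulate_trace(p, t)
        np.testing.assert_allclose(tr.values, ftot(t, p), atol=1e-15)

    def test_noise_mean_clt(self):
        p = ScramblingParams(f0=0.3, alpha=0.01, beta=0.005, gamma=2.0)
        t = np.array([0.0, 10.0])
        vals = [
            simulate_trace(p, t, noise_sd=0.01, seed=s).values[1]
            for s in range(1000)
        ]
        assert np.mean(vals) == pytest.approx(
            ftot(10.0, p), abs=3 * 0.01 / np.sqrt(1000)
        )

    def test_seeded_identical(self):
        p = ScramblingParams(f0=0.3, alpha=0.01, beta=0.005, gamma=2.0)
        t = np.arange(0, 50, 0.5)
        a = simulate_trace(p, t, noise_sd=0.01, seed=3)
        b = simulate_trace(p, t, noise_sd=0.01, seed=3)
        assert np.array_equal(a.values, b.values)


class TestFitScrambling:
    def test_noiseless_recovery_within_1pct(self):
        p = ScramblingParams(f0=0.3, alpha=0.01, beta=0.005, gamma=2.0,
                             L_i_PF=0.5)
        t = np.arange(0, 600, 1 / 3)
        tr = simulate_trace(p, t)
        fr = fit_scrambling(tr, L_i_PF=0.5, gamma=2.0, seed=0)
        assert fr.f0 == pytest.approx(0.3, rel=0.01)
        assert fr.alpha == pytest.approx(0.01, rel=0.01)
        assert fr.beta == pytest.approx(0.005, rel=0.01)
        assert fr.sse < 1e-12

    def test_noisy_grid_median_error(self):
        # scaled-down version of the recovery study: 10 replicates per alpha
        t = np.arange(0, 600, 1 / 3)
        for alpha in (0.002, 0.01, 0.05):
            errs = []
            for rep in range(10):
                p = ScramblingParams(f0=0.3, alpha=alpha, beta=alpha / 2,
                                     gamma=2.0, L_i_PF=0.5)
                tr = simulate_trace(p, t, noise_sd=0.005, seed=rep)
                fr = fit_scrambling(tr, L_i_PF=0.5, gamma=2.0, seed=rep,
                                    n_starts=4)
                errs.append(abs(fr.alpha - alpha) / alpha)
            assert np.median(errs) <= 0.10

    def test_saturating_alpha_warns(self):
        p = ScramblingParams(f0=0.3, alpha=10.0, beta=5.0, gamma=1.0,
                             L_i_PF=0.5)
        t = np.arange(0, 300, 1 / 3)
        tr = simulate_trace(p, t, noise_sd=0.002, seed=1)
        fr = fit_scrambling(tr, L_i_PF=0.5, gamma=1.0, seed=0, n_starts=4)
        assert fr.identifiability_warning

    def test_short_trace_warns(self):
        p = ScramblingParams(f0=0.3, alpha=0.01, beta=0.005, gamma=0.01)
        t = np.arange(0, 100, 1 / 3)
        tr = simulate_trace(p, t)
        with pytest.warns(UserWarning, match="slow-fit"):
            fit_scrambling(tr, L_i_PF=0.5, gamma=0.01, seed=0, n_starts=2)

    def test_sse_matches_recomputation(self):
        p = ScramblingParams(f0=0.4, alpha=0.02, beta=0.01, gamma=2.0,
                             L_i_PF=0.5)
        t = np.arange(0, 600, 1 / 3)
        tr = simulate_trace(p, t, noise_sd=0.005, seed=2)
        fr = fit_scrambling(tr, L_i_PF=0.5, gamma=2.0, seed=0, n_starts=4)
        fitted = ScramblingParams(f0=fr.f0, alpha=fr.alpha, beta=fr.beta,
                                  gamma=2.0, L_i_PF=0.5)
        sse = float(np.sum((ftot(t, fitted) - tr.values) ** 2))
        assert fr.sse == pytest.approx(sse, abs=1e-9)


class TestFitLeak:
    def test_printed_leak_slope_recovered(self):
        # fixture built with the published protein-free leak rate
        L = 5.4e-5
        t = np.arange(0.0, 600.0, 1 / 3)
        trace = FluorescenceTrace(times=t, values=1.0 - L * t)
        assert fit_leak(trace) == pytest.approx(L, abs=1e-9)

    def test_flat_tail_zero(self):
        t = np.arange(0.0, 600.0, 1 / 3)
        trace = FluorescenceTrace(times=t, values=np.ones_like(t))
        assert fit_leak(trace) == pytest.approx(0.0, abs=1e-12)

    def test_unbiased_under_noise(self):
        L = 5.4e-5
        t = np.arange(0.0, 600.0, 1 / 3)
        rng = np.random.default_rng(0)
        ests = []
        for _ in range(100):
            vals = 1.0 - L * t + rng.normal(0, 0.002, len(t))
            ests.append(fit_leak(FluorescenceTrace(times=t, values=vals)))
        se = np.std(ests) / 10.0
        assert np.mean(ests) == pytest.approx(L, abs=2 * se + 1e-12)

    def test_short_tail_errors(self):
        t = np.arange(0.0, 10.0, 0.5)
        trace = FluorescenceTrace(times=t, values=np.ones_like(t))
        with pytest.raises(ValueError, match="100"):
            fit_leak(trace)


class TestFlux:
    def test_equal_gives_zero(self):
        assert flux_active_fraction(1.5, 1.5).active_percent == 0.0

    def test_zero_gives_hundred(self):
        assert flux_active_fraction(0.0, 2.0).active_percent == 100.0

    def test_quarter(self):
        rec = flux_active_fraction(0.25 * 1.2, 1.2)
        assert rec.active_percent == pytest.approx(75.0)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            rec = flux_active_fraction(3.0, 1.0)
        assert rec.active_percent == 0.0

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            flux_active_fraction(1.0, 0.0)


class TestFoldChange:
    def test_exact_hundred_band_edge(self):
        ratio, band = fold_change(0.2, 0.002)
        assert ratio == pytest.approx(100.0)
        assert band == ">=100-fold"

    def test_equal_rates_no_band(self):
        ratio, band = fold_change(0.2, 0.2)
        assert ratio == 1.0 and band == ""

    def test_double_mutant_category(self):
        ratio, band = fold_change(0.2, 0.0001)
        assert ratio == pytest.approx(2000.0)
        assert band == ">=1000-fold"

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)
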