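"""Peak extraction, orbit classification, Lyapunov and statistical fits."""

import numpy as np
import pytest

import socrcc
from socrcc import (classify_orbit, detect_changepoint, fit_curve,
                    generate_fixture, information_criteria, lyapunov_local,
                    powerlaw_mle, remove_transient)
from socrcc.analysis import UndeterminedOrbitError, epoch_peaks


class TestRemoveTransient:
    def test_fraction_arithmetic(self):
        out = remove_transient(np.arange(1000), fraction=0.25)
        assert len(out) == 750 and out[0] == 250

    def test_zero_fraction_identity(self):
        x = np.arange(10)
        np.testing.assert_array_equal(remove_transient(x, fraction=0.0), x)

    def test_overtrim_signals(self):
        with pytest.raises(ValueError):
            remove_transient(np.arange(5), steps=5)
        with pytest.raises(ValueError):
            remove_transient(np.array([]))


class TestClassifyOrbit:
    def test_simple_cycle(self):
        t = np.linspace(0, 40 * np.pi, 4000)
        assert classify_orbit(np.sin(t)).period == 1

    def test_two_orbit(self):
        t = np.linspace(0, 40 * np.pi, 8000)
        oc = classify_orbit(np.sin(t) + 0.3 * np.sin(t / 2))
        assert oc.period == 2 and not oc.aperiodic

    def test_generated_two_orbit_train(self):
        y = generate_fixture("two-orbit-train", seed=1, n=2000, period=100)
        assert classify_orbit(y).period == 2

    def test_aperiodic_flagged(self, rng):
        # random-height peak train: no repeating level structure
        y = np.ravel(np.column_stack([rng.uniform(1, 5, 40),
                                      np.zeros(40)]))
        oc = classify_orbit(y)
        assert oc.aperiodic and oc.period == 0

    def test_too_few_peaks(self):
        with pytest.raises(UndeterminedOrbitError):
            classify_orbit(np.sin(np.linspace(0, 3, 100)))


def _toy_trajectory(M, n_epochs, eps_sums=None):
    n = len(M) // n_epochs
    eps = np.zeros((n_epochs, 2))
    if eps_sums is not None:
        eps[:, 0] = eps_sums
    return socrcc.Trajectory(
        t=np.arange(len(M), dtype=float),
        M=np.asarray(M, float),
        F=np.asarray(M, float) * 0.1,
        epoch=np.repeat(np.arange(n_epochs), n),
        eps=eps,
        eps_sum=np.abs(eps.sum(axis=1)),
        weights=np.ones((n_epochs, 2)),
        dt=1.0,
        record_stride=1,
    )


class TestEpochPeaks:
    def test_sinusoid_peak(self):
        t = np.linspace(0, 60 * np.pi, 6000)
        traj = _toy_trajectory(np.sin(t) + 2.0, 1)
        [s] = epoch_peaks(traj)
        assert s.max_M == pytest.approx(3.0, abs=1e-3)
        assert s.stable and s.orbit_period == 1

    def test_matches_bruteforce_max(self, rng):
        M = rng.uniform(0, 10, 400)
        traj = _toy_trajectory(M, 4)
        for s in epoch_peaks(traj, classify=False):
            seg = M[s.epoch * 100:(s.epoch + 1) * 100]
            assert s.max_M == pytest.approx(seg[25:].max())

    def test_seven_epochs_seven_summaries(self):
        t = np.linspace(0, 70 * np.pi, 7000)
        traj = _toy_trajectory(np.sin(t) + 2, 7)
        assert len(epoch_peaks(traj)) == 7


class TestLyapunov:
    def test_linear_decay_rate(self):
        _, lam = lyapunov_local(lambda t, y: -y, np.array([1.0]), 0.01, 4000,
                                window=100)
        assert np.mean(lam) == pytest.approx(-1.0, abs=0.02)

    def test_linear_growth_rate(self):
        _, lam = lyapunov_local(lambda t, y: +y, np.array([1.0]), 0.01,
                                4000, window=100)
        assert np.mean(lam) == pytest.approx(1.0, abs=0.02)

    def test_lorenz_sign_matches_two_trajectory_oracle(self):
        """Positive exponent for Lorenz, and sign agreement with a
        two-trajectory divergence estimate."""

        def lorenz(t, y):
            x, yy, z = y
            return np.array([10 * (yy - x), x * (28 - z) - yy,
                             x * yy - 8 / 3 * z])

        y0 = np.array([1.0, 1.0, 20.0])
        _, lam = lyapunov_local(lorenz, y0, 0.005, 8000, window=200)
        est = np.mean(lam[4:])
        assert est > 0

        # oracle: renormalised separation of two nearby trajectories
        d0 = 1e-8
        a, b = y0.copy(), y0 + np.array([d0, 0, 0])
        logs = []
        for k in range(8000):
            a = socrcc.step(lorenz, a, 0, 0.005)
            b = socrcc.step(lorenz, b, 0, 0.005)
            if k % 200 == 199:
                d = np.linalg.norm(b - a)
                logs.append(np.log(d / d0))
                b = a + (b - a) * d0 / d
        oracle = np.sum(logs) / (8000 * 0.005)
        assert np.sign(est) == np.sign(oracle)
        assert est == pytest.approx(oracle, rel=0.5)


class TestPowerlawMLE:
    def test_closed_form_on_exact_powers(self):
        x = 2.0 ** np.arange(10)  # {1, 2, 4, ...}
        fit = powerlaw_mle(x, x_min_candidates=[1.0])
        expect = 1 + len(x) / np.sum(np.log(x / 1.0))
        assert fit.alpha == pytest.approx(expect, rel=1e-12)

    def test_pareto_recovery(self):
        x = generate_fixture("pareto", seed=3, alpha=2.5, x_min=1.0, n=5000)
        fit = powerlaw_mle(x)
        assert fit.alpha == pytest.approx(2.5, abs=0.1)

    def test_mean_recovery_over_fixture_battery(self):
        """Mean |alpha_hat - alpha| < 0.1 over 20 seeded Pareto fixtures."""
        errs = []
        k = 0
        for alpha in (1.5, 2.5, 3.5):
            for seed in range(7):
                if k >= 20:
                    break
                x = generate_fixture("pareto", seed=seed + 10 * int(alpha * 2),
                                     alpha=alpha, x_min=1.0, n=2000)
                errs.append(abs(powerlaw_mle(x).alpha - alpha))
                k += 1
        assert np.mean(errs) < 0.1

    def test_exponential_fits_worse_than_pareto(self):
        pareto = generate_fixture("pareto", seed=5, alpha=2.5, n=2000)
        expo = generate_fixture("exponential", seed=5, scale=1.0, n=2000)
        ks_p = powerlaw_mle(pareto, min_tail_frac=0.5).ks_distance
        ks_e = powerlaw_mle(expo, min_tail_frac=0.5).ks_distance
        assert ks_e > ks_p

    def test_discrete_mode_close_to_continuous_for_large_alpha(self):
        x = np.round(generate_fixture("pareto", seed=2, alpha=3.0, x_min=5.0,
                                      n=4000)).astype(float)
        x = x[x >= 5]
        cont = powerlaw_mle(x, x_min_candidates=[5.0])
        disc = powerlaw_mle(x, discrete=True, x_min_candidates=[5.0])
        assert disc.alpha == pytest.approx(cont.alpha, rel=0.15)

    def test_degenerate_and_tiny_samples(self):
        with pytest.raises(ValueError):
            powerlaw_mle(np.full(100, 3.0))
        with pytest.raises(ValueError):
            powerlaw_mle([1.0, 2.0])

    def test_ccdf_slope_convention(self):
        x = generate_fixture("pareto", seed=1, alpha=2.5, n=1000)
        fit = powerlaw_mle(x)
        assert fit.ccdf_slope == pytest.approx(-(fit.alpha - 1))


class TestFitCurve:
    def test_exact_power_recovery(self):
        x = np.linspace(0.5, 5, 40)
        fit = fit_curve(x, 2.0 * x ** -0.5, "power")
        assert fit.a == pytest.approx(2.0, abs=1e-8)
        assert fit.b == pytest.approx(-0.5, abs=1e-8)
        assert fit.mse < 1e-16

    def test_exact_exponential_recovery(self):
        x = np.linspace(0, 2, 30)
        fit = fit_curve(x, 3.0 * np.exp(2.0 * x), "exponential")
        assert fit.a == pytest.approx(3.0, abs=1e-6)
        assert fit.b == pytest.approx(2.0, abs=1e-8)

    def test_noisy_power_within_three_se(self, rng):
        """Log-log regression slope recovers truth within 3 analytic SEs."""
        n, b_true = 100, -0.7
        x = np.exp(rng.uniform(0, 3, n))
        sigma = 0.2
        y = 2.0 * x ** b_true * np.exp(sigma * rng.standard_normal(n))
        fit = fit_curve(x, y, "power", refine=False)
        lx = np.log(x)
        se = sigma / np.sqrt(np.sum((lx - lx.mean()) ** 2))
        assert abs(fit.b - b_true) < 3 * se

    def test_power_rejects_nonpositive_x(self):
        with pytest.raises(ValueError):
            fit_curve([-1, 1, 2], [1, 2, 3], "power")


class TestInformationCriteria:
    def test_printed_form_values(self):
        aic, bic = information_criteria(1.0, 50, 2)
        assert aic == 4.0 and bic == pytest.approx(2 * np.log(50))
        aic, bic = information_criteria(np.e, 10, 2)
        assert aic == pytest.approx(-6.0)

    def test_hand_computed_dataset(self):
        resid = np.array([0.5, -1.0, 0.25])
        mse = float(np.mean(resid ** 2))
        aic, bic = information_criteria(mse, 3, 2)
        assert aic == pytest.approx(-3 * np.log(mse) + 4)
        assert bic == pytest.approx(-3 * np.log(mse) + 2 * np.log(3))

    def test_conventions_are_mse_term_negations(self):
        for mse in (0.3, 2.0, 40.0):
            ap, bp_ = information_criteria(mse, 20, 2, "printed")
            ac, bc = information_criteria(mse, 20, 2, "conventional")
            assert ap + ac == pytest.approx(8.0)        # 2*(2k)
            assert bp_ + bc == pytest.approx(4 * np.log(20))

    def test_perfect_fit_signalled(self):
        with pytest.raises(ValueError):
            information_criteria(0.0, 10, 2)


class TestChangepoint:
    def test_recovers_constructed_break(self, rng):
        x = np.exp(rng.uniform(np.log(0.001), np.log(0.2), 400))
        split_true = 0.04
        y = np.where(x <= split_true, 100 * x ** -0.3, 5e4 * x ** 2.0)
        y *= np.exp(0.05 * rng.standard_normal(400))
        split = detect_changepoint(x, y)
        assert 0.5 * split_true < split < 2 * split_true
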