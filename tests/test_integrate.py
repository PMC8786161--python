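"""Fixed-step integrators, the compiled network kernel, and epoch plumbing."""

import dataclasses

import numpy as np
import pytest

import socrcc
from socrcc import IntegratorSpec, PerturbationSchedule, integrate_epochs, step


class TestStep:
    @pytest.mark.parametrize("method", ["rk4", "rk_fehlberg", "rk_prince_dormand"])
    def test_exponential_decay_one_step(self, method):
        y1 = step(lambda t, y: -y, np.array([1.0]), 0.0, 0.1, method)
        assert y1[0] == pytest.approx(np.exp(-0.1), abs=1e-7)

    def test_zero_field_is_identity(self):
        y0 = np.array([1.0, -2.0, 3.0])
        y1 = step(lambda t, y: 0 * y, y0, 0.0, 0.5)
        np.testing.assert_array_equal(y0, y1)

    def test_rk4_order_of_convergence(self):
        """Global error on dx/dt = -x over [0,1] scales as dt^4."""
        errs = []
        for dt in (0.1, 0.05, 0.025):
            y = np.array([1.0])
            for k in range(round(1.0 / dt)):
                y = step(lambda t, yy: -yy, y, k * dt, dt)
            errs.append(abs(y[0] - np.exp(-1.0)))
        slopes = np.diff(np.log(errs)) / np.diff(np.log([0.1, 0.05, 0.025]))
        assert np.all(np.abs(slopes - 4.0) < 0.3)

    def test_divergence_raises(self):
        with pytest.raises(socrcc.integrate.DivergenceError):
            step(lambda t, y: y ** 3, np.array([1e200]), 0.0, 1.0)


class TestKernelAgainstReference:
    @pytest.mark.parametrize("mode", ["all_to_all", "stencil", "crank_nicholson"])
    def test_backends_agree(self, mode, rng):
        """Compiled kernel matches the numpy reference path step for step."""
        cfg = socrcc.NetworkConfig(
            n_units=4, weights=(1e-4, 2e-4, 1.5e-4, 2.5e-4), grid_shape=(2, 2),
            coupling_mode=mode)
        sched = PerturbationSchedule(redraw_interval=100, n_epochs=2, seed=5)
        spec = IntegratorSpec(dt=0.5, record_stride=4)
        y0 = rng.uniform(0.5, 4.0, (4, 4))
        t_nb = integrate_epochs(cfg, sched, spec, y0=y0, backend="numba",
                                record_states=True)
        t_np = integrate_epochs(cfg, sched, spec, y0=y0, backend="numpy",
                                record_states=True)
        np.testing.assert_allclose(t_nb.M, t_np.M, rtol=1e-12)
        np.testing.assert_allclose(t_nb.states, t_np.states, rtol=1e-12)

    def test_feedback_backends_agree(self, rng):
        cfg = socrcc.NetworkConfig(
            n_units=4, weights=(1e-4, 2e-4, 1.5e-4, 2.5e-4), grid_shape=(2, 2),
            feedback_sign=-1, feedback_v=1e-5)
        sched = PerturbationSchedule(redraw_interval=80, n_epochs=1, seed=6)
        spec = IntegratorSpec(dt=0.5, record_stride=4)
        y0 = rng.uniform(0.5, 4.0, (4, 4))
        t_nb = integrate_epochs(cfg, sched, spec, y0=y0, backend="numba")
        t_np = integrate_epochs(cfg, sched, spec, y0=y0, backend="numpy")
        np.testing.assert_allclose(t_nb.M, t_np.M, rtol=1e-12)


class TestEpochPlumbing:
    def test_epoch_segments(self, small_net):
        sched = PerturbationSchedule(redraw_interval=200, n_epochs=7, seed=1)
        traj = integrate_epochs(small_net, sched, IntegratorSpec(dt=0.5,
                                                                 record_stride=10))
        assert traj.n_epochs == 7
        assert set(np.unique(traj.epoch)) == set(range(7))

    def test_zero_length_schedule(self, small_net):
        sched = PerturbationSchedule(redraw_interval=100, n_epochs=0, seed=1)
        traj = integrate_epochs(small_net, sched, IntegratorSpec())
        assert len(traj.M) == 0 and traj.n_epochs == 0

    def test_determinism(self, small_net):
        sched = PerturbationSchedule(redraw_interval=300, n_epochs=3, seed=42)
        spec = IntegratorSpec(dt=0.5, record_stride=5)
        t1 = integrate_epochs(small_net, sched, spec)
        t2 = integrate_epochs(small_net, sched, spec)
        np.testing.assert_array_equal(t1.M, t2.M)
        np.testing.assert_array_equal(t1.eps, t2.eps)

    def test_divergence_flagged_with_epoch(self):
        """Excessive connectivity drives the summed matrix into a singularity
        which is reported, not silently clipped."""
        cfg = socrcc.NetworkConfig(n_units=4, weights=(0.5,) * 4,
                                   grid_shape=(2, 2), ceiling=1e4)
        sched = PerturbationSchedule(redraw_interval=5000, n_epochs=3, seed=1)
        traj = integrate_epochs(cfg, sched, IntegratorSpec(dt=1.0))
        assert traj.diverged
        assert traj.diverged_epoch is not None

    def test_method_agreement_on_network(self, net16):
        """rk4 and fixed-step Dormand-Prince agree on per-epoch max(M) to
        0.1% over a short horizon (weak chaos precludes long-horizon
        bit-agreement)."""
        sched = PerturbationSchedule(redraw_interval=4000, n_epochs=2, seed=2)
        peaks = {}
        for method in ("rk4", "rk_prince_dormand"):
            spec = IntegratorSpec(method=method, dt=0.1, record_stride=10)
            traj = integrate_epochs(net16, sched, spec)
            summ = socrcc.epoch_peaks(traj, classify=False)
            peaks[method] = np.array([s.max_M for s in summ])
        np.testing.assert_allclose(peaks["rk4"], peaks["rk_prince_dormand"],
                                   rtol=1e-3)

    def test_feedback_uses_instantaneous_global_sum(self, rng):
        """Stage-level M feedback differs measurably from frozen
        previous-step M feedback: the instantaneous contract is real."""
        cfg = socrcc.NetworkConfig(
            n_units=4, weights=(1e-4, 2e-4, 1.5e-4, 2.5e-4), grid_shape=(2, 2),
            feedback_sign=1, feedback_v=9e-5)
        y0 = rng.uniform(0.5, 4.0, (4, 4))
        sched = PerturbationSchedule(redraw_interval=2000, n_epochs=1, seed=3,
                                     distribution="none")
        spec = IntegratorSpec(dt=1.0, record_stride=10)
        inst = integrate_epochs(cfg, sched, spec, y0=y0)

        # stale variant: feedback frozen at the committed state's M
        from socrcc.network import network_rhs
        Y = y0.copy()
        stale_M = []
        base = dataclasses.replace(cfg, feedback_sign=0)
        for it in range(2000):
            committed = Y.copy()
            fbterm = cfg.v_signed * committed[:, 0].sum()

            def deriv(_t, yflat):
                out = network_rhs(yflat.reshape(4, 4), base, np.zeros(4),
                                  Y_prev=committed)
                out[:, 0] += fbterm
                return out.ravel()

            Y = step(deriv, Y.ravel(), 0.0, 1.0).reshape(4, 4)
            if (it + 1) % 10 == 0:
                stale_M.append(Y[:, 0].sum())
        assert np.max(np.abs(np.array(stale_M) - inst.M)) > 1e-8


class TestTrajectoryIO:
    def test_hdf5_roundtrip(self, small_net, tmp_path):
        sched = PerturbationSchedule(redraw_interval=100, n_epochs=2, seed=4)
        traj = integrate_epochs(small_net, sched,
                                IntegratorSpec(dt=0.5, record_stride=5),
                                record_states=True)
        path = tmp_path / "traj.h5"
        traj.to_hdf5(path)
        back = socrcc.Trajectory.from_hdf5(path)
        np.testing.assert_array_equal(traj.M, back.M)
        np.testing.assert_array_equal(traj.states, back.states)
        assert back.dt == traj.dt

    def test_tidy_csv(self, small_net, tmp_path):
        import pandas as pd

        sched = PerturbationSchedule(redraw_interval=100, n_epochs=1, seed=4)
        traj = integrate_epochs(small_net, sched,
                                IntegratorSpec(dt=0.5, record_stride=10),
                                record_states=True)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "unit", "m", "f", "p", "g"]
        assert len(df) == len(traj.t) * 4
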