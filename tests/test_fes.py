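"""Reconstruction machinery: reweighting, WHAM, angular FES, bootstrap."""

import numpy as np
import pytest

import dimerfes as df
from dimerfes.constants import kt
from dimerfes.fes import integrated_autocorrelation_time

from conftest import harmonic_window_samples


# ------------------------------------------------------------- reweighting

class TestReweight:
    def test_empty_hills_equal_weights(self):
        traj = df.CVTrajectory(times=np.arange(5.0) + 1.0,
                               data=np.linspace(0.5, 0.9, 5)[:, None],
                               cv_names=("r",))
        ws = df.reweight_metad(traj, df.HillsLog.empty(cv_names=("r",)))
        assert np.allclose(ws.weights, 1.0)

    def test_constant_bias_shift_absorbed_by_offset(self, rng):
        """Adding a flat bias everywhere (a huge-width hill) leaves the
        relative frame weights unchanged: c(t) absorbs constants."""
        n = 40
        times = np.arange(n) * 10.0 + 10.0
        centers = rng.uniform(0.3, 0.7, (n, 1))
        base = df.HillsLog(times=times, centers=centers,
                           sigmas=np.full((n, 1), 0.05),
                           heights=np.full(n, 0.1), cv_names=("theta",))
        # same log with one flat pseudo-hill prepended
        shifted = df.HillsLog(
            times=np.concatenate([[0.5], times]),
            centers=np.vstack([[0.5], centers]),
            sigmas=np.vstack([[1e6], np.full((n, 1), 0.05)]),
            heights=np.concatenate([[3.0], np.full(n, 0.1)]),
            cv_names=("theta",),
        )
        traj = df.CVTrajectory(
            times=np.linspace(1, n * 10.0, 200),
            data=np.column_stack([np.full(200, 1.0),
                                  rng.uniform(0.3, 0.7, 200)]),
            cv_names=("r", "theta"),
        )
        w1 = df.reweight_metad(traj, base).weights
        w2 = df.reweight_metad(traj, shifted).weights
        assert np.allclose(w1, w2, rtol=1e-6)

    def test_inconsistent_time_span_rejected(self, rng):
        traj = df.CVTrajectory(
            times=np.linspace(1, 50, 20),
            data=np.column_stack([np.ones(20),
                                  rng.uniform(0.3, 0.7, 20)]),
            cv_names=("r", "theta"))
        hills = df.HillsLog(times=np.arange(10.0, 500.0, 10.0),
                            centers=rng.uniform(0.3, 0.7, (49, 1)),
                            sigmas=np.full((49, 1), 0.05),
                            heights=np.full(49, 0.1), cv_names=("theta",))
        with pytest.raises(ValueError, match="inconsistent"):
            df.reweight_metad(traj, hills)


# ------------------------------------------------------------------ WHAM

class TestWham:
    def test_single_unbiased_window_is_log_histogram(self, rng):
        kT = kt(300)
        r = rng.normal(1.0, 0.1, 20000)
        ws = df.WeightedSamples(r=r, weights=np.ones(r.size))
        uw = df.UmbrellaWindow(center=1.0, force_constant=1e-12)
        prof = df.wham([(uw, ws)], grid=(0.6, 1.4, 0.02))
        H, edges = np.histogram(r, bins=np.arange(0.6, 1.42, 0.02))
        m = prof.sampled & (H > 0)
        expected = -kT * np.log(H[m])
        d = prof.F[m] - expected
        assert np.allclose(d, d[0], atol=1e-9)

    def test_harmonic_windows_recover_parabola(self, rng):
        windows = harmonic_window_samples(rng, k_pot=30.0, k_umb=60.0, x0=1.0,
                                          centers=np.linspace(0.5, 1.5, 5),
                                          n=4000)
        prof = df.wham(windows, grid=(0.4, 1.6, 0.02))
        m = prof.sampled
        expected = 0.5 * 30.0 * (prof.r[m] - 1.0) ** 2
        d = prof.F[m] - expected
        d -= d.mean()
        assert np.sqrt((d**2).mean()) <= 0.1

    def test_self_consistency_plugback(self, rng):
        """The converged window constants satisfy the WHAM equations."""
        windows = harmonic_window_samples(rng, 30.0, 60.0, 1.0,
                                          np.linspace(0.5, 1.5, 5), 4000)
        prof = df.wham(windows, grid=(0.4, 1.6, 0.02), tol=1e-10)
        assert prof.provenance["residual"] < 1e-8
        # independent plug-back of the self-consistency equations
        kT = kt(300)
        edges = np.asarray(prof.provenance["edges"])
        g = np.asarray(prof.provenance["g"]) / kT
        N = np.asarray(prof.provenance["N"])
        H = np.array([np.histogram(ws.r, bins=edges)[0]
                      for _, ws in windows], dtype=float)
        bU = np.array([df.umbrella_energy(uw, prof.r) / kT
                       for uw, _ in windows])
        num = H.sum(axis=0)
        den = (N[:, None] * np.exp(g[:, None] - bU)).sum(axis=0)
        P = np.where(num > 0, num / den, 0.0)
        g_new = -np.log((P[None, :] * np.exp(-bU)).sum(axis=1))
        g_new -= g_new[0]
        assert np.max(np.abs(g_new - g)) * kT < 1e-6

    def test_reorder_invariance(self, rng):
        windows = harmonic_window_samples(rng, 30.0, 60.0, 1.0,
                                          np.linspace(0.5, 1.5, 5), 2000)
        p1 = df.wham(windows, grid=(0.4, 1.6, 0.02))
        p2 = df.wham(windows[::-1], grid=(0.4, 1.6, 0.02))
        m = p1.sampled
        d = p1.F[m] - p2.F[m]
        assert np.allclose(d - d.mean(), 0.0, atol=1e-6)

    def test_split_window_invariance(self, rng):
        """Splitting one window's samples into two windows with the same
        bias leaves the profile unchanged."""
        windows = harmonic_window_samples(rng, 30.0, 60.0, 1.0,
                                          np.linspace(0.5, 1.5, 5), 2000)
        uw, ws = windows[2]
        half = len(ws) // 2
        split = windows[:2] + [
            (uw, ws.take(np.arange(half))),
            (uw, ws.take(np.arange(half, len(ws)))),
        ] + windows[3:]
        p1 = df.wham(windows, grid=(0.4, 1.6, 0.02))
        p2 = df.wham(split, grid=(0.4, 1.6, 0.02))
        m = p1.sampled
        d = p1.F[m] - p2.F[m]
        assert np.allclose(d - d.mean(), 0.0, atol=1e-6)

    def test_disconnected_windows_rejected(self, rng):
        w1 = df.WeightedSamples(r=rng.normal(0.5, 0.01, 500),
                                weights=np.ones(500))
        w2 = df.WeightedSamples(r=rng.normal(1.5, 0.01, 500),
                                weights=np.ones(500))
        windows = [
            (df.UmbrellaWindow(center=0.5, force_constant=100.0, index=0), w1),
            (df.UmbrellaWindow(center=1.5, force_constant=100.0, index=1), w2),
        ]
        with pytest.raises(ValueError, match="disconnected"):
            df.wham(windows, grid=(0.4, 1.6, 0.02))

    def test_low_overlap_warns(self, rng):
        w1 = df.WeightedSamples(r=rng.normal(0.5, 0.05, 2000),
                                weights=np.ones(2000))
        w2 = df.WeightedSamples(r=rng.normal(0.72, 0.05, 2000),
                                weights=np.ones(2000))
        windows = [
            (df.UmbrellaWindow(center=0.5, force_constant=100.0, index=0), w1),
            (df.UmbrellaWindow(center=0.72, force_constant=100.0, index=1), w2),
        ]
        with pytest.warns(UserWarning, match="overlap"):
            df.wham(windows, grid=(0.3, 0.95, 0.02))


class TestSetReference:
    def test_constant_profile_maps_to_zero(self):
        p = df.FreeEnergyProfile(r=np.linspace(1, 2, 11),
                                 F=np.full(11, 3.3), stderr=np.zeros(11))
        q = df.set_reference(p, (1.2, 1.8))
        assert np.allclose(q.F, 0.0)

    def test_tail_reference_preserves_depth(self):
        r = np.linspace(1, 2, 101)
        F = 5.0 - 12.0 * np.exp(-((r - 1.3) ** 2) / 0.005)
        p = df.FreeEnergyProfile(r=r, F=F, stderr=np.zeros(101))
        q = df.set_reference(p, (1.8, 2.0))
        assert q.F[r > 1.9].mean() == pytest.approx(0.0, abs=1e-6)
        assert q.F.min() == pytest.approx(-12.0, abs=0.01)

    def test_idempotent(self):
        p = df.FreeEnergyProfile(r=np.linspace(1, 2, 11),
                                 F=np.arange(11.0), stderr=np.zeros(11))
        q1 = df.set_reference(p, (1.0, 2.0))
        q2 = df.set_reference(q1, (1.0, 2.0))
        assert np.allclose(q1.F, q2.F)

    def test_unsampled_range_rejected(self):
        F = np.full(11, np.inf)
        F[:5] = 0.0
        p = df.FreeEnergyProfile(r=np.linspace(1, 2, 11), F=F,
                                 stderr=np.zeros(11))
        with pytest.raises(ValueError, match="reference"):
            df.set_reference(p, (1.8, 2.0))


# ------------------------------------------------------------ angular FES

def _angular_window(rng, u_fn, n=150_000, box=(0.1, 0.9)):
    """One pseudo-window of exact Boltzmann angle samples at fixed r."""
    kT = kt(300)
    th = rng.uniform(box[0], box[1], (int(n * 3), 2))
    u = u_fn(th)
    keep = rng.uniform(0, 1, th.shape[0]) < np.exp(-(u - u.min()) / kT)
    th = th[keep][:n]
    ws = df.WeightedSamples(r=np.full(th.shape[0], 1.0),
                            weights=np.ones(th.shape[0]), theta=th)
    uw = df.UmbrellaWindow(center=1.0, force_constant=1e-12)
    return [(uw, ws)]


class TestAngularFes:
    def test_flat_potential_constant_surface(self, rng):
        wins = _angular_window(rng, lambda th: np.zeros(th.shape[0]))
        ang = df.angular_fes(wins, (0.9, 1.1), resolution=0.05)
        m = np.isfinite(ang.F)
        assert ang.F[m].max() - ang.F[m].min() < 0.3

    def test_two_well_depth_difference(self, rng):
        # well at (0.3,0.3) is 1 kcal/mol deeper than the one at (0.7,0.7)
        wins = _angular_window(rng, lambda th: (
            -2.0 * np.exp(-((th - [0.3, 0.3]) ** 2).sum(1) / 0.02)
            - 1.0 * np.exp(-((th - [0.7, 0.7]) ** 2).sum(1) / 0.02)
        ))
        ang = df.angular_fes(wins, (0.9, 1.1), resolution=0.04)
        ia1 = np.argmin(np.abs(ang.theta_a - 0.3))
        ia2 = np.argmin(np.abs(ang.theta_a - 0.7))
        diff = ang.F[ia2, ia2] - ang.F[ia1, ia1]
        assert diff == pytest.approx(1.0, abs=0.3)

    def test_symmetric_potential_symmetric_surface(self, rng):
        wins = _angular_window(rng, lambda th: (
            -1.5 * np.exp(-((th - [0.3, 0.6]) ** 2).sum(1) / 0.02)
            - 1.5 * np.exp(-((th - [0.6, 0.3]) ** 2).sum(1) / 0.02)
        ))
        ang = df.angular_fes(wins, (0.9, 1.1), resolution=0.05)
        m = np.isfinite(ang.F) & np.isfinite(ang.F.T) & (ang.F < 2.0)
        assert np.abs((ang.F - ang.F.T)[m]).max() < 0.4

    def test_empty_slice_rejected(self, rng):
        wins = _angular_window(rng, lambda th: np.zeros(th.shape[0]), n=1000)
        with pytest.raises(ValueError, match="slice"):
            df.angular_fes(wins, (5.0, 6.0))


class TestFindMinima:
    def _surface(self, F):
        g = np.linspace(0, 1, F.shape[0])
        return df.AngularFES(theta_a=g, theta_b=g, F=F, r_slice=(0.9, 1.1))

    def test_single_quadratic_well(self):
        g = np.linspace(0, 1, 21)
        TA, TB = np.meshgrid(g, g, indexing="ij")
        F = (TA - 0.5) ** 2 + (TB - 0.5) ** 2
        mins = df.find_minima(self._surface(F), depth_threshold=0.5)
        assert len(mins) == 1
        assert mins[0]["theta_a"] == pytest.approx(0.5)
        assert mins[0]["label"] == "Theta1"

    def test_two_wells_ordered_by_depth(self):
        g = np.linspace(0, 1, 41)
        TA, TB = np.meshgrid(g, g, indexing="ij")
        F = (2.0 - 2.0 * np.exp(-((TA - 0.25) ** 2 + (TB - 0.25) ** 2) / 0.01)
             - 1.2 * np.exp(-((TA - 0.75) ** 2 + (TB - 0.75) ** 2) / 0.01))
        F -= F.min()
        mins = df.find_minima(self._surface(F), depth_threshold=1.5)
        assert len(mins) == 2
        assert mins[0]["F"] < mins[1]["F"]
        assert mins[0]["theta_a"] == pytest.approx(0.25, abs=0.03)
        assert mins[1]["theta_a"] == pytest.approx(0.75, abs=0.03)

    def test_flat_surface_no_minima(self):
        F = np.full((11, 11), 3.0)
        assert df.find_minima(self._surface(F), depth_threshold=2.0) == []


# -------------------------------------------------------------- bootstrap

class TestBootstrap:
    def test_zero_variance_zero_errors(self):
        ws = df.WeightedSamples(r=np.full(500, 1.0), weights=np.ones(500))
        uw = df.UmbrellaWindow(center=1.0, force_constant=100.0)
        err, reps = df.bootstrap_errors([(uw, ws)], n_boot=5,
                                        grid=np.array([0.9, 1.0, 1.1]))
        assert np.all(err == 0.0)

    def test_errors_non_negative_and_shrink_with_replication(self, rng):
        windows = harmonic_window_samples(rng, 30.0, 60.0, 1.0,
                                          np.linspace(0.5, 1.5, 5), 800)
        grid = np.arange(0.4, 1.62, 0.02)
        err1, _ = df.bootstrap_errors(windows, n_boot=40, block_length=1,
                                      seed=1, grid=grid,
                                      reference_range=(0.9, 1.1))
        dup = []
        for uw, ws in windows:
            idx = np.tile(np.arange(len(ws)), 4)
            dup.append((uw, ws.take(idx)))
        err4, _ = df.bootstrap_errors(dup, n_boot=40, block_length=1,
                                      seed=2, grid=grid,
                                      reference_range=(0.9, 1.1))
        assert np.all(err1 >= 0) and np.all(err4 >= 0)
        m = (err1 > 0) & (err4 > 0)
        ratio = err4[m].mean() / err1[m].mean()
        assert ratio == pytest.approx(0.5, abs=0.2)

    def test_n_boot_guard(self):
        with pytest.raises(ValueError):
            df.bootstrap_errors([], n_boot=1)


class TestIact:
    def test_white_noise_near_one(self, rng):
        x = rng.standard_normal(20000)
        assert integrated_autocorrelation_time(x) < 1.5

    def test_ar1_matches_theory(self, rng):
        phi = 0.9
        n = 200_000
        e = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = e[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + e[i]
        tau = integrated_autocorrelation_time(x)
        expected = (1 + phi) / (1 - phi)
        assert tau == pytest.approx(expected, rel=0.4)

    def test_constant_series(self):
        assert integrated_autocorrelation_time(np.ones(100)) == 1.0
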