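"""K_D / K_X / ΔG_X° conversions and their error propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dimerfes as df
from dimerfes.constants import kt


def flat_profile(F0=0.0, r_max=2.0, n=201, ref=(1.8, 2.0)):
    r = np.linspace(0.01, r_max, n)
    return df.FreeEnergyProfile(r=r, F=np.full(n, F0), stderr=np.zeros(n),
                                reference_range=ref)


class TestKdFromProfile:
    def test_flat_profile_pure_geometric_area(self):
        """With F ≡ 0 the integral reduces to the in-plane area π r_D²
        scaled by the allowed orientation fraction ||Ω0||/(2π)²."""
        omega0, r_d = 0.25, 1.5
        p = flat_profile()
        kd = df.k_d_from_profile(p, omega0, r_d)
        r0 = p.r[0]
        expected = omega0 / (2 * np.pi) ** 2 * np.pi * (r_d**2 - r0**2) * 1e-6
        assert kd == pytest.approx(expected, rel=1e-5)

    def test_square_well_closed_form(self):
        """F = −F0 on [r1, r2], zero elsewhere: quadrature matches the
        analytic 2πr integral."""
        kT = kt(300)
        F0, r1, r2, r_d, omega0 = 3.0, 0.8, 1.0, 1.8, 0.21
        r = np.linspace(0.01, 2.0, 4001)
        F = np.where((r >= r1) & (r <= r2), -F0, 0.0)
        p = df.FreeEnergyProfile(r=r, F=F, stderr=np.zeros_like(r),
                                 reference_range=(1.85, 2.0))
        kd = df.k_d_from_profile(p, omega0, r_d)
        area = (np.pi * (r_d**2 - r[0] ** 2)
                + np.pi * (r2**2 - r1**2) * (np.exp(F0 / kT) - 1.0))
        expected = omega0 / (2 * np.pi) ** 2 * area * 1e-6
        # discontinuous F on a finite quadrature grid: percent-level agreement
        assert kd == pytest.approx(expected, rel=5e-3)

    def test_constant_shift_absorbed_by_referencing(self, rng):
        r = np.linspace(0.01, 2.0, 301)
        F = -5.0 * np.exp(-((r - 1.0) ** 2) / 0.01)
        base = df.set_reference(
            df.FreeEnergyProfile(r=r, F=F, stderr=np.zeros_like(r)),
            (1.8, 2.0))
        shifted = df.set_reference(
            df.FreeEnergyProfile(r=r, F=F + 7.7, stderr=np.zeros_like(r)),
            (1.8, 2.0))
        kd1 = df.k_d_from_profile(base, 0.21, 1.7)
        kd2 = df.k_d_from_profile(shifted, 0.21, 1.7)
        assert kd1 == pytest.approx(kd2, rel=1e-12)

    @settings(derandomize=True, max_examples=15)
    @given(depth=st.floats(0.5, 8.0), extra=st.floats(0.01, 2.0))
    def test_monotone_in_depth_and_rd(self, depth, extra):
        r = np.linspace(0.01, 2.0, 301)

        def prof(d):
            F = -d * np.exp(-((r - 1.0) ** 2) / 0.01)
            return df.set_reference(
                df.FreeEnergyProfile(r=r, F=F, stderr=np.zeros_like(r)),
                (1.8, 2.0))

        kd_lo = df.k_d_from_profile(prof(depth), 0.21, 1.5)
        kd_hi = df.k_d_from_profile(prof(depth + extra), 0.21, 1.5)
        kd_far = df.k_d_from_profile(prof(depth), 0.21, 1.5 + 0.3)
        assert kd_hi >= kd_lo
        assert kd_far >= kd_lo

    def test_unreferenced_profile_rejected(self):
        p = df.FreeEnergyProfile(r=np.linspace(0.1, 2, 20),
                                 F=np.zeros(20), stderr=np.zeros(20))
        with pytest.raises(ValueError, match="referenced"):
            df.k_d_from_profile(p, 0.21, 1.5)

    def test_rd_beyond_grid_rejected(self):
        with pytest.raises(ValueError, match="extrapolat"):
            df.k_d_from_profile(flat_profile(r_max=2.0), 0.21, 3.0)

    def test_bad_omega_rejected(self):
        with pytest.raises(ValueError):
            df.k_d_from_profile(flat_profile(), 0.0, 1.0)


class TestConversions:
    def test_kx_arithmetic(self):
        m = df.MembraneSpec(lipid_density=1.65e6)
        assert df.k_x(7.2, m) == pytest.approx(1.188e7, rel=1e-9)

    def test_kx_trivial_cases(self):
        m = df.MembraneSpec(lipid_density=1.65e6)
        assert df.k_x(0.0, m) == 0.0
        assert df.k_x(1.0 / 1.65e6, m) == pytest.approx(1.0)

    def test_delta_g_zero_at_unit_kx(self):
        assert df.delta_g_x(1.0, df.MembraneSpec()) == 0.0

    def test_delta_g_negative_for_association(self):
        m = df.MembraneSpec()
        assert df.delta_g_x(df.k_x(7.2, m), m) < 0

    def test_nonpositive_kx_rejected(self):
        with pytest.raises(ValueError):
            df.delta_g_x(0.0, df.MembraneSpec())

    def test_round_trip_kd(self):
        m = df.MembraneSpec()
        kd = 7.2
        dg = df.delta_g_x(df.k_x(kd, m), m)
        kx_back = np.exp(-dg / (df.KB_KCAL * m.temperature))
        assert kx_back / m.lipid_density == pytest.approx(kd, rel=1e-9)


class TestPropagateCi:
    def test_zero_errors_degenerate_ci(self):
        p = flat_profile(F0=0.0)
        res = df.propagate_ci(p, 0.21, 1.5, df.MembraneSpec())
        assert res.k_d_ci == (res.k_d, res.k_d)
        assert res.delta_g_ci == (res.delta_g, res.delta_g)
        res.validate()

    def test_ci_brackets_point_estimate(self, rng):
        p = flat_profile()
        p.stderr = np.full_like(p.F, 0.1)
        res = df.propagate_ci(p, 0.21, 1.5, df.MembraneSpec(), seed=3)
        assert res.k_d_ci[0] <= res.k_d <= res.k_d_ci[1]
        assert res.delta_g_ci[0] <= res.delta_g <= res.delta_g_ci[1]

    def test_wider_errors_widen_ci(self):
        p1 = flat_profile()
        p1.stderr = np.full_like(p1.F, 0.1)
        p2 = flat_profile()
        p2.stderr = np.full_like(p2.F, 0.2)
        m = df.MembraneSpec()
        w1 = np.diff(df.propagate_ci(p1, 0.21, 1.5, m, seed=5).delta_g_ci)[0]
        w2 = np.diff(df.propagate_ci(p2, 0.21, 1.5, m, seed=5).delta_g_ci)[0]
        assert w2 > w1


def test_kd_predicts_bound_fraction_in_particle_simulation():
    """Independent cross-check of the 2πr measure: a Brownian particle pair
    in a reflecting box, interacting through an isotropic well, spends a
    fraction of time bound that mass action predicts from K_D."""
    import dimerfes.potentials as pots

    depth, sigma, L, r_d = 2.0, 0.3, 3.0, 0.9
    pot = pots.ModelPotential.gaussian_wells(
        cv_names=("x", "y"), heights=[-depth], centers=[[0.0, 0.0]],
        sigmas=[[sigma, sigma]], domain=[[-2.5, -2.5], [2.5, 2.5]],
        wall_lo=np.array([-L / 2, -L / 2]), wall_hi=np.array([L / 2, L / 2]),
        wall_kappa=np.array([1e4, 1e4]),
    )
    cfg = df.DynamicsConfig(diffusion=2e-3, timestep=0.01, n_steps=4_000_000,
                            output_stride=0.5, seed=21,
                            initial_state=np.array([0.0, 0.0]))
    traj, _ = df.simulate(pot, cfg)
    rr = np.sqrt((traj.data**2).sum(axis=1))
    observed = float((rr < r_d).mean())

    # prediction from the K_D quadrature with no angular restriction
    kT = kt(300)
    r = np.linspace(1e-3, r_d, 2001)
    F = -depth * np.exp(-(r**2) / (2 * sigma**2))
    prof = df.FreeEnergyProfile(r=r, F=F, stderr=np.zeros_like(r),
                                reference_range=(0.85, 0.9))
    kd_nm2 = df.k_d_from_profile(prof, (2 * np.pi) ** 2, r_d) / 1e-6
    # single pair in a box of area L²: p_bound/p_free = K_D / (A_free)
    a_free = L**2 - np.pi * r_d**2
    predicted = kd_nm2 / (kd_nm2 + a_free)
    assert observed == pytest.approx(predicted, abs=0.05)
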