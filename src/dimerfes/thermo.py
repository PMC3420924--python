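"""Dimerization thermodynamics from the separation free-energy profile.

With the monomeric state at F = 0, the surface dimerization constant is

    K_D = (||Ω₀|| / (2π)²) · ∫₀^{r_D} 2πr · e^{−βF(r)} dr        [µm²]

where ||Ω₀|| is the restrained angular area (the sampled fraction of the
full 2π × 2π relative-rotation space of the two protomers) and r_D the
largest separation counted as dimeric.  The in-plane measure 2πr enters
here, not in F(r) itself, which is the plain −kT·log of the r histogram.
On the mole-fraction scale K_X = (N_L/A)·K_D with the lipid surface density
N_L/A, and ΔG_X° = −RT·ln K_X.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KCAL, NM2_TO_UM2, kt
from .fes import FreeEnergyProfile

__all__ = [
    "MembraneSpec",
    "ThermoResult",
    "k_d_from_profile",
    "k_x",
    "delta_g_x",
    "propagate_ci",
]


@dataclass(frozen=True)
class MembraneSpec:
    """Membrane patch parameters: lipid surface density and temperature."""

    lipid_density: float = 1.65e6    # N_L/A, µm⁻²
    temperature: float = 300.0       # K

    def __post_init__(self) -> None:
        if self.lipid_density <= 0:
            raise ValueError("lipid surface density must be positive")


@dataclass
class ThermoResult:
    """Dimerization constants and standard free energy with CIs."""

    k_d: float                                   # µm²
    k_x: float                                   # dimensionless
    delta_g: float                               # kcal/mol
    k_d_ci: tuple[float, float] | None = None
    k_x_ci: tuple[float, float] | None = None
    delta_g_ci: tuple[float, float] | None = None
    r_d: float | None = None                     # nm
    omega0: float | None = None                  # rad²
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        m = self.membrane
        if abs(self.k_x - m.lipid_density * self.k_d) > 1e-9 * max(1.0, self.k_x):
            raise AssertionError("K_X != (N_L/A)·K_D")
        rt = KB_KCAL * m.temperature
        if abs(self.delta_g + rt * np.log(self.k_x)) > 1e-9:
            raise AssertionError("ΔG_X° != −RT·ln K_X")

    def as_dict(self) -> dict:
        return dict(
            k_d_um2=self.k_d, k_x=self.k_x, delta_g_kcal_mol=self.delta_g,
            k_d_ci=list(self.k_d_ci) if self.k_d_ci else None,
            delta_g_ci=list(self.delta_g_ci) if self.delta_g_ci else None,
            r_d_nm=self.r_d, omega0_rad2=self.omega0,
            lipid_density_um2=self.membrane.lipid_density,
            temperature_K=self.membrane.temperature,
        )


def _kd_integral(r: np.ndarray, F: np.ndarray, omega0: float, r_d: float,
                 temperature: float) -> float:
    kT = kt(temperature)
    m = np.isfinite(F)
    r, F = r[m], F[m]
    if r.size < 2:
        raise ValueError("profile has fewer than two sampled bins")
    if r_d > r[-1] + 1e-9:
        raise ValueError(
            f"r_D = {r_d} nm lies beyond the sampled range (max {r[-1]:.3f} nm); "
            "refusing to extrapolate"
        )
    grid = np.linspace(r[0], min(r_d, r[-1]), 2001)
    Fg = np.interp(grid, r, F)
    integrand = 2.0 * np.pi * grid * np.exp(-Fg / kT)
    area_nm2 = np.trapezoid(integrand, grid)
    return omega0 / (2.0 * np.pi) ** 2 * area_nm2 * NM2_TO_UM2


def k_d_from_profile(p: FreeEnergyProfile, omega0: float, r_d: float) -> float:
    """Surface dimerization constant K_D (µm²) from a referenced profile.

    ``p`` must already be offset to the monomeric reference (F = 0 there);
    the integral runs from the lower edge of the sampled grid (the repulsive
    core contributes nothing) up to ``r_D``.
    """
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    if p.reference_range is None:
        raise ValueError(
            "profile must be referenced to the monomeric state first "
            "(use set_reference)"
        )
    return _kd_integral(p.r, p.F, omega0, r_d, p.temperature)


def k_x(k_d: float, m: MembraneSpec) -> float:
    """Mole-fraction association constant K_X = (N_L/A)·K_D."""
    if k_d < 0:
        raise ValueError("K_D must be non-negative")
    return float(m.lipid_density * k_d)


def delta_g_x(kx: float, m: MembraneSpec) -> float:
    """Standard mole-fraction free energy ΔG_X° = −RT·ln K_X (kcal/mol)."""
    if kx <= 0:
        raise ValueError("K_X must be positive for a defined free energy")
    return float(-KB_KCAL * m.temperature * np.log(kx))


def propagate_ci(
    p: FreeEnergyProfile,
    omega0: float,
    r_d: float,
    m: MembraneSpec,
    replicas: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> ThermoResult:
    """K_D, K_X, ΔG_X° with percentile (2.5/97.5) confidence intervals.

    Uses stored bootstrap replicas of the profile when given; otherwise
    perturbs each bin independently with its Gaussian standard error.  With
    zero errors the CI degenerates to the point estimate.
    """
    kd = k_d_from_profile(p, omega0, r_d)
    kx_val = k_x(kd, m)
    dg = delta_g_x(kx_val, m)

    if replicas is not None:
        Fsets = [rep for rep in replicas]
    elif np.any(p.stderr > 0):
        rng = np.random.default_rng(int(seed) % 2**31)
        Fsets = [
            p.F + rng.standard_normal(p.F.shape) * p.stderr
            for _ in range(n_boot)
        ]
    else:
        Fsets = []

    if Fsets:
        kds = []
        for F in Fsets:
            try:
                kds.append(_kd_integral(p.r, np.asarray(F, dtype=float),
                                        omega0, r_d, p.temperature))
            except ValueError:
                continue
        kds = np.array(kds)
        kd_ci = tuple(np.percentile(kds, [2.5, 97.5]))
        kx_ci = (m.lipid_density * kd_ci[0], m.lipid_density * kd_ci[1])
        dg_ci = (delta_g_x(kx_ci[1], m), delta_g_x(kx_ci[0], m))
    else:
        kd_ci = (kd, kd)
        kx_ci = (kx_val, kx_val)
        dg_ci = (dg, dg)

    res = ThermoResult(
        k_d=kd, k_x=kx_val, delta_g=dg,
        k_d_ci=kd_ci, k_x_ci=kx_ci, delta_g_ci=dg_ci,
        r_d=r_d, omega0=omega0, membrane=m,
        provenance=dict(n_replicas=len(Fsets)),
    )
    res.validate()
    return res
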