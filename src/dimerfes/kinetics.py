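"""Diffusion-limited dimerization kinetics in a membrane (2D Smoluchowski).

In two dimensions the diffusion-limited capture rate has no steady state;
at long times it decays logarithmically:

    k_on(t) = 4π D_C / [ln(4 D_C t / R²) − 2γ]

with D_C the sum of the two protomers' diffusion constants, R the contact
radius (the sum of the protomer radii), γ the Euler–Mascheroni constant and
t the experimental diffusion timescale.  Dissociation follows from detailed
balance, k_off = k_on / K_D, and an initial dimer surface density [D]₀
relaxes to the mass-action equilibrium; the dimer half-life is the time at
which the density first reaches [D]₀/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DiffusionSpec",
    "KineticsResult",
    "k_on",
    "k_off",
    "dimer_decay",
    "half_life",
    "evaluate_kinetics",
]

EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class DiffusionSpec:
    """Inputs to the 2D capture-rate estimate; no defaults on purpose —
    these are not derivable from the free-energy calculation.

    Note: the source describes R as the "sum of the protomer ratios", almost
    certainly a typo for radii; it is treated as a contact radius here.
    """

    d_c: float              # sum of protomer diffusion constants, µm²/s
    contact_radius: float   # R, µm
    timescale: float        # t, s

    def __post_init__(self) -> None:
        if min(self.d_c, self.contact_radius, self.timescale) <= 0:
            raise ValueError("all diffusion-spec fields must be positive")
        if 4.0 * self.d_c * self.timescale <= self.contact_radius**2:
            raise ValueError(
                "long-time 2D rate invalid: need 4·D_C·t > R²"
            )


@dataclass
class KineticsResult:
    k_on: float          # µm²/s
    k_off: float         # 1/s
    half_life: float | None   # s; None when equilibrium stays above [D]0/2
    d0: float            # initial dimer density, µm⁻²
    spec: DiffusionSpec = None
    provenance: dict = field(default_factory=dict)


def k_on(d: DiffusionSpec) -> float:
    """Long-time 2D Smoluchowski association rate (µm²/s)."""
    den = np.log(4.0 * d.d_c * d.timescale / d.contact_radius**2) - 2.0 * EULER_GAMMA
    if den <= 0:
        raise ValueError(
            "outside the long-time regime: ln(4·D_C·t/R²) must exceed 2γ "
            f"(got {den + 2 * EULER_GAMMA:.4f} vs {2 * EULER_GAMMA:.4f})"
        )
    return 4.0 * np.pi * d.d_c / den


def k_off(kon: float, k_d: float) -> float:
    """Dissociation rate from detailed balance, k_off = k_on / K_D (1/s)."""
    if k_d <= 0:
        raise ValueError("K_D must be positive")
    return kon / k_d


def _mass_action_roots(kon: float, koff: float, m_tot: float):
    """Roots of k_on·(m_tot − 2d)² − k_off·d = 0 (d1 ≤ d2; d1 is equilibrium)."""
    a = 4.0 * kon
    b = -(4.0 * kon * m_tot + koff)
    c = kon * m_tot**2
    disc = b * b - 4.0 * a * c
    sq = np.sqrt(max(disc, 0.0))
    d1 = (-b - sq) / (2.0 * a)
    d2 = (-b + sq) / (2.0 * a)
    return min(d1, d2), max(d1, d2)


def dimer_decay(d0: float, kon: float, koff: float, t, m0: float = 0.0):
    """Dimer surface density at time t under mass-action kinetics.

    d' = k_on·m² − k_off·d with monomer conservation m = m_tot − 2d,
    m_tot = 2·d0 + m0.  Closed Riccati solution; starts at d0 and approaches
    the mass-action equilibrium as t → ∞.  Pure first-order decay
    d0·exp(−k_off·t) when k_on = 0.
    """
    t = np.asarray(t, dtype=float)
    if d0 < 0 or kon < 0 or koff < 0:
        raise ValueError("inputs must be non-negative")
    if kon == 0.0:
        out = d0 * np.exp(-koff * t)
        return float(out) if out.ndim == 0 else out
    m_tot = 2.0 * d0 + m0
    d1, d2 = _mass_action_roots(kon, koff, m_tot)
    a = 4.0 * kon
    lam = a * (d2 - d1)            # > 0
    if abs(d0 - d2) < 1e-300:
        out = np.full_like(t, d2, dtype=float)
        return float(out) if out.ndim == 0 else out
    q0 = (d0 - d1) / (d0 - d2)
    q = q0 * np.exp(-lam * t)      # (d−d1)/(d−d2) decays toward the d1 root
    out = (d1 - d2 * q) / (1.0 - q)
    return float(out) if out.ndim == 0 else out


def half_life(kon: float, koff: float, d0: float, m0: float = 0.0) -> float:
    """Time at which the dimer density first reaches d0/2 (seconds).

    Equals ln2/k_off for pure dissociation.  Raises when the mass-action
    equilibrium density is at or above d0/2 (the target is never reached).
    """
    if d0 <= 0 or koff <= 0:
        raise ValueError("need d0 > 0 and k_off > 0")
    if kon == 0.0:
        return float(np.log(2.0) / koff)
    m_tot = 2.0 * d0 + m0
    d_eq, _ = _mass_action_roots(kon, koff, m_tot)
    target = 0.5 * d0
    if d_eq >= target:
        raise ValueError(
            f"equilibrium dimer density {d_eq:.4g} ≥ [D]0/2 = {target:.4g}; "
            "no half-life in this regime"
        )
    f = lambda t: dimer_decay(d0, kon, koff, t, m0) - target
    t_hi = np.log(2.0) / koff
    while f(t_hi) > 0:
        t_hi *= 2.0
        if t_hi > 1e18:
            raise RuntimeError("half-life search failed to bracket")
    return float(brentq(f, 0.0, t_hi, xtol=1e-15, rtol=1e-12))


def evaluate_kinetics(spec: DiffusionSpec, k_d: float, d0: float,
                      m0: float = 0.0) -> KineticsResult:
    """k_on, k_off and dimer half-life for a system with constant K_D."""
    kon = k_on(spec)
    koff = k_off(kon, k_d)
    try:
        t_half = half_life(kon, koff, d0, m0)
    except ValueError:
        t_half = None
    return KineticsResult(k_on=kon, k_off=koff, half_life=t_half, d0=d0,
                          spec=spec)
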