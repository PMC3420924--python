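"""Hybrid biasing protocol: umbrella restraint on r, well-tempered
metadynamics on the rotational angles, and steep repulsive walls confining
the angles to the allowed region Ω₀.

Published bias parameters carried as defaults: umbrella force constant
2400 kcal/(mol·nm²); initial Gaussian height 0.12 kcal/mol; deposition
stride 10 ps; σ_M = 0.035 rad; bias factor γ = 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import kt

__all__ = [
    "UmbrellaWindow",
    "MetadConfig",
    "HillsLog",
    "AngularRestraint",
    "BiasProtocol",
    "umbrella_energy",
    "metad_bias",
    "deposit_hill",
    "wall_energy",
    "omega_norm",
    "layout_windows",
]

WALL_EXP = 4
DEFAULT_WALL_KAPPA = 1e4  # kcal/(mol·rad⁴); wall forces dwarf kT within 0.05 rad


@dataclass(frozen=True)
class UmbrellaWindow:
    """Harmonic restraint ½k(r−r_i)² on the separation CV."""

    center: float                      # r_i, nm
    force_constant: float = 2400.0     # kcal/(mol·nm²)
    index: int = 0

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")


@dataclass(frozen=True)
class MetadConfig:
    """Well-tempered metadynamics parameters for the angle CVs."""

    height: float = 0.12          # w0, kcal/mol
    sigma: float = 0.035          # σ_M, rad
    stride: float = 10.0          # deposition stride, ps
    bias_factor: float = 15.0     # γ
    grid_resolution: float = 0.01  # rad; cached-bias grid spacing

    def __post_init__(self) -> None:
        if self.height <= 0 or self.sigma <= 0:
            raise ValueError("height and sigma must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must exceed 1")


@dataclass
class HillsLog:
    """Deposited-Gaussian history defining the time-dependent bias.

    ``centers`` has one column per biased CV (1 or 2); ``sigmas`` likewise.
    """

    times: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    heights: np.ndarray
    bias_factor: float = 15.0
    temperature: float = 300.0
    cv_names: tuple[str, ...] = ("theta_a", "theta_b")

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        n = self.times.shape[0]
        ncv = len(self.cv_names)
        self.centers = np.asarray(self.centers, dtype=float).reshape(n, ncv)
        self.sigmas = np.asarray(self.sigmas, dtype=float).reshape(n, ncv)
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        if n and np.any(np.diff(self.times) < 0):
            raise ValueError("hill deposition times must be non-decreasing")
        if np.any(self.heights <= 0):
            raise ValueError("hill heights must be strictly positive")

    def __len__(self) -> int:
        return self.times.shape[0]

    @classmethod
    def empty(cls, cv_names=("theta_a", "theta_b"), bias_factor=15.0,
              temperature=300.0) -> "HillsLog":
        ncv = len(cv_names)
        return cls(
            times=np.zeros(0), centers=np.zeros((0, ncv)),
            sigmas=np.zeros((0, ncv)), heights=np.zeros(0),
            bias_factor=bias_factor, temperature=temperature,
            cv_names=tuple(cv_names),
        )


@dataclass(frozen=True)
class AngularRestraint:
    """Steep repulsive walls confining an angle CV to [min_theta, max_theta]."""

    min_theta: float
    max_theta: float
    kappa: float = DEFAULT_WALL_KAPPA
    exponent: int = WALL_EXP

    def __post_init__(self) -> None:
        if self.max_theta <= self.min_theta:
            raise ValueError("max_theta must exceed min_theta")

    @property
    def width(self) -> float:
        return self.max_theta - self.min_theta


@dataclass
class BiasProtocol:
    """Full per-window bias: umbrella on one CV, metadynamics + walls on others."""

    umbrella: UmbrellaWindow | None = None
    umbrella_dim: int = 0
    restraints: dict = field(default_factory=dict)   # CV index -> AngularRestraint
    metad: MetadConfig | None = None
    metad_dims: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        if self.metad is not None and not 1 <= len(self.metad_dims) <= 2:
            raise ValueError("metadynamics supports 1 or 2 biased CVs")


# ---------------------------------------------------------------- energies

def umbrella_energy(w: UmbrellaWindow, r) -> float | np.ndarray:
    """½·k·(r − r_i)² in kcal/mol."""
    r = np.asarray(r, dtype=float)
    e = 0.5 * w.force_constant * (r - w.center) ** 2
    return float(e) if e.ndim == 0 else e


def wall_energy(a: AngularRestraint, theta) -> float | np.ndarray:
    """0 inside [min, max]; κ·(excess)^exponent outside."""
    th = np.asarray(theta, dtype=float)
    exc = np.clip(a.min_theta - th, 0.0, None) + np.clip(th - a.max_theta, 0.0, None)
    e = a.kappa * exc**a.exponent
    return float(e) if e.ndim == 0 else e


def omega_norm(a: AngularRestraint, sigma_m: float = 0.035) -> float:
    """Allowed angular area ||Ω₀|| = (maxθ − minθ − σ_M)² in rad².

    The Gaussian width σ_M is subtracted from the wall-to-wall range because
    hills of finite width cannot center closer than σ_M to the walls.
    """
    eff = a.width - sigma_m
    if eff <= 0:
        raise ValueError(
            f"angular range {a.width:.4g} rad is not larger than sigma_M {sigma_m:.4g}"
        )
    return eff * eff


def metad_bias(hills: HillsLog, points, time: float | None = None) -> np.ndarray | float:
    """Exact metadynamics bias V(s, t): direct sum over deposited hills.

    ``points`` is one state (length-ncv) or a batch (m, ncv); only hills with
    deposition time ≤ ``time`` contribute (all hills if ``time`` is None).
    Hills are non-periodic (θ = arccos lives on [0, π]).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    scalar = np.asarray(points).ndim == 1
    if len(hills) == 0:
        out = np.zeros(pts.shape[0])
        return float(out[0]) if scalar else out
    sel = slice(None) if time is None else hills.times <= time + 1e-12
    c = hills.centers[sel]
    s = hills.sigmas[sel]
    h = hills.heights[sel]
    # (m, nhills) exponent matrix; fine at the scales used in analysis
    expo = np.zeros((pts.shape[0], c.shape[0]))
    for k in range(pts.shape[1]):
        expo += ((pts[:, k, None] - c[None, :, k]) / s[None, :, k]) ** 2
    v = (h[None, :] * np.exp(-0.5 * expo)).sum(axis=1)
    return float(v[0]) if scalar else v


def deposit_hill(hills: HillsLog, cfg: MetadConfig, state, time: float,
                 temperature: float = 300.0) -> HillsLog:
    """Append one well-tempered hill at ``state``.

    Height follows the well-tempering rule w = w0·exp(−V(s,t)/((γ−1)k_BT)),
    so heights decay as bias accumulates and the deposited bias converges to
    −(1−1/γ)·F plus a constant.
    """
    state = np.atleast_1d(np.asarray(state, dtype=float))
    v_here = metad_bias(hills, state, time)
    h = cfg.height * np.exp(-v_here / ((cfg.bias_factor - 1.0) * kt(temperature)))
    ncv = state.shape[0]
    return HillsLog(
        times=np.append(hills.times, time),
        centers=np.vstack([hills.centers, state[None, :]]) if len(hills)
        else state[None, :],
        sigmas=np.vstack([hills.sigmas, np.full((1, ncv), cfg.sigma)]) if len(hills)
        else np.full((1, ncv), cfg.sigma),
        heights=np.append(hills.heights, h),
        bias_factor=cfg.bias_factor,
        temperature=temperature,
        cv_names=hills.cv_names,
    )


def layout_windows(r_range: tuple[float, float], n_windows: int = 40,
                   force_constant: float = 2400.0) -> list[UmbrellaWindow]:
    """Uniform ladder of umbrella windows spanning ``r_range``.

    Extra windows can be inserted afterwards where the reweighted
    distribution turns out to be insufficiently sampled.
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    centers = np.linspace(r_range[0], r_range[1], n_windows)
    return [
        UmbrellaWindow(center=float(c), force_constant=force_constant, index=i)
        for i, c in enumerate(centers)
    ]
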