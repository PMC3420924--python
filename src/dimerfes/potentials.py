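"""Model potentials over collective-variable space with known ground truth.

These potentials stand in for the molecular system in validation studies:
diffusive dynamics on a known U(r, θa, θb) lets the whole biased-sampling /
reconstruction pipeline be checked against an exact reference, because the
marginal free energy F_exact(r) is available by numerical quadrature.

A potential is a sum of (axis-aligned) Gaussian wells or barriers, an
optional harmonic term, and optional steep quartic confining walls, over an
explicit rectangular domain.  A 1D tabulated form (linear interpolation) is
also supported for testing, but cannot be simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import kt

__all__ = ["ModelPotential", "make_paper_like_potential", "evaluate_potential"]

_WALL_EXP = 4


@dataclass
class ModelPotential:
    """Closed-form potential U over a rectangular CV domain.

    Parameters are plain arrays so the Langevin integrator can consume them
    directly: ``well_height`` (kcal/mol, negative = attractive well),
    ``well_center``/``well_sigma`` with one row per well and one column per
    CV; harmonic ½k(x−x0)² per dimension; quartic walls κ·(excess)⁴ outside
    [wall_lo, wall_hi].
    """

    cv_names: tuple[str, ...]
    domain_lo: np.ndarray
    domain_hi: np.ndarray
    well_height: np.ndarray = field(default_factory=lambda: np.zeros(0))
    well_center: np.ndarray | None = None
    well_sigma: np.ndarray | None = None
    harmonic_k: np.ndarray | None = None
    harmonic_center: np.ndarray | None = None
    wall_lo: np.ndarray | None = None
    wall_hi: np.ndarray | None = None
    wall_kappa: np.ndarray | None = None
    table_x: np.ndarray | None = None
    table_y: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = self.ndim
        self.domain_lo = np.asarray(self.domain_lo, dtype=float)
        self.domain_hi = np.asarray(self.domain_hi, dtype=float)
        self.well_height = np.atleast_1d(np.asarray(self.well_height, dtype=float))
        n = self.well_height.shape[0]
        if self.well_center is None:
            self.well_center = np.zeros((n, d))
        if self.well_sigma is None:
            self.well_sigma = np.ones((n, d))
        self.well_center = np.asarray(self.well_center, dtype=float).reshape(n, d)
        self.well_sigma = np.asarray(self.well_sigma, dtype=float).reshape(n, d)
        for name in ("harmonic_k", "harmonic_center", "wall_kappa"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(d))
            else:
                setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.wall_lo is None:
            self.wall_lo = np.full(d, -np.inf)
        if self.wall_hi is None:
            self.wall_hi = np.full(d, np.inf)
        self.wall_lo = np.asarray(self.wall_lo, dtype=float)
        self.wall_hi = np.asarray(self.wall_hi, dtype=float)
        if np.any(self.domain_hi <= self.domain_lo):
            raise ValueError("domain_hi must exceed domain_lo in every dimension")

    # ------------------------------------------------------------------ api
    @property
    def ndim(self) -> int:
        return len(self.cv_names)

    @property
    def is_tabulated(self) -> bool:
        return self.table_x is not None

    def _check_domain(self, x: np.ndarray) -> None:
        lo, hi = self.domain_lo, self.domain_hi
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            raise ValueError(
                f"state {x} outside potential domain [{lo}, {hi}]"
            )

    def energy(self, x, check_domain: bool = True) -> np.ndarray | float:
        """U at one state (length-d array) or a batch (m, d); kcal/mol."""
        arr = np.asarray(x, dtype=float)
        scalar = arr.ndim == 1
        pts = np.atleast_2d(arr)
        if pts.shape[1] != self.ndim:
            raise ValueError(f"expected {self.ndim}-dimensional states")
        if check_domain:
            for p in pts:
                self._check_domain(p)
        if self.is_tabulated:
            u = np.interp(pts[:, 0], self.table_x, self.table_y)
            return float(u[0]) if scalar else u
        u = np.zeros(pts.shape[0])
        for a, c, s in zip(self.well_height, self.well_center, self.well_sigma):
            u += a * np.exp(-0.5 * (((pts - c) / s) ** 2).sum(axis=1))
        u += (0.5 * self.harmonic_k * (pts - self.harmonic_center) ** 2).sum(axis=1)
        lo_exc = np.clip(self.wall_lo - pts, 0.0, None)
        hi_exc = np.clip(pts - self.wall_hi, 0.0, None)
        with np.errstate(invalid="ignore"):
            wl = np.where(np.isfinite(self.wall_lo), self.wall_kappa * lo_exc**_WALL_EXP, 0.0)
            wh = np.where(np.isfinite(self.wall_hi), self.wall_kappa * hi_exc**_WALL_EXP, 0.0)
        u += wl.sum(axis=1) + wh.sum(axis=1)
        return float(u[0]) if scalar else u

    def gradient(self, x) -> np.ndarray:
        """Analytic ∇U at one state."""
        p = np.asarray(x, dtype=float)
        if self.is_tabulated:
            raise NotImplementedError("tabulated potentials have no analytic gradient")
        g = np.zeros(self.ndim)
        for a, c, s in zip(self.well_height, self.well_center, self.well_sigma):
            e = a * np.exp(-0.5 * (((p - c) / s) ** 2).sum())
            g += e * (-(p - c) / s**2)
        g += self.harmonic_k * (p - self.harmonic_center)
        lo_exc = np.clip(self.wall_lo - p, 0.0, None)
        hi_exc = np.clip(p - self.wall_hi, 0.0, None)
        k = np.where(np.isfinite(self.wall_lo), self.wall_kappa, 0.0)
        g += -_WALL_EXP * k * lo_exc ** (_WALL_EXP - 1)
        k = np.where(np.isfinite(self.wall_hi), self.wall_kappa, 0.0)
        g += _WALL_EXP * k * hi_exc ** (_WALL_EXP - 1)
        return g

    # -------------------------------------------------------- exact marginal
    def exact_free_energy_r(
        self,
        r_grid: np.ndarray,
        temperature: float = 300.0,
        n_quad: int = 201,
        box=None,
    ) -> np.ndarray:
        """Ground-truth marginal F(r) = −kT ln ⟨e^{−βU}⟩_Ω by quadrature.

        The average runs over the non-r dimensions with flat measure on
        ``box`` (list of (lo, hi) per non-r dimension; defaults to the
        domain), so in regions where U ≡ 0 the marginal is 0.  Pass the
        restrained angular interval as ``box`` when comparing against
        sampling that confines the angles.  For a 1D potential this is just
        U(r) itself.
        """
        kT = kt(temperature)
        r_grid = np.asarray(r_grid, dtype=float)
        if self.ndim == 1:
            return np.asarray(self.energy(r_grid[:, None], check_domain=False))
        if box is None:
            box = [
                (self.domain_lo[i], self.domain_hi[i]) for i in range(1, self.ndim)
            ]
        axes = [np.linspace(lo, hi, n_quad) for lo, hi in box]
        mesh = np.meshgrid(*axes, indexing="ij")
        ang = np.stack([m.ravel() for m in mesh], axis=1)
        F = np.empty_like(r_grid)
        for j, r in enumerate(r_grid):
            pts = np.concatenate(
                [np.full((ang.shape[0], 1), r), ang], axis=1
            )
            u = self.energy(pts, check_domain=False)
            w = np.exp(-u / kT).reshape(mesh[0].shape)
            for ax in reversed(axes):
                w = np.trapezoid(w, ax, axis=-1)
            vol = float(np.prod([hi - lo for lo, hi in box]))
            F[j] = -kT * np.log(w / vol)
        return F

    # ------------------------------------------------------------- builders
    @classmethod
    def gaussian_wells(cls, cv_names, heights, centers, sigmas, domain, **kw):
        lo, hi = np.asarray(domain, dtype=float).reshape(2, -1)
        return cls(
            cv_names=tuple(cv_names),
            domain_lo=lo,
            domain_hi=hi,
            well_height=np.asarray(heights, dtype=float),
            well_center=np.asarray(centers, dtype=float),
            well_sigma=np.asarray(sigmas, dtype=float),
            **kw,
        )

    @classmethod
    def harmonic(cls, k, center, domain, cv_name="r"):
        lo, hi = np.asarray(domain, dtype=float).reshape(2, -1)
        d = lo.shape[0]
        return cls(
            cv_names=(cv_name,) * d if d > 1 else (cv_name,),
            domain_lo=lo,
            domain_hi=hi,
            harmonic_k=np.full(d, float(k)),
            harmonic_center=np.full(d, float(center)),
        )

    @classmethod
    def double_well(cls, centers=(0.7, 1.3), depth=3.0, sigma=0.12,
                    domain=(0.3, 1.7), kappa=1e4, cv_name="r"):
        """1D double well: two Gaussian wells inside quartic confining walls."""
        lo, hi = float(domain[0]), float(domain[1])
        return cls(
            cv_names=(cv_name,),
            domain_lo=np.array([lo - 0.5]),
            domain_hi=np.array([hi + 0.5]),
            well_height=np.array([-depth, -depth]),
            well_center=np.array([[centers[0]], [centers[1]]]),
            well_sigma=np.full((2, 1), sigma),
            wall_lo=np.array([lo]),
            wall_hi=np.array([hi]),
            wall_kappa=np.array([kappa]),
        )

    @classmethod
    def tabulated(cls, x, y, cv_name="r"):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape or x.shape[0] < 2:
            raise ValueError("tabulated form needs matching 1D x, y with ≥ 2 rows")
        if np.any(np.diff(x) <= 0):
            raise ValueError("table x must be strictly increasing")
        return cls(
            cv_names=(cv_name,),
            domain_lo=np.array([x[0]]),
            domain_hi=np.array([x[-1]]),
            table_x=x,
            table_y=y,
        )


def evaluate_potential(p: ModelPotential, state) -> float:
    """Energy (kcal/mol) of ``state`` (CVState or array) under ``p``."""
    x = state.as_array() if hasattr(state, "as_array") else np.asarray(state, float)
    return float(p.energy(x[: p.ndim]))


# --------------------------------------------------------------- presets

#: Restrained angular intervals per interface, chosen so that the allowed
#: angular area (range − σ_M)² matches the published 0.51² (TM4/3) and 0.46²
#: (TM1/H8) values with σ_M = 0.035 rad.
_PRESETS = {
    "TM1/H8": dict(
        r_min=3.7, depth=-12.0, r_sigma=0.08,
        theta_minima=[(0.47, 0.47)],
        theta_lo=0.2225, theta_hi=0.7175,       # width 0.495 = 0.46 + σ_M
        monomer_range=(5.5, 5.9),
        r_domain=(3.0, 6.3), r_wall=(3.2, 6.1),
    ),
    "TM4/3": dict(
        r_min=3.45, depth=-4.8, r_sigma=0.07,
        theta_minima=[(0.2, 0.4), (0.4, 0.2), (0.45, 0.45)],
        theta_lo=0.0525, theta_hi=0.5975,       # width 0.545 = 0.51 + σ_M
        monomer_range=(4.5, 4.8),
        r_domain=(2.6, 5.2), r_wall=(2.8, 5.0),
    ),
}

#: Shallow angular corrugation (kcal/mol).  Kept small so the angle-marginal
#: F(r) equals the configured well depth to within the angular-entropy term.
_ANGULAR_AMPLITUDE = 0.05
_ANGULAR_SIGMA = 0.12


def make_paper_like_potential(interface: str = "TM1/H8") -> ModelPotential:
    """Model potential emulating a receptor-dimer free-energy landscape.

    A single dimer well in r (depth −12.0 kcal/mol at 3.7 nm for the TM1/H8
    preset; −4.8 at 3.45 nm for TM4/3), flat beyond the monomeric range, with
    shallow angular minima near the published Θ locations.  The angular
    corrugation is gauged to zero at its deepest minimum so that U at the
    global minimum equals the configured depth exactly.
    """
    if interface not in _PRESETS:
        raise ValueError(f"unknown interface {interface!r}; use {sorted(_PRESETS)}")
    p = _PRESETS[interface]
    d = 3
    heights, centers, sigmas = [], [], []
    # r well carries the full depth; effectively angle-independent
    th0 = p["theta_minima"][0]
    heights.append(p["depth"])
    centers.append([p["r_min"], 0.0, 0.0])
    sigmas.append([p["r_sigma"], 1e6, 1e6])
    # shallow angular wells, localized at the dimer separation
    for ta, tb in p["theta_minima"]:
        heights.append(-_ANGULAR_AMPLITUDE)
        centers.append([p["r_min"], ta, tb])
        sigmas.append([3 * p["r_sigma"], _ANGULAR_SIGMA, _ANGULAR_SIGMA])
    pot = ModelPotential(
        cv_names=("r", "theta_a", "theta_b"),
        domain_lo=np.array([p["r_domain"][0], 0.0, 0.0]),
        domain_hi=np.array([p["r_domain"][1], np.pi, np.pi]),
        well_height=np.array(heights),
        well_center=np.array(centers),
        well_sigma=np.array(sigmas),
        wall_lo=np.array([p["r_wall"][0], -np.inf, -np.inf]),
        wall_hi=np.array([p["r_wall"][1], np.inf, np.inf]),
        wall_kappa=np.array([1e4, 0.0, 0.0]),
        meta=dict(
            interface=interface,
            r_min=p["r_min"],
            depth=p["depth"],
            theta_minima=p["theta_minima"],
            theta_lo=p["theta_lo"],
            theta_hi=p["theta_hi"],
            monomer_range=p["monomer_range"],
            r_wall=p["r_wall"],
        ),
    )
    # gauge: make U at (r_min, Θ1) equal the configured depth exactly
    x0 = np.array([p["r_min"], th0[0], th0[1]])
    delta = pot.energy(x0) - p["depth"]
    if abs(delta) > 1e-12:
        pot.well_height[0] -= delta
    return pot
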