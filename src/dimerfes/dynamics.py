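"""Overdamped Langevin sampling of collective variables on model potentials.

This is the synthetic-data engine of the package: it emulates the diffusive
CV dynamics of a coarse-grained membrane-protein simulation (a dimer well in
r, restrained angular ranges) with a known ground truth, so the biased
sampling and reconstruction machinery can be validated end to end.  Only
stationary statistics matter for free-energy recovery, hence Brownian
(inertia-free) dynamics: drift −D∇U/kT, noise variance 2DΔt per CV per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from ._integrate import integrate
from .biasing import BiasProtocol, HillsLog, MetadConfig, umbrella_energy, wall_energy
from .constants import kt
from .geometry import CVState
from .potentials import ModelPotential

__all__ = ["DynamicsConfig", "CVTrajectory", "simulate"]


@dataclass
class DynamicsConfig:
    """Integration parameters.

    ``diffusion`` is one constant per CV (nm²/ps for r, rad²/ps for angles)
    or a scalar applied to all.  ``output_stride`` and the metadynamics
    deposition stride are in ps and are rounded to whole steps.
    """

    temperature: float = 300.0
    diffusion: float | tuple = 5e-4
    timestep: float = 0.02          # ps
    n_steps: int = 100_000
    output_stride: float = 0.2      # ps
    seed: int = 0
    initial_state: np.ndarray | None = None
    max_step: float = 1.0           # divergence guard, nm or rad per step

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if np.any(np.asarray(self.diffusion) <= 0):
            raise ValueError("diffusion constants must be positive")
        if self.output_stride < self.timestep:
            raise ValueError("output_stride must be at least one timestep")

    def diffusion_array(self, ndim: int) -> np.ndarray:
        d = np.atleast_1d(np.asarray(self.diffusion, dtype=float))
        if d.shape[0] == 1:
            d = np.full(ndim, d[0])
        if d.shape[0] != ndim:
            raise ValueError("diffusion must be scalar or one value per CV")
        return d

    def as_dict(self) -> dict:
        return dict(
            temperature=self.temperature,
            diffusion=np.atleast_1d(np.asarray(self.diffusion)).tolist(),
            timestep=self.timestep,
            n_steps=int(self.n_steps),
            output_stride=self.output_stride,
            seed=int(self.seed),
        )


@dataclass
class CVTrajectory:
    """Time series of collective variables for one window.

    ``bias`` is the instantaneous *metadynamics* bias V(θ(t), t) in kcal/mol
    (zero for unbiased runs); the static umbrella and wall energies are
    recomputable from the coordinates and the window parameters.
    """

    times: np.ndarray
    data: np.ndarray                      # (n_frames, n_cv)
    cv_names: tuple[str, ...]
    bias: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.bias is None:
            self.bias = np.zeros(self.times.shape[0])
        self.bias = np.asarray(self.bias, dtype=float)
        n = self.times.shape[0]
        if self.data.shape[0] != n or self.bias.shape[0] != n:
            raise ValueError("times, data and bias must have equal length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.cv_names) != self.data.shape[1]:
            raise ValueError("cv_names must match the data columns")

    def __len__(self) -> int:
        return self.times.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.cv_names.index(name)]

    @property
    def r(self) -> np.ndarray:
        return self.column("r")

    @property
    def states(self) -> Iterator[CVState]:
        """Frames as CVState objects (requires the standard 3-CV layout)."""
        ia = self.cv_names.index("theta_a")
        ib = self.cv_names.index("theta_b")
        ir = self.cv_names.index("r")
        for row in self.data:
            yield CVState(r=row[ir], theta_a=row[ia], theta_b=row[ib])


def _metad_grid_bounds(dim, bias: BiasProtocol, p: ModelPotential,
                       margin: float = 0.15) -> tuple[float, float]:
    if dim in bias.restraints:
        rst = bias.restraints[dim]
        return rst.min_theta - margin, rst.max_theta + margin
    lo = p.wall_lo[dim] if np.isfinite(p.wall_lo[dim]) else p.domain_lo[dim]
    hi = p.wall_hi[dim] if np.isfinite(p.wall_hi[dim]) else p.domain_hi[dim]
    return lo - margin, hi + margin


def simulate(
    p: ModelPotential,
    cfg: DynamicsConfig,
    bias: BiasProtocol | Callable | None = None,
) -> tuple[CVTrajectory, HillsLog | None]:
    """Run overdamped Langevin dynamics of the CVs on potential ``p``.

    With no bias the long-time stationary distribution is the Boltzmann
    distribution of ``p`` at ``cfg.temperature``.  A ``BiasProtocol`` adds
    the umbrella restraint, angular walls and well-tempered metadynamics; a
    plain callable ``bias(time, state) -> energy`` is also accepted (slow
    pure-Python path, for testing custom biases).

    Returns the trajectory and the deposited-hills log (None when
    metadynamics is off).  Raises if any single step exceeds
    ``cfg.max_step`` (timestep too large for the forces present).
    """
    if p.is_tabulated:
        raise ValueError("tabulated potentials cannot be simulated")
    if callable(bias) and not isinstance(bias, BiasProtocol):
        return _simulate_callable(p, cfg, bias), None

    d = p.ndim
    bias = bias or BiasProtocol(umbrella=None, metad=None, restraints={})
    D = cfg.diffusion_array(d)
    kT = kt(cfg.temperature)
    out_stride = max(1, int(round(cfg.output_stride / cfg.timestep)))

    umb_k = np.zeros(d)
    umb_c = np.zeros(d)
    if bias.umbrella is not None:
        umb_k[bias.umbrella_dim] = bias.umbrella.force_constant
        umb_c[bias.umbrella_dim] = bias.umbrella.center
    bwall_lo = np.full(d, -np.inf)
    bwall_hi = np.full(d, np.inf)
    bwall_k = np.zeros(d)
    for dim, rst in bias.restraints.items():
        bwall_lo[dim] = rst.min_theta
        bwall_hi[dim] = rst.max_theta
        bwall_k[dim] = rst.kappa

    if bias.metad is not None:
        md = bias.metad
        md_dim0 = bias.metad_dims[0]
        md_dim1 = bias.metad_dims[1] if len(bias.metad_dims) > 1 else -1
        md_stride = max(1, int(round(md.stride / cfg.timestep)))
        glo0, ghi0 = _metad_grid_bounds(md_dim0, bias, p)
        gn0 = max(2, int(np.ceil((ghi0 - glo0) / md.grid_resolution)) + 1)
        if md_dim1 >= 0:
            glo1, ghi1 = _metad_grid_bounds(md_dim1, bias, p)
            gn1 = max(2, int(np.ceil((ghi1 - glo1) / md.grid_resolution)) + 1)
        else:
            glo1, ghi1, gn1 = 0.0, 1.0, 1
        md_args = (md_dim0, md_dim1, md.height, md.sigma, md.sigma,
                   md.bias_factor, md_stride, glo0, ghi0, gn0, glo1, ghi1, gn1)
    else:
        md_args = (-1, -1, 0.0, 1.0, 1.0, 15.0, 1, 0.0, 1.0, 2, 0.0, 1.0, 1)

    x0 = _initial_state(p, cfg, bias)
    seed = int(cfg.seed) % 2**31

    (times, X, vbias, h_t, h_c0, h_c1, h_h, diverged) = integrate(
        x0, D, cfg.timestep, int(cfg.n_steps), out_stride, kT, seed,
        cfg.max_step,
        p.well_height, p.well_center, p.well_sigma,
        p.harmonic_k, p.harmonic_center,
        p.wall_lo, p.wall_hi, p.wall_kappa,
        umb_k, umb_c, bwall_lo, bwall_hi, bwall_k,
        *md_args,
    )
    if diverged:
        raise RuntimeError(
            "integration diverged (per-step displacement exceeded "
            f"{cfg.max_step}); reduce the timestep"
        )

    prov = dict(config=cfg.as_dict(), seed=seed,
                bias=_describe_bias(bias), potential=p.meta or p.cv_names)
    traj = CVTrajectory(times=times, data=X, cv_names=p.cv_names,
                        bias=vbias, provenance=prov)
    hills = None
    if bias.metad is not None:
        ncv = 1 if md_args[1] < 0 else 2
        centers = h_c0[:, None] if ncv == 1 else np.stack([h_c0, h_c1], axis=1)
        hills = HillsLog(
            times=h_t,
            centers=centers,
            sigmas=np.full((h_t.shape[0], ncv), bias.metad.sigma),
            heights=h_h,
            bias_factor=bias.metad.bias_factor,
            temperature=cfg.temperature,
            cv_names=tuple(p.cv_names[i] for i in bias.metad_dims),
        )
    return traj, hills


def _initial_state(p: ModelPotential, cfg: DynamicsConfig,
                   bias: BiasProtocol) -> np.ndarray:
    if cfg.initial_state is not None:
        x0 = np.asarray(cfg.initial_state, dtype=float).copy()
        if x0.shape[0] != p.ndim:
            raise ValueError("initial_state must have one entry per CV")
        return x0
    x0 = np.empty(p.ndim)
    for i in range(p.ndim):
        if bias.umbrella is not None and i == bias.umbrella_dim:
            x0[i] = bias.umbrella.center
        elif i in bias.restraints:
            rst = bias.restraints[i]
            x0[i] = 0.5 * (rst.min_theta + rst.max_theta)
        elif np.isfinite(p.wall_lo[i]) and np.isfinite(p.wall_hi[i]):
            x0[i] = 0.5 * (p.wall_lo[i] + p.wall_hi[i])
        else:
            x0[i] = 0.5 * (p.domain_lo[i] + p.domain_hi[i])
    return x0


def _describe_bias(bias: BiasProtocol) -> dict:
    out: dict = {}
    if bias.umbrella is not None:
        out["umbrella"] = dict(center=bias.umbrella.center,
                               force_constant=bias.umbrella.force_constant,
                               dim=bias.umbrella_dim)
    if bias.restraints:
        out["restraints"] = {
            int(k): dict(min=v.min_theta, max=v.max_theta, kappa=v.kappa)
            for k, v in bias.restraints.items()
        }
    if bias.metad is not None:
        out["metad"] = dict(height=bias.metad.height, sigma=bias.metad.sigma,
                            stride=bias.metad.stride,
                            bias_factor=bias.metad.bias_factor,
                            dims=list(bias.metad_dims))
    return out


def _simulate_callable(p: ModelPotential, cfg: DynamicsConfig,
                       bias_fn: Callable) -> CVTrajectory:
    """Pure-Python path for an arbitrary time-dependent bias (slow)."""
    d = p.ndim
    D = cfg.diffusion_array(d)
    kT = kt(cfg.temperature)
    out_stride = max(1, int(round(cfg.output_stride / cfg.timestep)))
    rng = np.random.default_rng(int(cfg.seed) % 2**31)
    x = _initial_state(p, cfg, BiasProtocol(umbrella=None, metad=None))
    eps = 1e-6
    times, frames, biases = [0.0], [x.copy()], [float(bias_fn(0.0, x))]
    for step in range(1, int(cfg.n_steps) + 1):
        t = step * cfg.timestep
        g = p.gradient(x)
        b0 = bias_fn(t, x)
        for i in range(d):
            xp = x.copy()
            xp[i] += eps
            g[i] += (bias_fn(t, xp) - b0) / eps
        dx = -(D / kT) * g * cfg.timestep + rng.standard_normal(d) * np.sqrt(
            2 * D * cfg.timestep
        )
        if np.any(np.abs(dx) > cfg.max_step):
            raise RuntimeError("integration diverged; reduce the timestep")
        x = x + dx
        if step % out_stride == 0:
            times.append(t)
            frames.append(x.copy())
            biases.append(float(bias_fn(t, x)))
    return CVTrajectory(
        times=np.array(times), data=np.array(frames), cv_names=p.cv_names,
        bias=np.array(biases),
        provenance=dict(config=cfg.as_dict(), bias="callable"),
    )
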