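"""End-to-end orchestration: windows → sampling → unbias → WHAM → thermo.

``run_pipeline`` executes the full protocol on a preset model potential:
umbrella windows along r, each with well-tempered metadynamics on the
angles inside the restrained region, metadynamics reweighting, WHAM
reconstruction of F(r) with block-bootstrap errors, the angular FES at the
dimer minimum, and conversion to K_D / K_X / ΔG_X° (plus kinetics when
diffusion parameters are supplied).  Everything is deterministic under the
master seed; each stage's inputs and outputs are plain text files in the
run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as dfio
from .biasing import (AngularRestraint, BiasProtocol, MetadConfig,
                      UmbrellaWindow, layout_windows, omega_norm, wall_energy)
from .dynamics import DynamicsConfig, simulate
from .fes import (FreeEnergyProfile, WeightedSamples, angular_fes,
                  bootstrap_errors, find_minima, reweight_metad, set_reference,
                  wham)
from .kinetics import DiffusionSpec, evaluate_kinetics
from .potentials import ModelPotential, make_paper_like_potential
from .thermo import MembraneSpec, propagate_ci

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("dimerfes")

_SEED_STRIDE = 7919  # prime offset deriving per-window seeds from the master


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration for a full run.

    Fields left at None are filled from the interface preset (window range,
    angular restraint, monomeric reference range, r_D).
    """

    interface: str = "TM1/H8"
    n_windows: int = 48
    r_range: tuple | None = None
    force_constant: float = 2400.0
    # metadynamics on the angles
    metad_height: float = 0.12
    metad_sigma: float = 0.035
    metad_stride: float = 10.0
    bias_factor: float = 15.0
    grid_resolution: float = 0.01
    # restraint
    theta_range: tuple | None = None
    wall_kappa: float = 1e4
    # dynamics; the timestep keeps D·k_eff·Δt/kT ≲ 0.02 for the stiffest
    # umbrella+well curvature, where the Euler–Maruyama stationary bias is
    # negligible
    temperature: float = 300.0
    diffusion: float = 5e-4
    timestep: float = 0.005
    n_steps: int = 400_000
    output_stride: float = 0.4
    # analysis
    bin_width: float = 0.02
    reference_range: tuple | None = None
    r_d: float | None = None
    n_boot: int = 16
    angular_slice_halfwidth: float = 0.03
    angular_resolution: float = 0.04
    equilibration_fraction: float = 0.05
    # conversions
    lipid_density: float = 1.65e6
    # kinetics (all-or-nothing; optional)
    kinetics_d_c: float | None = None
    kinetics_contact_radius: float | None = None
    kinetics_timescale: float | None = None
    kinetics_d0: float | None = None
    seed: int = 0

    def resolved(self) -> "PipelineConfig":
        """Fill preset-dependent defaults from the interface geometry."""
        pot = make_paper_like_potential(self.interface)
        meta = pot.meta
        out = PipelineConfig(**asdict(self))
        if out.r_range is None:
            lo, hi = meta["r_wall"]
            out.r_range = (lo + 0.2, hi - 0.1)
        if out.theta_range is None:
            out.theta_range = (meta["theta_lo"], meta["theta_hi"])
        if out.reference_range is None:
            out.reference_range = meta["monomer_range"]
        if out.r_d is None:
            out.r_d = out.reference_range[0]
        out.r_range = tuple(float(x) for x in out.r_range)
        out.theta_range = tuple(float(x) for x in out.theta_range)
        out.reference_range = tuple(float(x) for x in out.reference_range)
        return out

    # -- lossless text round trip
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("r_range", "theta_range", "reference_range"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PipelineResult:
    profile: FreeEnergyProfile
    thermo: object
    angular: object
    kinetics: object | None
    summary: dict
    outdir: Path | None


def _window_seed(master: int, index: int) -> int:
    return (int(master) + _SEED_STRIDE * (index + 1)) % 2**31


def sample_windows(cfg: PipelineConfig, pot: ModelPotential,
                   outdir: Path | None = None):
    """Simulate all umbrella windows; returns (windows, trajs, hills)."""
    restraint = AngularRestraint(cfg.theta_range[0], cfg.theta_range[1],
                                 kappa=cfg.wall_kappa)
    metad = MetadConfig(height=cfg.metad_height, sigma=cfg.metad_sigma,
                        stride=cfg.metad_stride, bias_factor=cfg.bias_factor,
                        grid_resolution=cfg.grid_resolution)
    umbrellas = layout_windows(cfg.r_range, cfg.n_windows, cfg.force_constant)
    windows, trajs, hills_all = [], [], []
    for uw in umbrellas:
        dyn = DynamicsConfig(
            temperature=cfg.temperature, diffusion=cfg.diffusion,
            timestep=cfg.timestep, n_steps=cfg.n_steps,
            output_stride=cfg.output_stride,
            seed=_window_seed(cfg.seed, uw.index),
        )
        bias = BiasProtocol(
            umbrella=uw, umbrella_dim=0,
            restraints={1: restraint, 2: restraint},
            metad=metad, metad_dims=(1, 2),
        )
        traj, hills = simulate(pot, dyn, bias)
        n_eq = int(cfg.equilibration_fraction * len(traj))
        traj_eq = type(traj)(
            times=traj.times[n_eq:], data=traj.data[n_eq:],
            cv_names=traj.cv_names, bias=traj.bias[n_eq:],
            provenance=traj.provenance,
        )
        ws = reweight_metad(traj_eq, hills, resolution=cfg.grid_resolution,
                            window_index=uw.index)
        windows.append((uw, ws))
        trajs.append(traj)
        hills_all.append(hills)
        n_out = _wall_violations(traj, restraint, cfg.metad_sigma)
        log.info(
            "window %02d: center %.3f nm, %d frames, %d hills, "
            "wall-excess frames %.2f%%",
            uw.index, uw.center, len(traj), len(hills), 100 * n_out,
        )
        if outdir is not None:
            wdir = Path(outdir) / "windows"
            wdir.mkdir(parents=True, exist_ok=True)
            dfio.write_colvar(traj, wdir / f"colvar_{uw.index:03d}.dat")
            dfio.write_hills(hills, wdir / f"hills_{uw.index:03d}.dat")
    return windows, trajs, hills_all


def _wall_violations(traj, restraint: AngularRestraint, sigma_m: float) -> float:
    th = traj.data[:, 1:]
    out = (th < restraint.min_theta - 2 * sigma_m) | \
          (th > restraint.max_theta + 2 * sigma_m)
    return float(out.any(axis=1).mean())


def run_pipeline(cfg: PipelineConfig, outdir=None,
                 make_plots: bool = False) -> PipelineResult:
    """Run the full free-energy protocol; see module docstring."""
    cfg = cfg.resolved()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")

    pot = make_paper_like_potential(cfg.interface)
    windows, trajs, hills_all = sample_windows(cfg, pot, out)

    grid = np.arange(cfg.r_range[0] - 0.1, cfg.r_range[1] + 0.1, cfg.bin_width)
    profile = wham(windows, grid=grid, temperature=cfg.temperature)
    profile = set_reference(profile, cfg.reference_range)
    stderr, replicas = bootstrap_errors(
        windows, n_boot=cfg.n_boot, seed=cfg.seed, grid=grid,
        temperature=cfg.temperature, reference_range=cfg.reference_range,
    )
    profile.stderr = stderr
    log.info("WHAM converged: residual %.2e after %d iterations",
             profile.provenance["residual"], profile.provenance["iterations"])

    # angular FES at the dimer minimum
    m = profile.sampled
    r_min = float(profile.r[m][np.argmin(profile.F[m])])
    hw = cfg.angular_slice_halfwidth
    ang = angular_fes(windows, (r_min - hw, r_min + hw),
                      resolution=cfg.angular_resolution,
                      temperature=cfg.temperature, profile=profile,
                      theta_range=cfg.theta_range)
    find_minima(ang, depth_threshold=1.0, max_minima=5)

    restraint = AngularRestraint(cfg.theta_range[0], cfg.theta_range[1])
    omega0 = omega_norm(restraint, cfg.metad_sigma)
    membrane = MembraneSpec(lipid_density=cfg.lipid_density,
                            temperature=cfg.temperature)
    thermo = propagate_ci(profile, omega0, cfg.r_d, membrane,
                          replicas=replicas)

    kin = None
    kin_fields = (cfg.kinetics_d_c, cfg.kinetics_contact_radius,
                  cfg.kinetics_timescale, cfg.kinetics_d0)
    if all(v is not None for v in kin_fields):
        spec = DiffusionSpec(d_c=cfg.kinetics_d_c,
                             contact_radius=cfg.kinetics_contact_radius,
                             timescale=cfg.kinetics_timescale)
        kin = evaluate_kinetics(spec, thermo.k_d, cfg.kinetics_d0)
    else:
        log.info("kinetics skipped: diffusion parameters not configured")

    summary = dict(
        interface=cfg.interface,
        seed=int(cfg.seed),
        n_windows=int(cfg.n_windows),
        n_steps_per_window=int(cfg.n_steps),
        f_min_kcal_mol=float(np.min(profile.F[m])),
        r_min_nm=r_min,
        omega0_rad2=float(omega0),
        r_d_nm=float(cfg.r_d),
        reference_range_nm=list(cfg.reference_range),
        thermo=thermo.as_dict(),
        angular_minima=ang.minima,
        wham_residual=float(profile.provenance["residual"]),
    )
    if kin is not None:
        summary["kinetics"] = dict(
            k_on_um2_s=kin.k_on, k_off_per_s=kin.k_off,
            half_life_s=kin.half_life, d0_um2=kin.d0,
        )

    if out is not None:
        dfio.write_profile(profile, out / "profile.tsv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        if make_plots:
            _plot(profile, ang, out)
    return PipelineResult(profile=profile, thermo=thermo, angular=ang,
                          kinetics=kin, summary=summary, outdir=out)


def _plot(profile: FreeEnergyProfile, ang, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    s = profile.sampled
    ax.errorbar(profile.r[s], profile.F[s], yerr=profile.stderr[s], lw=1.2,
                elinewidth=0.6, errorevery=3)
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("F(r) (kcal/mol)")
    fig.tight_layout()
    fig.savefig(out / "profile.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    Fm = np.ma.masked_invalid(ang.F)
    pcm = ax.pcolormesh(ang.theta_a, ang.theta_b, Fm.T, shading="nearest")
    fig.colorbar(pcm, ax=ax, label="F (kcal/mol)")
    ax.set_xlabel(r"$\theta_a$ (rad)")
    ax.set_ylabel(r"$\theta_b$ (rad)")
    fig.tight_layout()
    fig.savefig(out / "angular_fes.png", dpi=150)
    plt.close(fig)
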