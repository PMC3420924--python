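"""Free-energy-surface reconstruction from biased CV trajectories.

Stages:

1. ``reweight_metad`` removes the time-dependent well-tempered metadynamics
   bias from each umbrella window, attaching a statistical weight
   w ∝ exp(+β[V(θ(t), t) − c(t)]) to every frame, where c(t) is the running
   bias offset estimated on a grid from the evolving bias (the well-tempered
   estimate F ≈ −γ/(γ−1)·V is used for the ensemble average).
2. ``wham`` combines the umbrella windows self-consistently into the
   unbiased distribution of the separation r and hence F(r).
3. ``angular_fes`` reconstructs F(θa, θb) at a fixed r slice, treating the
   umbrella restraint as an external potential that is divided out.
4. ``bootstrap_errors`` attaches moving-block-bootstrap error bars, with the
   block length set by the integrated autocorrelation time of r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.special import logsumexp

from .biasing import HillsLog, UmbrellaWindow, umbrella_energy
from .constants import kt
from .dynamics import CVTrajectory

__all__ = [
    "WeightedSamples",
    "FreeEnergyProfile",
    "AngularFES",
    "reweight_metad",
    "wham",
    "set_reference",
    "angular_fes",
    "find_minima",
    "bootstrap_errors",
    "integrated_autocorrelation_time",
]


# ----------------------------------------------------------------- types

@dataclass
class WeightedSamples:
    """Per-frame unbiasing weights for one umbrella window.

    ``weights`` remove only the metadynamics bias; the umbrella restraint is
    handled downstream (WHAM, or as an external potential for the angular
    FES).  Frames stay in time order so block bootstrap can respect
    autocorrelation.
    """

    r: np.ndarray
    weights: np.ndarray
    theta: np.ndarray | None = None       # (n, n_metad_cv)
    times: np.ndarray | None = None
    window_index: int = 0
    temperature: float = 300.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.r.shape != self.weights.shape:
            raise ValueError("r and weights must have equal length")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be positive and finite")

    def __len__(self) -> int:
        return self.r.shape[0]

    def take(self, idx: np.ndarray) -> "WeightedSamples":
        return WeightedSamples(
            r=self.r[idx], weights=self.weights[idx],
            theta=None if self.theta is None else self.theta[idx],
            times=None, window_index=self.window_index,
            temperature=self.temperature, meta=self.meta,
        )


@dataclass
class FreeEnergyProfile:
    """F(r) on a uniform grid with standard errors (kcal/mol).

    Unsampled bins carry F = +inf.  ``reference_range`` records the r
    interval whose mean free energy has been offset to zero (the monomeric
    state convention).
    """

    r: np.ndarray
    F: np.ndarray
    stderr: np.ndarray
    temperature: float = 300.0
    reference_range: tuple[float, float] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if np.any(self.stderr < 0):
            raise ValueError("standard errors must be non-negative")

    @property
    def sampled(self) -> np.ndarray:
        return np.isfinite(self.F)

    def interp(self, r: np.ndarray) -> np.ndarray:
        m = self.sampled
        return np.interp(r, self.r[m], self.F[m])


@dataclass
class AngularFES:
    """F(θa, θb) at a fixed r slice, offset so the global minimum is zero."""

    theta_a: np.ndarray
    theta_b: np.ndarray
    F: np.ndarray                          # (n_a, n_b)
    r_slice: tuple[float, float]
    temperature: float = 300.0
    minima: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


# ----------------------------------------------------- metadynamics unbias

def _replay_bias_grid(hills: HillsLog, extents, resolution: float):
    """Grids of the evolving bias and the running offset c(t) per hill."""
    ncv = hills.centers.shape[1]
    axes = [
        np.arange(lo, hi + resolution, resolution) for lo, hi in extents
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    V = np.zeros(pts.shape[0])
    kT = kt(hills.temperature)
    g = hills.bias_factor
    c_of_hill = np.empty(len(hills))
    V_frames_grids = []
    for k in range(len(hills)):
        expo = np.zeros(pts.shape[0])
        for j in range(ncv):
            expo += ((pts[:, j] - hills.centers[k, j]) / hills.sigmas[k, j]) ** 2
        V += hills.heights[k] * np.exp(-0.5 * expo)
        # c(t) = kT·ln[ Σ e^{βγV/(γ−1)} / Σ e^{βV/(γ−1)} ]
        a = V / kT
        c_of_hill[k] = kT * (
            logsumexp(g / (g - 1.0) * a) - logsumexp(1.0 / (g - 1.0) * a)
        )
    return axes, V.reshape(mesh[0].shape), c_of_hill


def _interp_grid(axes, grid, pts):
    from scipy.interpolate import RegularGridInterpolator

    f = RegularGridInterpolator(axes, grid, bounds_error=False, fill_value=None)
    return f(pts)


def reweight_metad(
    traj: CVTrajectory,
    hills: HillsLog,
    resolution: float = 0.01,
    window_index: int = 0,
    r_name: str = "r",
) -> WeightedSamples:
    """Frame weights that undo the well-tempered metadynamics bias.

    Uses the hill log to rebuild V(θ, t) on a grid, computes the running
    offset c(t) at every deposition, and weights each frame by
    exp(+β[V(θ(t), t) − c(t)]).  With an empty hill log all weights are
    equal.  Raises when the hill log and trajectory do not cover the same
    time span.
    """
    temperature = hills.temperature
    kT = kt(temperature)
    r = traj.column(r_name)
    md_cols = [traj.cv_names.index(n) for n in hills.cv_names
               if n in traj.cv_names]
    theta = traj.data[:, md_cols] if md_cols else None

    if len(hills) == 0:
        w = np.ones(len(traj))
        return WeightedSamples(r=r, weights=w, theta=theta, times=traj.times,
                               window_index=window_index,
                               temperature=temperature)

    if len(md_cols) != hills.centers.shape[1]:
        raise ValueError("trajectory lacks the CVs the hills were deposited on")
    stride = float(np.median(np.diff(hills.times))) if len(hills) > 1 else (
        hills.times[0] if hills.times[0] > 0 else 1.0
    )
    # hills deposited before the first retained frame are fine (equilibration
    # trimming); what must not happen is bias history missing for frames, or
    # hills claiming to extend beyond the sampled span
    if hills.times[-1] > traj.times[-1] + 2 * stride or \
            traj.times[-1] > hills.times[-1] + 5 * stride:
        raise ValueError(
            "hills and trajectory cover inconsistent time spans "
            f"(hills {hills.times[0]:.6g}–{hills.times[-1]:.6g} ps, "
            f"trajectory {traj.times[0]:.6g}–{traj.times[-1]:.6g} ps)"
        )

    extents = []
    for j in range(hills.centers.shape[1]):
        # median sigma keeps the grid bounded even if a few anomalously wide
        # hills (e.g. near-flat offsets) are present
        margin = 6 * float(np.median(hills.sigmas[:, j]))
        lo = min(hills.centers[:, j].min(), theta[:, j].min()) - margin
        hi = max(hills.centers[:, j].max(), theta[:, j].max()) + margin
        extents.append((lo, hi))
    axes, _, c_of_hill = _replay_bias_grid(hills, extents, resolution)

    # assign each frame the bias state after the last hill deposited before it
    idx = np.searchsorted(hills.times, traj.times, side="right") - 1
    c = np.where(idx >= 0, c_of_hill[np.clip(idx, 0, None)], 0.0)

    # V(θ(t), t): rebuild incrementally per inter-hill interval
    V_frames = np.zeros(len(traj))
    ncv = hills.centers.shape[1]
    order = np.argsort(idx, kind="stable")
    # accumulate hills one by one, evaluating frames whose idx == k
    Vg = np.zeros([len(a) for a in axes])
    mesh = np.meshgrid(*axes, indexing="ij")
    pos = 0
    sorted_idx = idx[order]
    for k in range(len(hills)):
        expo = np.zeros(Vg.shape)
        for j in range(ncv):
            expo += ((mesh[j] - hills.centers[k, j]) / hills.sigmas[k, j]) ** 2
        Vg += hills.heights[k] * np.exp(-0.5 * expo)
        sel = order[(sorted_idx == k)]
        if sel.size:
            V_frames[sel] = _interp_grid(axes, Vg, theta[sel])
    # frames before the first hill keep V = 0

    logw = (V_frames - c) / kT
    w = np.exp(logw - logw.max())
    w *= len(w) / w.sum()
    return WeightedSamples(r=r, weights=w, theta=theta, times=traj.times,
                           window_index=window_index, temperature=temperature,
                           meta=dict(c_final=float(c_of_hill[-1])))


# ------------------------------------------------------------------ WHAM

def _wham_arrays(windows, edges, temperature):
    kT = kt(temperature)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nwin, nbin = len(windows), centers.shape[0]
    H = np.zeros((nwin, nbin))
    for i, (uw, ws) in enumerate(windows):
        wsum = ws.weights.sum()
        wnorm = ws.weights * (len(ws) / wsum)
        H[i], _ = np.histogram(ws.r, bins=edges, weights=wnorm)
    N = H.sum(axis=1)
    bU = np.array([
        umbrella_energy(uw, centers) / kT for uw, _ in windows
    ])
    return centers, H, N, bU


def _check_connected(H: np.ndarray) -> None:
    nwin = H.shape[0]
    occupied = H > 0
    seen = np.zeros(nwin, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        share = (occupied & occupied[i]).any(axis=1)
        for j in np.nonzero(share & ~seen)[0]:
            seen[j] = True
            stack.append(j)
    if not seen.all():
        raise ValueError(
            "disconnected umbrella windows: no shared sampled bins between "
            f"window groups {np.nonzero(seen)[0].tolist()} and "
            f"{np.nonzero(~seen)[0].tolist()}"
        )


def _overlap_diagnostic(H: np.ndarray) -> np.ndarray:
    """Histogram overlap (∑ min) between adjacent windows, as fractions."""
    P = H / np.clip(H.sum(axis=1, keepdims=True), 1e-300, None)
    return np.array([
        np.minimum(P[i], P[i + 1]).sum() for i in range(H.shape[0] - 1)
    ])


def wham(
    windows: list,
    grid=None,
    temperature: float = 300.0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    solver: str = "auto",
    overlap_warn: float = 0.05,
) -> FreeEnergyProfile:
    """Weighted-histogram combination of umbrella windows into F(r).

    ``windows`` is a list of (UmbrellaWindow, WeightedSamples); ``grid`` is
    (lo, hi, bin_width), an array of bin edges, or None (span of the data
    with 0.02 nm bins).  The self-consistent window free energies are
    iterated until the largest change is below ``tol`` kcal/mol (a convex
    quasi-Newton warm start keeps the iteration count small); failure to
    converge raises with the residual.  F is defined up to a constant —
    apply :func:`set_reference` afterwards.
    """
    if not windows:
        raise ValueError("need at least one window")
    kT = kt(temperature)
    if grid is None:
        lo = min(ws.r.min() for _, ws in windows)
        hi = max(ws.r.max() for _, ws in windows)
        edges = np.arange(lo, hi + 0.02, 0.02)
    elif isinstance(grid, tuple) and len(grid) == 3:
        edges = np.arange(grid[0], grid[1] + grid[2] * 0.5, grid[2])
    else:
        edges = np.asarray(grid, dtype=float)
    centers, H, N, bU = _wham_arrays(windows, edges, temperature)
    if len(windows) > 1:
        _check_connected(H)
        ov = _overlap_diagnostic(H)
        if np.any(ov < overlap_warn):
            worst = int(np.argmin(ov))
            warnings.warn(
                f"adjacent-window histogram overlap down to {ov.min():.3f} "
                f"(windows {worst}/{worst + 1}); WHAM bridging may be poor",
                stacklevel=2,
            )

    num = H.sum(axis=0)
    sampled = num > 0
    ln_num = np.where(sampled, np.log(np.clip(num, 1e-300, None)), -np.inf)
    lnN = np.log(np.clip(N, 1e-300, None))

    def direct_iter(g):
        ln_den = logsumexp(lnN[:, None] + g[:, None] - bU, axis=0)
        lnP = np.where(sampled, ln_num - ln_den, -np.inf)
        g_new = -logsumexp(lnP[None, :] - bU, axis=1)
        return g_new - g_new[0]

    g = np.zeros(len(windows))
    if solver in ("auto", "lbfgs") and len(windows) > 1:
        def objective(g_free):
            gg = np.concatenate([[0.0], g_free])
            ln_den = logsumexp(lnN[:, None] + gg[:, None] - bU, axis=0)
            phi = float((num[sampled] * ln_den[sampled]).sum() - (N * gg).sum())
            lnP = np.where(sampled, ln_num - ln_den, -np.inf)
            grad = N * np.exp(gg + logsumexp(lnP[None, :] - bU, axis=1)) - N
            return phi, grad[1:]

        res = optimize.minimize(
            objective, np.zeros(len(windows) - 1), jac=True,
            method="L-BFGS-B",
            options=dict(ftol=1e-15, gtol=1e-11, maxiter=5000, maxfun=10000),
        )
        g = np.concatenate([[0.0], res.x])

    residual = np.inf
    for it in range(max_iter):
        g_new = direct_iter(g)
        residual = float(np.max(np.abs(g_new - g)) * kT)
        g = g_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM failed to converge within {max_iter} iterations "
            f"(residual {residual:.3g} kcal/mol)"
        )

    ln_den = logsumexp(lnN[:, None] + g[:, None] - bU, axis=0)
    lnP = np.where(sampled, ln_num - ln_den, -np.inf)
    F = np.where(sampled, -kT * lnP, np.inf)
    return FreeEnergyProfile(
        r=centers, F=F, stderr=np.zeros_like(F), temperature=temperature,
        provenance=dict(
            g=(g * kT).tolist(), N=N.tolist(), residual=residual,
            iterations=it + 1, edges=edges.tolist(),
            overlaps=_overlap_diagnostic(H).tolist() if len(windows) > 1 else [],
        ),
    )


def set_reference(p: FreeEnergyProfile,
                  rng: tuple[float, float]) -> FreeEnergyProfile:
    """Offset F so its mean over the monomeric range ``rng`` is zero."""
    m = (p.r >= rng[0]) & (p.r <= rng[1]) & p.sampled
    if not m.any():
        raise ValueError(
            f"reference range {rng} contains no sampled bins; cannot define "
            "the monomeric reference state"
        )
    off = p.F[m].mean()
    return FreeEnergyProfile(
        r=p.r.copy(), F=p.F - off, stderr=p.stderr.copy(),
        temperature=p.temperature, reference_range=(float(rng[0]), float(rng[1])),
        provenance=dict(p.provenance),
    )


# ------------------------------------------------------------ angular FES

def angular_fes(
    windows: list,
    r_slice: tuple[float, float],
    resolution: float = 0.02,
    temperature: float = 300.0,
    profile: FreeEnergyProfile | None = None,
    theta_range: tuple[float, float] | None = None,
) -> AngularFES:
    """F(θa, θb) at the r slice, doubly reweighted and offset to min 0.

    Metadynamics weights come with the samples; the umbrella restraint is
    removed by dividing each frame's probability by its WHAM-consistent
    biased density (the umbrella acts as an external potential), using the
    window free energies from ``profile`` (recomputed here when absent).
    """
    kT = kt(temperature)
    if profile is None:
        profile = wham(windows, temperature=temperature)
    gkT = np.asarray(profile.provenance["g"], dtype=float) / kT
    N = np.asarray(profile.provenance["N"], dtype=float)

    th_all, w_all = [], []
    for i, (uw, ws) in enumerate(windows):
        if ws.theta is None or ws.theta.shape[1] != 2:
            raise ValueError("angular FES needs two angle CVs per frame")
        sel = (ws.r >= r_slice[0]) & (ws.r <= r_slice[1])
        if not sel.any():
            continue
        wnorm = ws.weights * (len(ws) / ws.weights.sum())
        bU = np.array([
            umbrella_energy(w2, ws.r[sel]) / kT for w2, _ in windows
        ])
        den = logsumexp(np.log(N)[:, None] + gkT[:, None] - bU, axis=0)
        w_all.append(wnorm[sel] * np.exp(-den))
        th_all.append(ws.theta[sel])
    if not th_all:
        raise ValueError(f"no frames inside the r slice {r_slice}")
    theta = np.concatenate(th_all)
    w = np.concatenate(w_all)

    if theta_range is None:
        lo, hi = theta.min(), theta.max()
    else:
        lo, hi = theta_range
    edges = np.arange(lo, hi + resolution * 0.5, resolution)
    Hst, ea, eb = np.histogram2d(theta[:, 0], theta[:, 1],
                                 bins=[edges, edges], weights=w)
    with np.errstate(divide="ignore"):
        F = np.where(Hst > 0, -kT * np.log(Hst), np.inf)
    F -= F.min()
    return AngularFES(
        theta_a=0.5 * (ea[:-1] + ea[1:]), theta_b=0.5 * (eb[:-1] + eb[1:]),
        F=F, r_slice=(float(r_slice[0]), float(r_slice[1])),
        temperature=temperature,
        provenance=dict(n_frames=int(theta.shape[0])),
    )


def find_minima(f: AngularFES, depth_threshold: float = 2.0,
                max_minima: int | None = None) -> list[dict]:
    """Local minima of the angular FES below ``depth_threshold`` kcal/mol.

    Sorted by depth and labeled Θ1, Θ2, ...; plateau minima report their
    first grid point; at most ``max_minima`` are kept when given.  The input
    surface is modified in place only by attaching the minima list.
    """
    F = np.where(np.isfinite(f.F), f.F, np.inf)
    if not np.isfinite(F).any():
        f.minima = []
        return []
    foot = ndimage.minimum_filter(F, size=3, mode="constant", cval=np.inf)
    is_min = (F <= foot) & np.isfinite(F) & (F < depth_threshold)
    ia, ib = np.nonzero(is_min)
    vals = F[ia, ib]
    order = np.argsort(vals, kind="stable")
    minima = []
    taken: list[tuple[float, float]] = []
    for k in order:
        if max_minima is not None and len(minima) >= max_minima:
            break
        ta, tb = f.theta_a[ia[k]], f.theta_b[ib[k]]
        # merge plateau/adjacent duplicates
        if any(abs(ta - x) <= 1.5 * (f.theta_a[1] - f.theta_a[0])
               and abs(tb - y) <= 1.5 * (f.theta_a[1] - f.theta_a[0])
               for x, y in taken):
            continue
        taken.append((ta, tb))
        minima.append(dict(
            label=f"Theta{len(minima) + 1}",
            theta_a=float(ta), theta_b=float(tb), F=float(vals[k]),
        ))
    f.minima = minima
    return minima


# -------------------------------------------------------------- bootstrap

def integrated_autocorrelation_time(x: np.ndarray, max_lag=None) -> float:
    """IACT in frames via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 4:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0:
        return 1.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    acf /= acf[0]
    if max_lag is None:
        max_lag = n // 2
    # sum consecutive-pair sums while positive (initial positive sequence)
    tau = 1.0
    k = 1
    while k + 1 < max_lag:
        pair = acf[k] + acf[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return max(1.0, tau)


def _block_resample(n: int, block: int, rng: np.random.Generator) -> np.ndarray:
    """Circular moving-block bootstrap indices of length n."""
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n, size=n_blocks)
    idx = (starts[:, None] + np.arange(block)[None, :]).ravel() % n
    return idx[:n]


def bootstrap_errors(
    windows: list,
    estimator=None,
    n_boot: int = 50,
    block_length=None,
    seed: int = 0,
    grid=None,
    temperature: float = 300.0,
    reference_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Moving-block bootstrap standard errors of the reconstruction.

    Returns ``(stderr, replicas)`` where replicas is (n_boot, n_bins) of
    re-estimated F values (inf where unsampled in a replica).  ``estimator``
    maps a resampled window list to a FreeEnergyProfile; the default runs
    WHAM on a fixed grid and applies the reference offset.  ``block_length``
    is one value (frames) or per-window; by default the integrated
    autocorrelation time of r in each window.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(int(seed) % 2**31)
    if grid is None:
        lo = min(ws.r.min() for _, ws in windows)
        hi = max(ws.r.max() for _, ws in windows)
        grid = np.arange(lo, hi + 0.02, 0.02)
    if estimator is None:
        def estimator(wins):
            prof = wham(wins, grid=grid, temperature=temperature,
                        overlap_warn=0.0)
            if reference_range is not None:
                prof = set_reference(prof, reference_range)
            return prof

    if block_length is None:
        blocks = [
            max(1, int(np.ceil(integrated_autocorrelation_time(ws.r))))
            for _, ws in windows
        ]
    else:
        b = np.atleast_1d(np.asarray(block_length, dtype=int))
        blocks = list(b) if b.shape[0] > 1 else [int(b[0])] * len(windows)

    replicas = []
    for _ in range(n_boot):
        wins_b = []
        for (uw, ws), L in zip(windows, blocks):
            idx = _block_resample(len(ws), max(1, min(L, len(ws))), rng)
            wins_b.append((uw, ws.take(idx)))
        replicas.append(estimator(wins_b).F)
    R = np.array(replicas)
    Rm = np.where(np.isfinite(R), R, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stderr = np.nanstd(Rm, axis=0, ddof=1)
    stderr = np.where(np.isfinite(stderr), stderr, 0.0)
    return stderr, R
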