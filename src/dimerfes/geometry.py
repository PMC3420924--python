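"""Dimerization collective variables from particle coordinates.

Two membrane-embedded protomers *a* and *b* are each described by a cloud of
bead positions.  Three collective variables (CVs) describe their dimeric
arrangement:

* ``r`` — distance between the centers of mass (COMs) of the two TM bundles;
* ``theta_a`` — the rotational angle of protomer *a*: the arccosine of the
  inner product of the normalized in-plane projections of (i) the vector from
  the bundle COM to the COM of the interface helix group and (ii) the vector
  from the bundle COM of *a* to the bundle COM of *b*;
* ``theta_b`` — the equivalent angle for protomer *b*.

The membrane plane is the plane orthogonal to a user-supplied unit normal
(default: the z axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ProtomerCoordinates",
    "CVState",
    "com",
    "separation",
    "rotation_angle",
    "cv_state",
    "read_xyz_points",
]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class CVState:
    """One point in collective-variable space (r in nm, angles in rad)."""

    r: float
    theta_a: float
    theta_b: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"separation r must be non-negative, got {self.r}")
        for name in ("theta_a", "theta_b"):
            th = getattr(self, name)
            if not (-1e-12 <= th <= np.pi + 1e-12):
                raise ValueError(f"{name} must lie in [0, pi], got {th}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.theta_a, self.theta_b])


@dataclass
class ProtomerCoordinates:
    """Bead positions (nm) of one protomer.

    ``bundle_points`` covers the whole TM bundle; ``interface_points`` is the
    subset of the interface helix group (e.g. the TM4/3 or TM1/H8 beads)
    whose COM defines the rotational angle.
    """

    label: str
    bundle_points: np.ndarray
    interface_points: np.ndarray
    membrane_normal: np.ndarray = field(default_factory=lambda: _Z.copy())

    def __post_init__(self) -> None:
        self.bundle_points = np.atleast_2d(np.asarray(self.bundle_points, dtype=float))
        self.interface_points = np.atleast_2d(
            np.asarray(self.interface_points, dtype=float)
        )
        self.membrane_normal = np.asarray(self.membrane_normal, dtype=float)
        if self.bundle_points.size == 0 or self.interface_points.size == 0:
            raise ValueError("bundle_points and interface_points must be non-empty")
        if self.bundle_points.shape[1] != 3 or self.interface_points.shape[1] != 3:
            raise ValueError("points must be 3D")
        norm = np.linalg.norm(self.membrane_normal)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(
                f"membrane_normal must have unit length (|n| = {norm:.12g})"
            )


def com(points: Sequence | np.ndarray, weights=None) -> np.ndarray:
    """Center of mass of ``points``; uniform weights if none are given.

    CG beads have near-equal masses, so the default is an unweighted mean;
    per-point masses are accepted for completeness.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("cannot take the center of mass of an empty point set")
    if weights is None:
        return pts.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != pts.shape[0]:
        raise ValueError("weights must match the number of points")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def _project_in_plane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - np.dot(v, normal) * normal


def separation(
    a: ProtomerCoordinates,
    b: ProtomerCoordinates,
    *,
    in_plane: bool = False,
    weights_a=None,
    weights_b=None,
) -> float:
    """Distance r (nm) between the bundle COMs of the two protomers.

    The full 3D distance by default; ``in_plane=True`` selects the
    membrane-projected convention (both protomers sit in the same bilayer, so
    the two differ little in practice).
    """
    d = com(b.bundle_points, weights_b) - com(a.bundle_points, weights_a)
    if in_plane:
        d = _project_in_plane(d, a.membrane_normal)
    return float(np.linalg.norm(d))


def rotation_angle(p: ProtomerCoordinates, partner_com: np.ndarray) -> float:
    """Rotational angle θ (rad) of protomer ``p`` relative to its partner.

    θ = arccos(û·v̂) with u the in-plane projection of (interface COM −
    bundle COM) and v the in-plane projection of (partner bundle COM − own
    bundle COM).  Result in [0, π].
    """
    n = p.membrane_normal
    own = com(p.bundle_points)
    u = _project_in_plane(com(p.interface_points) - own, n)
    v = _project_in_plane(np.asarray(partner_com, dtype=float) - own, n)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError(
            "degenerate geometry: zero-length in-plane projection "
            f"(|u| = {nu:.3g}, |v| = {nv:.3g})"
        )
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosang))


def cv_state(
    a: ProtomerCoordinates, b: ProtomerCoordinates, *, in_plane: bool = False
) -> CVState:
    """Compute the full CV triplet (r, θa, θb) for a protomer pair."""
    ca = com(a.bundle_points)
    cb = com(b.bundle_points)
    return CVState(
        r=separation(a, b, in_plane=in_plane),
        theta_a=rotation_angle(a, cb),
        theta_b=rotation_angle(b, ca),
    )


def read_xyz_points(path: str | Path) -> np.ndarray:
    """Read whitespace-delimited xyz points, one per line; '#' starts a comment."""
    pts = np.loadtxt(path, comments="#", ndmin=2)
    if pts.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, found {pts.shape[1]}")
    return pts
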