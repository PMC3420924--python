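"""Text formats: COLVAR- and HILLS-dialect trajectories, profile tables.

Both dialects follow the PLUMED convention of a ``#! FIELDS ...`` header
line followed by whitespace-separated numeric rows; additional metadata is
carried on ``#! SET key value`` lines and free-form ``#`` comments.  Floats
are written with 17 significant digits so write∘read is the identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .biasing import HillsLog
from .dynamics import CVTrajectory
from .fes import FreeEnergyProfile

__all__ = [
    "read_colvar", "write_colvar",
    "read_hills", "write_hills",
    "read_profile", "write_profile",
]

_FMT = "%.17g"


def _parse_header(path: Path):
    fields = None
    sets: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("#! FIELDS"):
                fields = s.split()[2:]
                n_header += 1
            elif s.startswith("#! SET"):
                parts = s.split()
                if len(parts) >= 4:
                    sets[parts[2]] = parts[3]
                n_header += 1
            elif s.startswith("#") or not s:
                n_header += 1
            else:
                break
    if fields is None:
        raise ValueError(f"{path}: malformed file, missing '#! FIELDS' header")
    return fields, sets, n_header


def _load_rows(path: Path, n_fields: int):
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no data.*")
        data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        return np.zeros((0, n_fields))
    if data.shape[1] != n_fields:
        raise ValueError(
            f"{path}: expected {n_fields} columns per row, found {data.shape[1]}"
        )
    return data


# ----------------------------------------------------------------- COLVAR

def write_colvar(traj: CVTrajectory, path) -> None:
    path = Path(path)
    fields = ["time", *traj.cv_names, "bias"]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for k, v in (traj.provenance or {}).items():
            if isinstance(v, (int, float, str)):
                fh.write(f"#! SET {k} {v}\n")
        arr = np.column_stack([traj.times, traj.data, traj.bias])
        np.savetxt(fh, arr, fmt=_FMT)


def read_colvar(path) -> CVTrajectory:
    """Read a COLVAR-dialect file; rejects missing fields and shuffled time."""
    path = Path(path)
    fields, sets, n_header = _parse_header(path)
    if "time" not in fields:
        raise ValueError(f"{path}: required field 'time' missing from header")
    cv_names = [f for f in fields if f not in ("time", "bias")]
    if not cv_names:
        raise ValueError(f"{path}: no collective-variable fields in header")
    data = _load_rows(path, len(fields))
    t = data[:, fields.index("time")]
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: time not strictly increasing at data row {bad[0] + 2} "
            f"(file line ~{n_header + bad[0] + 2})"
        )
    cols = np.column_stack([data[:, fields.index(n)] for n in cv_names])
    bias = (data[:, fields.index("bias")] if "bias" in fields
            else np.zeros(t.shape[0]))
    return CVTrajectory(times=t, data=cols, cv_names=tuple(cv_names),
                        bias=bias, provenance=dict(sets))


# ------------------------------------------------------------------ HILLS

def write_hills(log: HillsLog, path) -> None:
    path = Path(path)
    names = list(log.cv_names)
    fields = ["time", *names, *[f"sigma_{n}" for n in names], "height", "biasf"]
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        fh.write(f"#! SET temperature {log.temperature!r}\n")
        arr = np.column_stack([
            log.times, log.centers, log.sigmas, log.heights,
            np.full(len(log), log.bias_factor),
        ])
        np.savetxt(fh, arr, fmt=_FMT)


def read_hills(path) -> HillsLog:
    path = Path(path)
    fields, sets, _ = _parse_header(path)
    if fields[0] != "time" or "height" not in fields or "biasf" not in fields:
        raise ValueError(f"{path}: not a HILLS-dialect header: {fields}")
    cv_names = [f for f in fields[1:] if not f.startswith("sigma_")
                and f not in ("height", "biasf")]
    for n in cv_names:
        if f"sigma_{n}" not in fields:
            raise ValueError(f"{path}: missing field sigma_{n}")
    data = _load_rows(path, len(fields))
    if data.shape[0] == 0:
        return HillsLog.empty(
            cv_names=tuple(cv_names),
            temperature=float(sets.get("temperature", 300.0)),
        )
    heights = data[:, fields.index("height")]
    if np.any(heights <= 0):
        row = int(np.nonzero(heights <= 0)[0][0])
        raise ValueError(f"{path}: non-positive hill height at data row {row + 1}")
    return HillsLog(
        times=data[:, 0],
        centers=np.column_stack([data[:, fields.index(n)] for n in cv_names]),
        sigmas=np.column_stack(
            [data[:, fields.index(f"sigma_{n}")] for n in cv_names]
        ),
        heights=heights,
        bias_factor=float(data[0, fields.index("biasf")]),
        temperature=float(sets.get("temperature", 300.0)),
        cv_names=tuple(cv_names),
    )


# ---------------------------------------------------------------- profiles

def write_profile(p: FreeEnergyProfile, path) -> None:
    """Tab-separated r / F / stderr with provenance header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# free-energy profile F(r)\n")
        fh.write(f"# temperature_K\t{p.temperature!r}\n")
        if p.reference_range is not None:
            fh.write(
                f"# reference_range_nm\t{p.reference_range[0]!r}"
                f"\t{p.reference_range[1]!r}\n"
            )
        for k in ("residual", "iterations"):
            if k in p.provenance:
                fh.write(f"# {k}\t{p.provenance[k]!r}\n")
        fh.write("# r_nm\tF_kcal_mol\tstderr_kcal_mol\n")
        for r, F, s in zip(p.r, p.F, p.stderr):
            fh.write(f"{r:.17g}\t{F:.17g}\t{s:.17g}\n")


def read_profile(path) -> FreeEnergyProfile:
    path = Path(path)
    temperature, ref = 300.0, None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# temperature_K"):
                temperature = float(line.split("\t")[1])
            elif line.startswith("# reference_range_nm"):
                parts = line.strip().split("\t")
                ref = (float(parts[1]), float(parts[2]))
    data = np.loadtxt(path, comments="#", ndmin=2)
    return FreeEnergyProfile(
        r=data[:, 0], F=data[:, 1], stderr=data[:, 2],
        temperature=temperature, reference_range=ref,
    )
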