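"""File formats: XYZ-with-box trajectories, a minimal PSF dialect, TSV logs.

Conventions
-----------
* Trajectory: plain XYZ where the comment line carries the box and time,
  ``time=<ps> box=<lx>,<ly>,<lz>``; coordinates printed to 6 decimals.
* Topology: CHARMM/X-PLOR-flavoured PSF restricted to the title, atom and
  bond sections (segment, residue id/name, atom name/type, charge, mass).
  Residue ids are 1-based in files and 0-based in memory.
* Event log / charge report: tab-separated tables, one row per transfer
  event / per residue snapshot.  The event log is the contract consumed by
  the transport analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError
from .system import BoxSpec, Residue, SystemState, TransferEvent
from .templates import ResidueDualTemplate

__all__ = [
    "Trajectory",
    "read_frames",
    "write_frames",
    "PSFAtom",
    "read_topology",
    "write_topology",
    "system_from_topology",
    "write_events",
    "read_events",
    "events_to_frame",
    "write_charge_report",
    "read_charge_report",
]


@dataclass
class Trajectory:
    """In-memory trajectory: folded positions per frame plus box and times."""

    times: np.ndarray  # (F,) ps
    positions: np.ndarray  # (F, N, 3) A
    box: BoxSpec
    atom_names: list[str] | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]


# ---------------------------------------------------------------------------
# XYZ with box metadata
# ---------------------------------------------------------------------------


def write_frames(traj: Trajectory, path: str | Path) -> None:
    names = traj.atom_names or ["X"] * traj.n_atoms
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.positions):
            lx, ly, lz = traj.box.lengths
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"time={t:.6f} box={lx:.6f},{ly:.6f},{lz:.6f}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_frames(path: str | Path) -> Trajectory:
    times: list[float] = []
    frames: list[np.ndarray] = []
    box: BoxSpec | None = None
    names: list[str] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{i+1}: expected atom count, got {lines[i]!r}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta = dict(
            kv.split("=", 1) for kv in comment.split() if "=" in kv
        )
        if "box" not in meta:
            raise ParseError(
                f"{path}:{i+2}: comment line must carry box metadata 'box=lx,ly,lz'"
            )
        lengths = tuple(float(v) for v in meta["box"].split(","))
        frame_box = BoxSpec(lengths)  # type: ignore[arg-type]
        if box is None:
            box = frame_box
        elif frame_box.lengths != box.lengths:
            raise ParseError(f"{path}:{i+2}: box changed between frames")
        times.append(float(meta.get("time", len(times))))
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ParseError(f"{path}:{i+1}: frame declares {n} atoms, file truncated")
        coords = np.empty((n, 3))
        frame_names = []
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{i+3+k}: expected 'name x y z', got {line!r}")
            frame_names.append(parts[0])
            coords[k] = [float(p) for p in parts[1:]]
        if names is None:
            names = frame_names
        if frames and coords.shape != frames[0].shape:
            raise ParseError(f"{path}:{i+1}: atom count changed between frames")
        frames.append(coords)
        i += 2 + n
    if box is None:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(frames),
        box=box,
        atom_names=names,
    )


# ---------------------------------------------------------------------------
# PSF dialect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSFAtom:
    index: int  # 0-based
    segid: str
    resid: int  # 0-based (files are 1-based)
    resname: str
    name: str
    atom_type: str
    charge: float
    mass: float


def write_topology(state: SystemState, path: str | Path, segid: str = "SYS") -> None:
    """Write the atoms(+empty bonds) PSF dialect for the current state."""
    masses = state._mass_array()
    with open(path, "w") as fh:
        fh.write("PSF EXT\n\n")
        fh.write(f"{1:10d} !NTITLE\n")
        fh.write(" REMARKS pexkit minimal PSF (atoms + bonds sections only)\n\n")
        fh.write(f"{state.n_atoms:10d} !NATOM\n")
        k = 0
        for res in state.residues:
            atoms = res.template.atoms_for(res.current_state_name)
            for a in atoms:
                fh.write(
                    f"{k+1:10d} {segid:<8s} {res.id+1:<8d} "
                    f"{res.current_state_name:<8s} {a.atom_name:<8s} "
                    f"{a.atom_type:<8s} {state.charges[k]:14.6f} "
                    f"{masses[k]:14.4f} {0:10d}\n"
                )
                k += 1
        fh.write("\n")
        fh.write(f"{0:10d} !NBOND: bonds\n\n")


def read_topology(path: str | Path) -> tuple[dict[str, int], list[PSFAtom]]:
    """Parse the PSF dialect.

    Returns the residue composition (state name -> count) and the atom
    records.  Sections other than NATOM/NBOND are ignored.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("PSF"):
        raise ParseError(f"{path}:1: not a PSF file (missing 'PSF' header)")
    atoms: list[PSFAtom] = []
    i = 0
    natom = None
    while i < len(lines):
        if "!NATOM" in lines[i]:
            natom = int(lines[i].split()[0])
            break
        i += 1
    if natom is None:
        raise ParseError(f"{path}: no !NATOM section")
    for k in range(natom):
        lineno = i + 1 + k
        if lineno >= len(lines):
            raise ParseError(f"{path}: NATOM declares {natom} atoms, file truncated")
        parts = lines[lineno].split()
        if len(parts) < 8:
            raise ParseError(
                f"{path}:{lineno+1}: malformed atom record {lines[lineno]!r}"
            )
        try:
            atoms.append(
                PSFAtom(
                    index=int(parts[0]) - 1,
                    segid=parts[1],
                    resid=int(parts[2]) - 1,
                    resname=parts[3],
                    name=parts[4],
                    atom_type=parts[5],
                    charge=float(parts[6]),
                    mass=float(parts[7]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno+1}: {exc}") from exc
    composition: dict[str, int] = {}
    seen: set[int] = set()
    for a in atoms:
        if a.resid not in seen:
            seen.add(a.resid)
            composition[a.resname] = composition.get(a.resname, 0) + 1
    return composition, atoms


def system_from_topology(
    path: str | Path,
    positions: np.ndarray,
    box: BoxSpec,
    templates: Sequence[ResidueDualTemplate],
) -> SystemState:
    """Build a SystemState from a PSF plus coordinates.

    Every residue name in the file must be a state of some template.
    """
    composition, atoms = read_topology(path)
    by_state = {s: t for t in templates for s in t.state_names}
    for name in composition:
        if name not in by_state:
            raise ConfigError(f"PSF residue name {name!r} not defined by any template")

    residues: list[Residue] = []
    charges, eps, rmin, names, masses = [], [], [], [], []
    current_resid = None
    for a in atoms:
        if a.resid != current_resid:
            current_resid = a.resid
            template = by_state[a.resname]
            residues.append(
                Residue(
                    id=len(residues),
                    template=template,
                    current_state_name=a.resname,
                    atom_start=len(charges),
                )
            )
        t = residues[-1].template
        params = {p.atom_name: p for p in t.atoms_for(residues[-1].current_state_name)}
        if a.name not in params:
            raise ConfigError(
                f"atom {a.name!r} not in template state {residues[-1].current_state_name!r}"
            )
        p = params[a.name]
        charges.append(a.charge)
        eps.append(p.lj_epsilon)
        rmin.append(p.lj_rmin_half)
        names.append(a.name)
        masses.append(a.mass)
    return SystemState(
        positions=np.asarray(positions, float),
        box=box,
        residues=residues,
        charges=np.asarray(charges),
        lj_epsilon=np.asarray(eps),
        lj_rmin_half=np.asarray(rmin),
        atom_names=names,
        masses=np.asarray(masses),
    )


# ---------------------------------------------------------------------------
# TSV logs
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "time_ps",
    "residue_i",
    "residue_j",
    "reaction",
    "q_i_before",
    "q_j_before",
    "q_i_after",
    "q_j_after",
    "com_i_x",
    "com_i_y",
    "com_i_z",
    "com_j_x",
    "com_j_y",
    "com_j_z",
    "r_ij_x",
    "r_ij_y",
    "r_ij_z",
]


def events_to_frame(events: Iterable[TransferEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            (
                e.time,
                e.residue_i,
                e.residue_j,
                e.reaction,
                e.q_i_before,
                e.q_j_before,
                e.q_i_after,
                e.q_j_after,
                *e.com_i,
                *e.com_j,
                *e.r_ij,
            )
        )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_events(events: Iterable[TransferEvent] | pd.DataFrame, path: str | Path) -> None:
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: event log missing columns {missing}")
    return df


def write_charge_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


def read_charge_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
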