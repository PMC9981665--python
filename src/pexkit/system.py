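"""System container: positions, box, residues and their protonation states.

A :class:`SystemState` owns the per-atom parameter arrays (charge, LJ) and
a list of :class:`Residue` records that tie contiguous atom ranges to a
dual-state template.  Switching a residue's protonation state
(:func:`apply_state_to_residue`) rewrites its slice of the parameter
arrays from the template; atom count and ordering never change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PackingError
from .geometry import fold, minimum_image
from .templates import ResidueDualTemplate, single_bead_templates

__all__ = [
    "BoxSpec",
    "Residue",
    "SystemState",
    "TransferEvent",
    "apply_state_to_residue",
    "build_system",
]


@dataclass(frozen=True)
class BoxSpec:
    """Orthorhombic box edge lengths in A."""

    lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths):
            raise ValueError(f"box lengths must be positive, got {self.lengths}")

    @classmethod
    def cubic(cls, length: float) -> "BoxSpec":
        return cls((float(length),) * 3)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def min_length(self) -> float:
        return float(min(self.lengths))


@dataclass
class Residue:
    """One exchangeable molecule: a template plus its current state."""

    id: int
    template: ResidueDualTemplate
    current_state_name: str
    atom_start: int

    @property
    def n_atoms(self) -> int:
        return self.template.n_atoms

    @property
    def atom_indices(self) -> range:
        return range(self.atom_start, self.atom_start + self.n_atoms)

    @property
    def current_charge(self) -> int:
        return self.template.net_charge(self.current_state_name)

    @property
    def is_protonated(self) -> bool:
        return self.current_state_name == self.template.name_protonated


@dataclass
class TransferEvent:
    """Record of one executed proton transfer.

    ``com_i``/``com_j`` are the folded residue centers at event time and
    ``r_ij`` the minimum-image displacement ``mimage(com_j - com_i)`` —
    the geometry entering the collective-dipole correction.
    """

    time: float
    residue_i: int
    residue_j: int
    reaction: str
    q_i_before: int
    q_j_before: int
    q_i_after: int
    q_j_after: int
    com_i: tuple[float, float, float]
    com_j: tuple[float, float, float]
    r_ij: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.q_i_after + self.q_j_after != self.q_i_before + self.q_j_before:
            raise ValueError("transfer event violates charge conservation")


@dataclass
class SystemState:
    """Positions (folded), box, residues and per-atom nonbonded parameters."""

    positions: np.ndarray  # (N, 3) A, folded into [0, L)
    box: BoxSpec
    residues: list[Residue]
    charges: np.ndarray  # (N,) e
    lj_epsilon: np.ndarray  # (N,) kcal/mol (magnitude)
    lj_rmin_half: np.ndarray  # (N,) A
    atom_names: list[str] = field(default_factory=list)
    masses: np.ndarray | None = None  # (N,) amu; None -> unit masses
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = fold(np.asarray(self.positions, float).reshape(-1, 3), self.box.array)
        n = len(self.positions)
        for name, arr in (
            ("charges", self.charges),
            ("lj_epsilon", self.lj_epsilon),
            ("lj_rmin_half", self.lj_rmin_half),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    # -- bookkeeping --------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def total_charge(self) -> int:
        return sum(r.current_charge for r in self.residues)

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.residues:
            counts[r.current_state_name] = counts.get(r.current_state_name, 0) + 1
        return counts

    def residues_in_state(self, state_name: str) -> list[Residue]:
        return [r for r in self.residues if r.current_state_name == state_name]

    def _mass_array(self) -> np.ndarray:
        if self.masses is None:
            return np.ones(self.n_atoms)
        return self.masses

    def residue_center(self, residue: Residue) -> np.ndarray:
        """Folded center of mass of the residue's current non-dummy atoms.

        Minimum-image-aware: atoms straddling the boundary are gathered
        around the first atom before averaging.
        """
        idx = np.asarray(residue.atom_indices)
        atoms = residue.template.atoms_for(residue.current_state_name)
        keep = np.array(
            [
                not (a.atom_name in residue.template.dummy_atoms and a.is_dummy_like)
                for a in atoms
            ]
        )
        idx = idx[keep]
        pos = self.positions[idx]
        if len(idx) == 1:
            return pos[0].copy()
        w = self._mass_array()[idx]
        rel = minimum_image(pos - pos[0], self.box.array)
        com = pos[0] + np.average(rel, axis=0, weights=w)
        return fold(com, self.box.array)

    def residue_centers(self) -> np.ndarray:
        """(n_residues, 3) folded centers; fast path for single-bead systems."""
        if all(r.n_atoms == 1 for r in self.residues):
            starts = np.array([r.atom_start for r in self.residues])
            return self.positions[starts].copy()
        return np.array([self.residue_center(r) for r in self.residues])

    def residue_charges(self) -> np.ndarray:
        return np.array([r.current_charge for r in self.residues], dtype=int)

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            box=self.box,
            residues=[replace(r) for r in self.residues],
            charges=self.charges.copy(),
            lj_epsilon=self.lj_epsilon.copy(),
            lj_rmin_half=self.lj_rmin_half.copy(),
            atom_names=list(self.atom_names),
            masses=None if self.masses is None else self.masses.copy(),
            time=self.time,
        )


def apply_state_to_residue(
    state: SystemState,
    residue: Residue,
    target_state_name: str,
    mode: str = "all_nonbonded",
) -> SystemState:
    """Switch one residue to ``target_state_name`` in place.

    ``mode="charges_only"`` rewrites only the partial charges;
    ``"all_nonbonded"`` also swaps the LJ parameters.  Applying the current
    state is a no-op; applying A then B then A restores the original
    parameters bit-exactly (the mapping is a bijection).
    """
    if mode not in ("charges_only", "all_nonbonded"):
        raise ValueError(f"unknown mode {mode!r}")
    template = residue.template
    target_atoms = template.atoms_for(target_state_name)  # raises KeyError if unknown
    idx = residue.atom_start
    for a in target_atoms:
        state.charges[idx] = a.charge
        if mode == "all_nonbonded":
            state.lj_epsilon[idx] = a.lj_epsilon
            state.lj_rmin_half[idx] = a.lj_rmin_half
        idx += 1
    residue.current_state_name = target_state_name
    return state


def build_system(
    n_cation_anion_pairs: int,
    n_neutral_pairs: int,
    box: BoxSpec,
    min_separation: float,
    seed: int,
    templates: list[ResidueDualTemplate] | None = None,
    max_attempts_per_residue: int = 2000,
) -> SystemState:
    """Randomly pack a charge-neutral single-bead system.

    Creates ``n_cation_anion_pairs`` cation/anion residue pairs (states
    IM1H/OAC) and ``n_neutral_pairs`` neutral pairs (IM1/HOAC), placed by
    seeded rejection sampling so that no two residue centers fall closer
    than ``min_separation`` under the minimum image.  Deterministic for a
    given seed.
    """
    if templates is None:
        templates = single_bead_templates()
    if any(t.n_atoms != 1 for t in templates):
        raise ValueError("build_system packs single-bead residues only")
    by_state: dict[str, tuple[ResidueDualTemplate, str]] = {}
    for t in templates:
        by_state[t.name_protonated] = (t, t.name_protonated)
        by_state[t.name_deprotonated] = (t, t.name_deprotonated)

    roster: list[str] = (
        ["IM1H"] * n_cation_anion_pairs
        + ["OAC"] * n_cation_anion_pairs
        + ["IM1"] * n_neutral_pairs
        + ["HOAC"] * n_neutral_pairs
    )
    rng = np.random.default_rng(seed)
    lengths = box.array
    placed = np.empty((len(roster), 3))
    n_placed = 0
    for k in range(len(roster)):
        for _ in range(max_attempts_per_residue):
            trial = rng.random(3) * lengths
            if n_placed == 0:
                break
            d = minimum_image(placed[:n_placed] - trial, lengths)
            if np.min(np.sum(d * d, axis=1)) >= min_separation**2:
                break
        else:
            raise PackingError(
                f"could not place residue {k} of {len(roster)} at "
                f"min_separation={min_separation} A in box {box.lengths}"
            )
        placed[n_placed] = trial
        n_placed += 1

    residues: list[Residue] = []
    charges: list[float] = []
    eps: list[float] = []
    rmin: list[float] = []
    names: list[str] = []
    atom_start = 0
    for rid, state_name in enumerate(roster):
        template, _ = by_state[state_name]
        residues.append(
            Residue(
                id=rid,
                template=template,
                current_state_name=state_name,
                atom_start=atom_start,
            )
        )
        for a in template.atoms_for(state_name):
            charges.append(a.charge)
            eps.append(a.lj_epsilon)
            rmin.append(a.lj_rmin_half)
            names.append(a.atom_name)
        atom_start += template.n_atoms

    # single-bead templates: one atom per residue, position = bead
    return SystemState(
        positions=placed[: len(roster)],
        box=box,
        residues=residues,
        charges=np.array(charges),
        lj_epsilon=np.array(eps),
        lj_rmin_half=np.array(rmin),
        atom_names=names,
    )
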