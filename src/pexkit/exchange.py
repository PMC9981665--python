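"""The proton-exchange update step.

Every ``update_interval`` of simulation time the dynamics is paused and:

1. *candidate detection* — all donor-hydrogen / acceptor-site pairs closer
   than the reaction's ``r_max`` under the minimum image are collected;
2. *conflict resolution* — overlapping candidates are reduced to a
   disjoint set by greedy shortest-distance-first matching;
3. *feedback* — each composition-changing reaction's acceptance
   probability is moved away from ``p_ref`` by the cubic rule
   ``p = p_ref + c * (n_now/n_ref - 1)**3`` (clamped to [0, 1]) using the
   current count of its monitored species, steering the charged/neutral
   partitioning back toward the reference;
4. *acceptance* — each surviving pair transfers with its reaction's
   current probability (independent Bernoulli draws, dedicated RNG);
5. *execution* — accepted donors switch to their deprotonated state,
   acceptors to their protonated state, either instantaneously or along a
   linear charge interpolation, and one :class:`TransferEvent` per pair is
   logged with the minimum-image geometry needed later by the
   conductivity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, ConsistencyError, GeometryError
from .geometry import fold, minimum_image
from .system import Residue, SystemState, TransferEvent, apply_state_to_residue
from .templates import ResidueDualTemplate, TransferReaction

__all__ = [
    "CandidatePair",
    "ProbabilityState",
    "UpdateConfig",
    "find_candidates",
    "resolve_conflicts",
    "update_probability",
    "accept_transfers",
    "execute_update",
    "interpolate_states",
    "run_update",
    "n_update_opportunities",
]


@dataclass(frozen=True)
class CandidatePair:
    """A donor/acceptor contact eligible for transfer."""

    donor_residue: int
    acceptor_residue: int
    donor_atom: str
    acceptor_atom: str
    distance: float
    reaction: TransferReaction

    def __post_init__(self) -> None:
        if self.donor_residue == self.acceptor_residue:
            raise ValueError("donor and acceptor must be distinct residues")
        if self.distance > self.reaction.r_max:
            raise ValueError("candidate distance exceeds r_max")


@dataclass
class UpdateConfig:
    """Exchange-step schedule and mode."""

    update_interval: float = 1.0  # ps
    seed: int = 0
    swap_mode: str = "instantaneous"  # or "interpolated"
    n_lambda_steps: int = 1
    conflict_policy: str = "greedy_shortest"

    def __post_init__(self) -> None:
        if self.update_interval <= 0:
            raise ValueError("update_interval must be > 0")
        if self.n_lambda_steps < 1:
            raise ValueError("n_lambda_steps must be >= 1")
        if self.swap_mode not in ("instantaneous", "interpolated"):
            raise ValueError(f"unknown swap mode {self.swap_mode!r}")


def n_update_opportunities(total_time_ps: float, interval_ps: float) -> int:
    """Maximum number of exchange checks a molecule can face in a run."""
    if interval_ps <= 0:
        raise ValueError("interval must be > 0")
    return int(round(total_time_ps / interval_ps))


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------


def _donor_acceptor_species(
    reaction: TransferReaction, templates_by_state: dict[str, ResidueDualTemplate]
) -> tuple[str, str]:
    """Split the reactant pair into (donor species, acceptor species).

    The donor is the reactant currently in its template's protonated
    state; the acceptor the one in a deprotonated state.
    """
    a, b = reaction.reactant_pair
    a_prot = templates_by_state[a].name_protonated == a
    b_prot = templates_by_state[b].name_protonated == b
    if a_prot and not b_prot:
        return a, b
    if b_prot and not a_prot:
        return b, a
    raise ConfigError(
        f"reaction {reaction.name}: reactants must pair one protonated "
        "with one deprotonated species"
    )


def find_candidates(
    state: SystemState,
    reactions: Sequence[TransferReaction],
    templates: Sequence[ResidueDualTemplate],
) -> list[CandidatePair]:
    """All donor-H/acceptor-site contacts below each reaction's ``r_max``.

    Distances are strict minimum-image (`< r_max`).  For residues with
    several acceptor sites (e.g. both carboxylate oxygens) every site is
    checked and the closest donor/acceptor site pair is recorded.
    """
    templates_by_state = {s: t for t in templates for s in t.state_names}
    lengths = state.box.array
    half_min = state.box.min_length / 2.0
    candidates: list[CandidatePair] = []
    for reaction in reactions:
        if reaction.r_max >= half_min:
            raise GeometryError(
                f"reaction {reaction.name}: r_max={reaction.r_max} A must be "
                f"< half the smallest box length ({half_min} A)"
            )
        donor_species, acceptor_species = _donor_acceptor_species(
            reaction, templates_by_state
        )
        donors = state.residues_in_state(donor_species)
        acceptors = state.residues_in_state(acceptor_species)
        if not donors or not acceptors:
            continue

        d_pos, d_res, d_names = _site_coordinates(state, donors, donor=True)
        a_pos, a_res, a_names = _site_coordinates(state, acceptors, donor=False)

        tree_d = cKDTree(fold(d_pos, lengths), boxsize=lengths)
        tree_a = cKDTree(fold(a_pos, lengths), boxsize=lengths)
        best: dict[tuple[int, int], tuple[float, str, str]] = {}
        for di, neighbors in enumerate(tree_d.query_ball_tree(tree_a, reaction.r_max)):
            for ai in neighbors:
                delta = minimum_image(a_pos[ai] - d_pos[di], lengths)
                dist = float(np.sqrt(delta @ delta))
                if dist >= reaction.r_max:
                    continue
                key = (d_res[di], a_res[ai])
                if key[0] == key[1]:
                    continue
                if key not in best or dist < best[key][0]:
                    best[key] = (dist, d_names[di], a_names[ai])
        for (dres, ares), (dist, dname, aname) in best.items():
            candidates.append(
                CandidatePair(
                    donor_residue=dres,
                    acceptor_residue=ares,
                    donor_atom=dname,
                    acceptor_atom=aname,
                    distance=dist,
                    reaction=reaction,
                )
            )
    return candidates


def _site_coordinates(
    state: SystemState, residues: list[Residue], donor: bool
) -> tuple[np.ndarray, list[int], list[str]]:
    pos: list[np.ndarray] = []
    res_ids: list[int] = []
    names: list[str] = []
    for r in residues:
        idx = (
            r.template.donor_atom_indices() if donor else r.template.acceptor_atom_indices()
        )
        site_names = r.template.donor_atoms if donor else r.template.acceptor_atoms
        for k, name in zip(idx, site_names):
            pos.append(state.positions[r.atom_start + k])
            res_ids.append(r.id)
            names.append(name)
    return np.asarray(pos).reshape(-1, 3), res_ids, names


def resolve_conflicts(candidates: Iterable[CandidatePair]) -> list[CandidatePair]:
    """Greedy shortest-distance-first maximal matching.

    No residue appears in more than one returned pair; ties are broken by
    (donor id, acceptor id) so the result is deterministic.
    """
    ordered = sorted(
        candidates, key=lambda c: (c.distance, c.donor_residue, c.acceptor_residue)
    )
    used: set[int] = set()
    kept: list[CandidatePair] = []
    for c in ordered:
        if c.donor_residue in used or c.acceptor_residue in used:
            continue
        used.add(c.donor_residue)
        used.add(c.acceptor_residue)
        kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# feedback probabilities
# ---------------------------------------------------------------------------


def update_probability(p_ref: float, c: float, n_now: int, n_ref: int) -> float:
    """Cubic count-feedback rule, clamped to [0, 1].

    p = p_ref + c * (n_now/n_ref - 1)**3.  The cubic preserves the sign of
    the deviation: a monitored-species count below its reference lowers
    the probability of the reaction consuming it, and vice versa.
    """
    if n_ref <= 0:
        raise ValueError(f"n_ref must be > 0, got {n_ref}")
    p = p_ref + c * (n_now / n_ref - 1.0) ** 3
    return min(1.0, max(0.0, p))


@dataclass
class ProbabilityState:
    """Per-reaction current acceptance probabilities.

    ``n_ref`` holds the reference (initial) counts of each monitored
    species.  :meth:`refresh` recomputes every probability from the
    current composition; swap reactions (products a permutation of
    reactants) are composition-neutral, so the feedback leaves them at
    ``p_ref``.
    """

    reactions: tuple[TransferReaction, ...]
    n_ref: dict[str, int]
    current: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_reactions(
        cls, reactions: Sequence[TransferReaction], reference_counts: dict[str, int]
    ) -> "ProbabilityState":
        n_ref = {}
        for r in reactions:
            if not r.is_swap:
                if r.monitor_species not in reference_counts:
                    raise ConfigError(
                        f"reaction {r.name}: no reference count for monitored "
                        f"species {r.monitor_species!r}"
                    )
                n_ref[r.monitor_species] = reference_counts[r.monitor_species]
        ps = cls(reactions=tuple(reactions), n_ref=n_ref)
        ps.current = {r.name: r.p_ref for r in reactions}
        return ps

    def refresh(self, counts: dict[str, int]) -> None:
        for r in self.reactions:
            if r.is_swap or r.c == 0.0:
                self.current[r.name] = r.p_ref
            else:
                self.current[r.name] = update_probability(
                    r.p_ref, r.c, counts.get(r.monitor_species, 0), self.n_ref[r.monitor_species]
                )

    def probability(self, reaction: TransferReaction) -> float:
        return self.current[reaction.name]


def accept_transfers(
    pairs: Sequence[CandidatePair],
    probabilities: ProbabilityState,
    rng: np.random.Generator,
) -> list[CandidatePair]:
    """Independent Bernoulli acceptance with each reaction's current p."""
    accepted = []
    for pair in pairs:
        if rng.random() < probabilities.probability(pair.reaction):
            accepted.append(pair)
    return accepted


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def execute_update(
    state: SystemState,
    accepted: Sequence[CandidatePair],
    mode: str = "all_nonbonded",
    swap_mode: str = "instantaneous",
    n_lambda_steps: int = 1,
    dynamics_hook: Callable[[SystemState, float], None] | None = None,
) -> tuple[SystemState, list[TransferEvent]]:
    """Execute the accepted transfers (in place) and log one event each.

    The donor switches to its deprotonated state, the acceptor to its
    protonated state; the total charge moved is exactly one proton per
    pair, so protonations and deprotonations balance within the event.
    """
    events: list[TransferEvent] = []
    lengths = state.box.array
    for pair in accepted:
        donor = state.residues[pair.donor_residue]
        acceptor = state.residues[pair.acceptor_residue]
        if not donor.is_protonated or acceptor.is_protonated:
            raise ConsistencyError(
                f"pair ({donor.id},{acceptor.id}) not in reactant states for "
                f"reaction {pair.reaction.name}"
            )
        com_i = state.residue_center(donor)
        com_j = state.residue_center(acceptor)
        r_ij = minimum_image(com_j - com_i, lengths)
        q_i_b, q_j_b = donor.current_charge, acceptor.current_charge

        donor_target = donor.template.name_deprotonated
        acceptor_target = acceptor.template.name_protonated
        if swap_mode == "interpolated":
            interpolate_states(
                state, pair, n_lambda_steps, dynamics_hook=dynamics_hook, mode=mode
            )
        else:
            apply_state_to_residue(state, donor, donor_target, mode=mode)
            apply_state_to_residue(state, acceptor, acceptor_target, mode=mode)

        events.append(
            TransferEvent(
                time=state.time,
                residue_i=donor.id,
                residue_j=acceptor.id,
                reaction=pair.reaction.name,
                q_i_before=q_i_b,
                q_j_before=q_j_b,
                q_i_after=donor.current_charge,
                q_j_after=acceptor.current_charge,
                com_i=tuple(com_i),
                com_j=tuple(com_j),
                r_ij=tuple(r_ij),
            )
        )
    return state, events


def interpolate_states(
    state: SystemState,
    pair: CandidatePair,
    n_steps: int,
    dynamics_hook: Callable[[SystemState, float], None] | None = None,
    mode: str = "all_nonbonded",
) -> SystemState:
    """Swap the pair's states along a linear charge path.

    At each intermediate lambda = k/n_steps every atomic charge of the two
    residues is (1-lambda) q_source + lambda q_target; ``dynamics_hook``
    is invoked between increments so the surroundings can relax.  The
    endpoint (lambda = 1) applies the full target state, identical to an
    instantaneous swap.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    donor = state.residues[pair.donor_residue]
    acceptor = state.residues[pair.acceptor_residue]
    moves = [
        (donor, donor.template.name_deprotonated),
        (acceptor, acceptor.template.name_protonated),
    ]
    source_q = {
        r.id: np.array([a.charge for a in r.template.atoms_for(r.current_state_name)])
        for r, _ in moves
    }
    target_q = {
        r.id: np.array([a.charge for a in r.template.atoms_for(target)])
        for r, target in moves
    }
    for k in range(1, n_steps + 1):
        lam = k / n_steps
        if k < n_steps:
            for r, _ in moves:
                q = (1.0 - lam) * source_q[r.id] + lam * target_q[r.id]
                state.charges[r.atom_start : r.atom_start + r.n_atoms] = q
            if dynamics_hook is not None:
                dynamics_hook(state, lam)
        else:
            for r, target in moves:
                apply_state_to_residue(state, r, target, mode=mode)
    return state


def run_update(
    state: SystemState,
    reactions: Sequence[TransferReaction],
    templates: Sequence[ResidueDualTemplate],
    probabilities: ProbabilityState,
    rng: np.random.Generator,
    mode: str = "all_nonbonded",
    swap_mode: str = "instantaneous",
    n_lambda_steps: int = 1,
    dynamics_hook: Callable[[SystemState, float], None] | None = None,
) -> tuple[SystemState, list[TransferEvent]]:
    """One full exchange step: detect, resolve, refresh feedback, accept,
    execute.  Probabilities are refreshed from the composition at the
    start of the step, before the acceptance draws."""
    probabilities.refresh(state.species_counts())
    candidates = find_candidates(state, reactions, templates)
    disjoint = resolve_conflicts(candidates)
    accepted = accept_transfers(disjoint, probabilities, rng)
    return execute_update(
        state,
        accepted,
        mode=mode,
        swap_mode=swap_mode,
        n_lambda_steps=n_lambda_steps,
        dynamics_hook=dynamics_hook,
    )
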