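"""The packaged desk-scale demonstration system.

A 1,000-residue single-bead box at the 30%:70% charged:neutral
partitioning (150 cation/anion pairs, 350 neutral pairs) with the four
standard transfer channels and the cubic count feedback active.  These
defaults *are* the study conditions used by the test suite and the
example scripts; docs/methods.md discusses each value.

Two condition choices deserve emphasis (details in the methods note):

* electrostatics are strongly screened (Debye-like 0.5 A, the formal
  screening length of a dense ionic melt).  At weak screening the bare
  +/-1 bead charges bind cation/anion contact pairs by tens of kT, every
  cation is permanently paired, and the near-unity discharge channel
  fires for all of them at every update — a bang-bang composition
  oscillation instead of the sparse-transfer regime the method models;
* the transfer cutoff sits just inside the soft-sphere contact distance
  (0.95 sigma), making transfer opportunities rare (a few per update
  across 1,000 residues), as an atomistic H-bond criterion is rare on
  the scale of a first coordination shell.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dynamics import IntegratorConfig, RunResult, ToyForceField, run
from .exchange import UpdateConfig
from .system import BoxSpec, SystemState, build_system
from .templates import (
    ResidueDualTemplate,
    TransferReaction,
    single_bead_reactions,
    single_bead_templates,
)

__all__ = ["DemoConditions", "build_demo_system", "demo_forcefield", "run_demo"]


@dataclass(frozen=True)
class DemoConditions:
    """Fixed conditions of the packaged demonstration run."""

    n_cation_anion_pairs: int = 150
    n_neutral_pairs: int = 350
    box_length: float = 43.0  # A -> liquid-like packing at sigma = 4 A
    sigma: float = 4.0  # A bead contact scale
    epsilon: float = 0.5  # kcal/mol soft-sphere hardness
    screening_length: float = 0.5  # A (dense-melt Debye screening)
    cutoff: float = 8.0  # A interaction cutoff
    min_separation: float = 3.4  # A packing constraint
    r_max_factor: float = 0.95  # transfer cutoff = 0.95 sigma
    c: float = 300.0  # feedback constant
    temperature: float = 300.0  # K
    friction: float = 20.0  # 1/ps
    mass: float = 100.0  # amu
    timestep: float = 0.02  # ps
    update_interval: float = 0.5  # ps (25 mixing steps per cycle)
    n_cycles: int = 250
    n_equil_steps: int = 500  # plain dynamics before exchanges start
    frame_stride: int = 25  # steps -> one frame per update interval

    @property
    def r_max(self) -> float:
        return self.r_max_factor * self.sigma

    @property
    def n_residues(self) -> int:
        return 2 * (self.n_cation_anion_pairs + self.n_neutral_pairs)


def demo_forcefield(conditions: DemoConditions = DemoConditions()) -> ToyForceField:
    return ToyForceField(
        epsilon=conditions.epsilon,
        sigma=conditions.sigma,
        screening_length=conditions.screening_length,
        cutoff=conditions.cutoff,
    )


def build_demo_system(
    seed: int, conditions: DemoConditions = DemoConditions()
) -> tuple[SystemState, list[ResidueDualTemplate], list[TransferReaction]]:
    templates = single_bead_templates(sigma=conditions.sigma)
    reactions = single_bead_reactions(r_max=conditions.r_max, c=conditions.c)
    state = build_system(
        conditions.n_cation_anion_pairs,
        conditions.n_neutral_pairs,
        BoxSpec.cubic(conditions.box_length),
        min_separation=conditions.min_separation,
        seed=seed,
        templates=templates,
    )
    return state, templates, reactions


def run_demo(
    seed: int,
    conditions: DemoConditions = DemoConditions(),
    record_energies: bool = False,
) -> RunResult:
    """Build, equilibrate and run the packaged demo (deterministic per seed)."""
    state, templates, reactions = build_demo_system(seed, conditions)
    ff = demo_forcefield(conditions)
    if conditions.n_equil_steps:
        equil = IntegratorConfig(
            timestep=conditions.timestep,
            temperature=conditions.temperature,
            friction=conditions.friction,
            mass=conditions.mass,
            seed=seed + 3,
            n_steps=conditions.n_equil_steps,
        )
        run(state, ff, equil, None, frame_stride=conditions.n_equil_steps)
        state.time = 0.0
    steps_per_cycle = int(round(conditions.update_interval / conditions.timestep))
    integ = IntegratorConfig(
        timestep=conditions.timestep,
        temperature=conditions.temperature,
        friction=conditions.friction,
        mass=conditions.mass,
        seed=seed + 1,
        n_steps=conditions.n_cycles * steps_per_cycle,
    )
    upd = UpdateConfig(update_interval=conditions.update_interval, seed=seed + 2)
    return run(
        state,
        ff,
        integ,
        upd,
        templates=templates,
        reactions=reactions,
        frame_stride=conditions.frame_stride,
        record_energies=record_energies,
    )
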