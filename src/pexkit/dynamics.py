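"""Minimal Brownian-dynamics engine for single-bead residues.

The engine exists to *exercise* the exchange machinery and the analyses
at desk scale, not to reproduce condensed-phase physics: residues are
soft spheres (WCA repulsion) with bead charges interacting through a
screened (Yukawa) Coulomb potential, propagated by an overdamped
(position-Langevin) integrator in an orthorhombic periodic box.

    U = sum_pairs WCA(r) + C q_i q_j exp(-r/lambda_s)/r   (min. image)

Both terms are cut off at ``ff.cutoff`` and the Coulomb term is shifted
so U(cutoff) = 0.  With ``screening_length=None`` the bare 1/r Coulomb
potential is used (intended for small unscreened test cases, typically
together with ``cutoff=None``).

The overdamped update is

    x += (D0 / kT) F dt + sqrt(2 D0 dt) xi,   D0 = kT / (m gamma)

so free beads diffuse with the analytic D0 — the reference point for the
transport-analysis validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import NumericsError
from .exchange import ProbabilityState, UpdateConfig, run_update
from .geometry import fold, minimum_image
from .io import Trajectory
from .system import SystemState, TransferEvent
from .templates import ResidueDualTemplate, TransferReaction
from .units import AMU_A2_PS2_IN_KCAL_MOL, DEFAULT_UNITS, UnitSystem

__all__ = [
    "ToyForceField",
    "IntegratorConfig",
    "RunResult",
    "compute_forces_energy",
    "brownian_step",
    "diffusion_coefficient",
    "run",
]


@dataclass(frozen=True)
class ToyForceField:
    """Soft-sphere + screened-Coulomb bead force field.

    sigma/epsilon set the WCA contact scale; charges are read from the
    system state (so protonation-state swaps take effect immediately).
    """

    epsilon: float = 0.2  # kcal/mol
    sigma: float = 4.0  # A
    screening_length: float | None = 5.0  # A; None -> bare Coulomb
    cutoff: float | None = 12.0  # A; None -> all pairs
    units: UnitSystem = DEFAULT_UNITS

    @property
    def wca_range(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma


@dataclass(frozen=True)
class IntegratorConfig:
    """Overdamped-integrator parameters."""

    timestep: float = 0.02  # ps
    temperature: float = 300.0  # K
    friction: float = 20.0  # 1/ps
    mass: float = 100.0  # amu
    seed: int = 0
    n_steps: int = 1000

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction <= 0 or self.mass <= 0:
            raise ValueError("friction and mass must be > 0")

    def diffusion_coefficient(self, units: UnitSystem = DEFAULT_UNITS) -> float:
        """Free-particle D0 = kT/(m*gamma) in A^2/ps."""
        kT = units.kT(self.temperature)
        return kT / (self.mass * self.friction) / AMU_A2_PS2_IN_KCAL_MOL


def diffusion_coefficient(cfg: IntegratorConfig) -> float:
    return cfg.diffusion_coefficient()


def _pair_list(
    positions: np.ndarray, lengths: np.ndarray, cutoff: float | None
) -> tuple[np.ndarray, np.ndarray]:
    n = len(positions)
    if cutoff is None:
        ii, jj = np.triu_indices(n, k=1)
        return ii, jj
    tree = cKDTree(fold(positions, lengths), boxsize=lengths)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty(0, int), np.empty(0, int)
    return pairs[:, 0], pairs[:, 1]


def compute_forces_energy(
    state: SystemState, ff: ToyForceField
) -> tuple[np.ndarray, dict[str, float]]:
    """Forces (kcal/mol/A) and energy components for the toy force field.

    Raises :class:`NumericsError` on (near-)coincident beads.  Forces obey
    Newton's third law pairwise and sum to zero.
    """
    lengths = state.box.array
    if ff.cutoff is not None and ff.cutoff >= state.box.min_length / 2.0:
        raise ValueError("cutoff must be < half the smallest box length")
    pos = state.positions
    ii, jj = _pair_list(pos, lengths, ff.cutoff)
    forces = np.zeros_like(pos)
    energies = {"wca": 0.0, "coulomb": 0.0}
    if len(ii) == 0:
        energies["total"] = 0.0
        return forces, energies

    d = minimum_image(pos[jj] - pos[ii], lengths)
    r2 = np.sum(d * d, axis=1)
    if np.any(r2 < 1e-12):
        k = int(np.argmin(r2))
        raise NumericsError(
            f"beads {ii[k]} and {jj[k]} are (near-)coincident: r={np.sqrt(r2[k]):.2e} A"
        )
    r = np.sqrt(r2)

    # WCA: purely repulsive, zero beyond 2^(1/6) sigma
    wca_mask = r < ff.wca_range
    e_wca = np.zeros_like(r)
    f_wca = np.zeros_like(r)  # magnitude / r along d
    if np.any(wca_mask):
        rr = r[wca_mask]
        sr6 = (ff.sigma / rr) ** 6
        sr12 = sr6 * sr6
        e_wca[wca_mask] = 4.0 * ff.epsilon * (sr12 - sr6) + ff.epsilon
        f_wca[wca_mask] = 24.0 * ff.epsilon * (2.0 * sr12 - sr6) / (rr * rr)

    # screened Coulomb, shifted to zero at the cutoff
    qq = state.charges[ii] * state.charges[jj]
    C = ff.units.coulomb_constant
    if ff.screening_length is None:
        screen = np.ones_like(r)
        dscreen = np.zeros_like(r)
    else:
        screen = np.exp(-r / ff.screening_length)
        dscreen = screen / ff.screening_length
    e_coul = C * qq * screen / r
    if ff.cutoff is not None:
        if ff.screening_length is None:
            shift = C * qq / ff.cutoff
        else:
            shift = C * qq * np.exp(-ff.cutoff / ff.screening_length) / ff.cutoff
        e_coul = e_coul - shift
    # -dU/dr = C qq (screen/r^2 + dscreen/r); as prefactor of d/r:
    f_coul = C * qq * (screen / r2 + dscreen / r) / r

    fvec = (f_wca + f_coul)[:, None] * d
    n = len(pos)
    for k in range(3):
        forces[:, k] = np.bincount(jj, weights=fvec[:, k], minlength=n) - np.bincount(
            ii, weights=fvec[:, k], minlength=n
        )

    energies["wca"] = float(np.sum(e_wca))
    energies["coulomb"] = float(np.sum(e_coul))
    energies["total"] = energies["wca"] + energies["coulomb"]
    return forces, energies


def brownian_step(
    state: SystemState,
    forces: np.ndarray,
    cfg: IntegratorConfig,
    rng: np.random.Generator,
    units: UnitSystem = DEFAULT_UNITS,
) -> SystemState:
    """One overdamped step; positions refolded, time advanced by dt."""
    dt = cfg.timestep
    D0 = cfg.diffusion_coefficient(units)
    kT = units.kT(cfg.temperature)
    mobility = 1.0 / (cfg.mass * cfg.friction) / AMU_A2_PS2_IN_KCAL_MOL  # = D0/kT
    noise = np.sqrt(2.0 * D0 * dt) * rng.standard_normal(state.positions.shape)
    new = state.positions + mobility * forces * dt + noise
    if not np.all(np.isfinite(new)):
        raise NumericsError(
            "non-finite positions after Brownian step; reduce the timestep"
        )
    state.positions = fold(new, state.box.array)
    state.time += dt
    return state


@dataclass
class RunResult:
    """Everything a toy run emits."""

    trajectory: Trajectory
    events: list[TransferEvent]
    charge_report: pd.DataFrame
    energy_report: pd.DataFrame
    probability_trace: pd.DataFrame
    composition_trace: pd.DataFrame


def run(
    state: SystemState,
    ff: ToyForceField,
    integrator_cfg: IntegratorConfig,
    update_cfg: UpdateConfig | None,
    templates: Sequence[ResidueDualTemplate] = (),
    reactions: Sequence[TransferReaction] = (),
    frame_stride: int = 25,
    record_energies: bool = True,
) -> RunResult:
    """Alternate Brownian dynamics with exchange updates.

    Frames are recorded every ``frame_stride`` steps (plus the initial
    frame); exchange updates fire exactly every ``update_interval``; the
    charge report and composition trace are appended at every update.
    With ``update_cfg=None`` this is a plain Brownian run with an empty
    event log.
    """
    from .reporters import report_charges  # local import to avoid cycle

    dt = integrator_cfg.timestep
    n_steps = integrator_cfg.n_steps
    if update_cfg is not None:
        steps_per_update = int(round(update_cfg.update_interval / dt))
        if not np.isclose(steps_per_update * dt, update_cfg.update_interval):
            raise ValueError("update_interval must be a multiple of the timestep")
        if steps_per_update % frame_stride != 0:
            raise ValueError("update interval must be a multiple of the frame stride")
    else:
        steps_per_update = 0

    dyn_rng = np.random.default_rng(integrator_cfg.seed)
    exch_rng = np.random.default_rng(update_cfg.seed if update_cfg else 0)
    prob_state = (
        ProbabilityState.from_reactions(reactions, state.species_counts())
        if update_cfg is not None and reactions
        else None
    )

    # label atoms by the residue's state at the start of the run, so a
    # written trajectory + event log fully determine the state history
    initial_labels = [
        r.current_state_name for r in state.residues for _ in range(r.n_atoms)
    ]
    times = [state.time]
    frames = [state.positions.copy()]
    events: list[TransferEvent] = []
    charge_rows: list[pd.DataFrame] = [report_charges(state)]
    energy_rows: list[dict] = []
    prob_rows: list[dict] = []
    comp_rows: list[dict] = []

    for step in range(1, n_steps + 1):
        forces, energies = compute_forces_energy(state, ff)
        brownian_step(state, forces, integrator_cfg, dyn_rng, ff.units)
        if step % frame_stride == 0:
            times.append(state.time)
            frames.append(state.positions.copy())
        if steps_per_update and step % steps_per_update == 0:
            state, new_events = run_update(
                state,
                reactions,
                templates,
                prob_state,
                exch_rng,
                swap_mode=update_cfg.swap_mode,
                n_lambda_steps=update_cfg.n_lambda_steps,
            )
            events.extend(new_events)
            charge_rows.append(report_charges(state))
            counts = state.species_counts()
            comp_rows.append({"time_ps": state.time, **counts})
            if prob_state is not None:
                prob_rows.append(
                    {"time_ps": state.time, **prob_state.current}
                )
            if record_energies:
                _, e_after = compute_forces_energy(state, ff)
                energy_rows.append({"time_ps": state.time, **e_after})

    traj = Trajectory(
        times=np.asarray(times),
        positions=np.asarray(frames),
        box=state.box,
        atom_names=initial_labels,
    )
    return RunResult(
        trajectory=traj,
        events=events,
        charge_report=pd.concat(charge_rows, ignore_index=True),
        energy_report=pd.DataFrame(energy_rows),
        probability_trace=pd.DataFrame(prob_rows),
        composition_trace=pd.DataFrame(comp_rows),
    )
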