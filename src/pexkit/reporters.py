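"""Pure reporters: per-residue charge table and per-component energy table."""

from __future__ import annotations

import pandas as pd

from .system import SystemState

__all__ = ["report_charges", "report_energies"]


def report_charges(state: SystemState) -> pd.DataFrame:
    """One row per residue: (time_ps, residue_id, state, charge_e).

    The charge column sums to the total system charge.  Does not mutate
    the state.
    """
    rows = [
        (state.time, r.id, r.current_state_name, r.current_charge)
        for r in state.residues
    ]
    return pd.DataFrame(rows, columns=["time_ps", "residue_id", "state", "charge_e"])


def report_energies(state: SystemState, forcefield) -> pd.DataFrame:
    """One row per force component plus the total (kcal/mol)."""
    from .dynamics import compute_forces_energy

    _, energies = compute_forces_energy(state, forcefield)
    rows = [(state.time, name, e) for name, e in energies.items()]
    return pd.DataFrame(rows, columns=["time_ps", "component", "energy_kcal_mol"])
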