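import numpy as np
import pytest

import pexkit as pk


@pytest.fixture(scope="session")
def atomistic():
    """Packaged atomistic dual-state templates + the four reactions."""
    templates, reactions = pk.imidazolium_acetate_templates()
    return templates, reactions


@pytest.fixture(scope="session")
def bead_templates():
    return pk.single_bead_templates(sigma=4.0)


@pytest.fixture()
def two_bead_system(bead_templates):
    """One cation + one anion in a large box; positions settable by tests."""

    def make(distance, state_a="IM1H", state_b="OAC", box_length=40.0):
        by_state = {s: t for t in bead_templates for s in t.state_names}
        residues = []
        charges, eps, rmin = [], [], []
        for rid, (s, x) in enumerate([(state_a, 0.0), (state_b, distance)]):
            t = by_state[s]
            residues.append(
                pk.Residue(id=rid, template=t, current_state_name=s, atom_start=rid)
            )
            a = t.atoms_for(s)[0]
            charges.append(a.charge)
            eps.append(a.lj_epsilon)
            rmin.append(a.lj_rmin_half)
        return pk.SystemState(
            positions=np.array([[1.0, 1.0, 1.0], [1.0 + distance, 1.0, 1.0]]),
            box=pk.BoxSpec.cubic(box_length),
            residues=residues,
            charges=np.array(charges),
            lj_epsilon=np.array(eps),
            lj_rmin_half=np.array(rmin),
            atom_names=["BD", "BD"],
        )

    return make


@pytest.fixture(scope="session")
def small_packed_system(bead_templates):
    """Deterministic 60-residue packed box for engine-level tests."""
    return pk.build_system(
        10, 20, pk.BoxSpec.cubic(20.0), min_separation=3.0, seed=11,
        templates=bead_templates,
    )
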