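"""Dual-state residue templates and transfer-reaction definitions.

A residue that can gain or lose a proton is represented in a *single
topology*: one atom list shared by both protonation states, with a
one-to-one mapping between the per-state parameter sets.  Switching state
swaps per-atom charges, Lennard-Jones parameters and polarizabilities; a
proton that vanishes on deprotonation stays in the topology as a *dummy
atom* (zero charge, negligible LJ well).

A :class:`TransferReaction` names a reactant pair, a product pair, the
donor-acceptor distance cutoff ``r_max`` and the reference acceptance
probability ``p_ref``, plus the feedback constant ``c`` used to steer the
charged/neutral partitioning during a run (see :mod:`pexkit.exchange`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError, MappingError

__all__ = [
    "AtomStateParams",
    "ResidueDualTemplate",
    "TransferReaction",
    "load_templates",
    "dump_templates",
    "validate_mapping",
    "imidazolium_acetate_config_path",
    "imidazolium_acetate_templates",
    "single_bead_templates",
    "single_bead_reactions",
]


@dataclass(frozen=True)
class AtomStateParams:
    """Non-bonded parameters of one atom in one protonation state.

    ``lj_epsilon`` and ``polarizability`` are stored as magnitudes;
    CHARMM-style tables print both with a minus sign by convention and the
    loader normalises the sign.  Dummy atoms carry zero charge and zero
    polarizability.
    """

    atom_name: str
    atom_type: str
    lj_epsilon: float
    lj_rmin_half: float
    charge: float
    polarizability: float = 0.0
    thole: float = 0.0

    def __post_init__(self) -> None:
        if self.lj_rmin_half <= 0:
            raise ConfigError(
                f"atom {self.atom_name}: lj_rmin_half must be > 0, got {self.lj_rmin_half}"
            )
        if self.lj_epsilon < 0 or self.polarizability < 0:
            raise ConfigError(
                f"atom {self.atom_name}: lj_epsilon and polarizability are stored "
                "as magnitudes (>= 0); normalise signs before construction"
            )

    @property
    def is_dummy_like(self) -> bool:
        return self.charge == 0.0 and self.polarizability == 0.0


@dataclass(frozen=True)
class ResidueDualTemplate:
    """The two parameter states of one exchangeable residue.

    ``atom_mapping`` maps protonated-state atom names to deprotonated-state
    atom names (a bijection).  ``donor_atoms`` are the transferable
    hydrogens of the protonated state; ``acceptor_atoms`` the heavy-atom
    acceptor sites of the deprotonated state (e.g. both carboxylate
    oxygens); ``dummy_atoms`` the names that are dummies in the
    deprotonated state.  Coarse-grained single-bead templates declare no
    dummy atoms: the bead itself is donor and acceptor.
    """

    name_protonated: str
    name_deprotonated: str
    atoms_protonated: tuple[AtomStateParams, ...]
    atoms_deprotonated: tuple[AtomStateParams, ...]
    atom_mapping: Mapping[str, str]
    donor_atoms: tuple[str, ...]
    acceptor_atoms: tuple[str, ...]
    dummy_atoms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        violations = validate_mapping(self)
        if violations:
            raise MappingError(
                f"template {self.name_protonated}/{self.name_deprotonated}: "
                + "; ".join(violations)
            )

    # -- state access -------------------------------------------------
    @property
    def state_names(self) -> tuple[str, str]:
        return (self.name_protonated, self.name_deprotonated)

    def atoms_for(self, state_name: str) -> tuple[AtomStateParams, ...]:
        if state_name == self.name_protonated:
            return self.atoms_protonated
        if state_name == self.name_deprotonated:
            return self.atoms_deprotonated
        raise KeyError(
            f"state {state_name!r} not in template "
            f"{self.name_protonated}/{self.name_deprotonated}"
        )

    def other_state(self, state_name: str) -> str:
        prot, deprot = self.state_names
        if state_name == prot:
            return deprot
        if state_name == deprot:
            return prot
        raise KeyError(f"state {state_name!r} not in template {self.state_names}")

    def net_charge(self, state_name: str) -> int:
        return round(sum(a.charge for a in self.atoms_for(state_name)))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms_protonated)

    def donor_atom_indices(self) -> list[int]:
        """Indices (into the shared atom order) of the protonated-state donors."""
        names = [a.atom_name for a in self.atoms_protonated]
        return [names.index(n) for n in self.donor_atoms]

    def acceptor_atom_indices(self) -> list[int]:
        names = [a.atom_name for a in self.atoms_deprotonated]
        return [names.index(n) for n in self.acceptor_atoms]


def validate_mapping(t: ResidueDualTemplate) -> list[str]:
    """Return a list of invariant violations (empty list when valid).

    Checks cardinality, bijectivity, donor/acceptor/dummy name resolution
    and, for templates that declare dummy atoms, that every donor maps to a
    dummy in the deprotonated state.
    """
    violations: list[str] = []
    prot_names = [a.atom_name for a in t.atoms_protonated]
    deprot_names = [a.atom_name for a in t.atoms_deprotonated]

    if len(prot_names) != len(deprot_names):
        violations.append(
            f"state atom counts differ: {len(prot_names)} vs {len(deprot_names)}"
        )

    mapping = dict(t.atom_mapping)
    unmatched_src = [n for n in prot_names if n not in mapping]
    if unmatched_src:
        violations.append(f"unmatched protonated atoms: {unmatched_src}")
    targets = list(mapping.values())
    if len(set(targets)) != len(targets):
        violations.append("mapping is not injective")
    unmatched_dst = [n for n in deprot_names if n not in set(targets)]
    if unmatched_dst:
        violations.append(f"unmatched deprotonated atoms: {unmatched_dst}")
    bogus = [n for n in targets if n not in deprot_names]
    if bogus:
        violations.append(f"mapping targets not in deprotonated list: {bogus}")

    for d in t.donor_atoms:
        if d not in prot_names:
            violations.append(f"donor atom {d!r} not in protonated atom list")
    for a in t.acceptor_atoms:
        if a not in deprot_names:
            violations.append(f"acceptor atom {a!r} not in deprotonated atom list")
    for dm in t.dummy_atoms:
        if dm not in deprot_names:
            violations.append(f"dummy atom {dm!r} not in deprotonated atom list")

    if t.dummy_atoms:
        deprot_by_name = {a.atom_name: a for a in t.atoms_deprotonated}
        for d in t.donor_atoms:
            target = mapping.get(d)
            if target is None:
                continue
            if target not in t.dummy_atoms:
                violations.append(f"donor {d!r} maps to non-dummy {target!r}")
            elif target in deprot_by_name and not deprot_by_name[target].is_dummy_like:
                violations.append(
                    f"declared dummy {target!r} carries charge or polarizability"
                )
    return violations


@dataclass(frozen=True)
class TransferReaction:
    """One proton-transfer channel between two residue-state names.

    ``p_ref`` is a probability *fraction* in [0, 1]; configuration files
    may state it on the percent scale (``p_ref_percent``) and the loader
    divides by 100.  ``monitor_species`` is the species whose current count
    drives the cubic feedback rule; it defaults to the first reactant (the
    species the reaction consumes).
    """

    reactant_pair: tuple[str, str]
    product_pair: tuple[str, str]
    r_max: float
    p_ref: float
    c: float
    monitor_species: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_ref <= 1.0):
            raise ConfigError(f"p_ref must be in [0,1], got {self.p_ref}")
        if self.r_max <= 0:
            raise ConfigError(f"r_max must be > 0, got {self.r_max}")
        if not self.monitor_species:
            object.__setattr__(self, "monitor_species", self.reactant_pair[0])
        if not self.name:
            object.__setattr__(
                self,
                "name",
                f"{self.reactant_pair[0]}+{self.reactant_pair[1]}"
                f"->{self.product_pair[0]}+{self.product_pair[1]}",
            )

    @property
    def is_swap(self) -> bool:
        """True when products are a permutation of reactants (identity swap).

        Swap channels shuttle a proton between two residues of the same
        template and leave the species composition unchanged, so the count
        feedback cannot (and does not) act on them.
        """
        return sorted(self.reactant_pair) == sorted(self.product_pair)


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

_ATOM_FIELDS = ("name", "type", "lj_epsilon", "lj_rmin_half", "charge", "alpha", "thole")


def _atom_from_record(rec: Mapping, residue: str) -> AtomStateParams:
    try:
        return AtomStateParams(
            atom_name=str(rec["name"]),
            atom_type=str(rec["type"]),
            lj_epsilon=abs(float(rec["lj_epsilon"])),
            lj_rmin_half=float(rec["lj_rmin_half"]),
            charge=float(rec["charge"]),
            polarizability=abs(float(rec.get("alpha", 0.0))),
            thole=float(rec.get("thole", 0.0)),
        )
    except KeyError as exc:
        raise ConfigError(f"residue {residue}: atom record missing field {exc}") from exc


def load_templates(
    source: str | Path | Mapping,
) -> tuple[list[ResidueDualTemplate], list[TransferReaction]]:
    """Parse a template/reaction configuration.

    ``source`` is a YAML file path or an already-parsed mapping with
    ``residues`` and ``reactions`` sections.  Referential integrity is
    enforced: every reaction must name residue-state names defined by some
    template, donors/acceptors must resolve, and the per-residue atom
    mapping must be a bijection.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping) or "residues" not in doc:
        raise ConfigError("configuration must contain a 'residues' section")

    templates: list[ResidueDualTemplate] = []
    for rec in doc["residues"]:
        prot = str(rec["protonated"])
        atoms_p = tuple(_atom_from_record(a, prot) for a in rec["atoms_protonated"])
        atoms_d = tuple(_atom_from_record(a, prot) for a in rec["atoms_deprotonated"])
        mapping = rec.get("mapping", "identity")
        if mapping == "identity":
            mapping = {a.atom_name: a.atom_name for a in atoms_p}
        for key in ("donor_atoms", "acceptor_atoms"):
            if key not in rec:
                raise ConfigError(f"residue {prot}: missing {key}")
        try:
            templates.append(
                ResidueDualTemplate(
                    name_protonated=prot,
                    name_deprotonated=str(rec["deprotonated"]),
                    atoms_protonated=atoms_p,
                    atoms_deprotonated=atoms_d,
                    atom_mapping=dict(mapping),
                    donor_atoms=tuple(rec["donor_atoms"]),
                    acceptor_atoms=tuple(rec["acceptor_atoms"]),
                    dummy_atoms=tuple(rec.get("dummy_atoms", ())),
                )
            )
        except MappingError:
            raise
        except KeyError as exc:
            raise ConfigError(f"residue {prot}: missing field {exc}") from exc

    known_states = {s for t in templates for s in t.state_names}
    reactions: list[TransferReaction] = []
    for rec in doc.get("reactions", ()):
        reactants = tuple(str(x) for x in rec["reactants"])
        products = tuple(str(x) for x in rec["products"])
        for name in (*reactants, *products):
            if name not in known_states:
                raise ConfigError(
                    f"reaction references undefined residue-state name {name!r}"
                )
        if "p_ref_percent" in rec:
            p_ref = float(rec["p_ref_percent"]) / 100.0
        else:
            p_ref = float(rec["p_ref"])
        reactions.append(
            TransferReaction(
                reactant_pair=reactants,  # type: ignore[arg-type]
                product_pair=products,  # type: ignore[arg-type]
                r_max=float(rec["r_max"]),
                p_ref=p_ref,
                c=float(rec.get("c", 0.0)),
                monitor_species=str(rec.get("monitor_species", "")),
            )
        )
    return templates, reactions


def dump_templates(
    templates: Iterable[ResidueDualTemplate],
    reactions: Iterable[TransferReaction],
    path: str | Path,
) -> None:
    """Write a configuration that :func:`load_templates` reads back bit-exactly."""

    def atom_rec(a: AtomStateParams) -> dict:
        return {
            "name": a.atom_name,
            "type": a.atom_type,
            "lj_epsilon": a.lj_epsilon,
            "lj_rmin_half": a.lj_rmin_half,
            "charge": a.charge,
            "alpha": a.polarizability,
            "thole": a.thole,
        }

    doc = {
        "residues": [
            {
                "protonated": t.name_protonated,
                "deprotonated": t.name_deprotonated,
                "donor_atoms": list(t.donor_atoms),
                "acceptor_atoms": list(t.acceptor_atoms),
                "dummy_atoms": list(t.dummy_atoms),
                "mapping": dict(t.atom_mapping),
                "atoms_protonated": [atom_rec(a) for a in t.atoms_protonated],
                "atoms_deprotonated": [atom_rec(a) for a in t.atoms_deprotonated],
            }
            for t in templates
        ],
        "reactions": [
            {
                "reactants": list(r.reactant_pair),
                "products": list(r.product_pair),
                "r_max": r.r_max,
                "p_ref": r.p_ref,
                "c": r.c,
                "monitor_species": r.monitor_species,
            }
            for r in reactions
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def imidazolium_acetate_config_path() -> Path:
    """Path of the packaged 1-methylimidazolium acetate configuration."""
    return Path(resources.files("pexkit.data") / "imidazolium_acetate.yaml")


def imidazolium_acetate_templates() -> tuple[list[ResidueDualTemplate], list[TransferReaction]]:
    """Load the packaged atomistic IM1H/IM1 + OAC/HOAC dual-state fixture."""
    return load_templates(imidazolium_acetate_config_path())


def _bead(name: str, charge: float, sigma: float) -> AtomStateParams:
    # single-bead residues: r_min/2 = 2^(1/6) sigma / 2 so that r_min = 2^(1/6) sigma
    return AtomStateParams(
        atom_name=name,
        atom_type=name,
        lj_epsilon=0.2,
        lj_rmin_half=2.0 ** (1.0 / 6.0) * sigma / 2.0,
        charge=charge,
    )


def single_bead_templates(sigma: float = 4.0) -> list[ResidueDualTemplate]:
    """Coarse-grained one-bead templates for the cation/neutral base and
    acid/anion pairs (state names IM1H/IM1 and HOAC/OAC).

    The bead is simultaneously donor site and acceptor site; switching
    state only changes the bead charge (+1/0 for the base, 0/-1 for the
    acid).  No dummy atoms exist at this resolution.
    """
    base = ResidueDualTemplate(
        name_protonated="IM1H",
        name_deprotonated="IM1",
        atoms_protonated=(_bead("BD", 1.0, sigma),),
        atoms_deprotonated=(_bead("BD", 0.0, sigma),),
        atom_mapping={"BD": "BD"},
        donor_atoms=("BD",),
        acceptor_atoms=("BD",),
    )
    acid = ResidueDualTemplate(
        name_protonated="HOAC",
        name_deprotonated="OAC",
        atoms_protonated=(_bead("BD", 0.0, sigma),),
        atoms_deprotonated=(_bead("BD", -1.0, sigma),),
        atom_mapping={"BD": "BD"},
        donor_atoms=("BD",),
        acceptor_atoms=("BD",),
    )
    return [base, acid]


def single_bead_reactions(
    r_max: float,
    c: float = 300.0,
    p_ref: Sequence[float] = (0.994, 0.098, 0.201, 0.684),
) -> list[TransferReaction]:
    """The four transfer channels on the coarse-grained system.

    ``p_ref`` follows the standard reaction ordering: cation+anion ->
    neutral, neutral -> cation+anion, cation/base swap, acid/anion swap.
    ``r_max`` is a bead-contact criterion (typically ~1.2 sigma), not the
    atomistic H-bond distance.
    """
    p1, p2, p3, p4 = p_ref
    return [
        TransferReaction(("IM1H", "OAC"), ("IM1", "HOAC"), r_max, p1, c),
        TransferReaction(("IM1", "HOAC"), ("IM1H", "OAC"), r_max, p2, c),
        TransferReaction(("IM1H", "IM1"), ("IM1", "IM1H"), r_max, p3, c),
        TransferReaction(("HOAC", "OAC"), ("OAC", "HOAC"), r_max, p4, c),
    ]
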