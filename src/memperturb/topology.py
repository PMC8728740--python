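"""Role-annotated topology for bilayer systems.

A :class:`Topology` maps every atom to a molecule and a molecule kind
(POPC lipid, permeation enhancer, water, ion), and carries the role sets the
analyses need: phosphate headgroup atoms, terminal acyl-tail carbons and their
hydrogens, water sites, and the per-enhancer reference (headgroup) atom and
chain carbons.  Roles are resolved from configurable atom-name patterns so the
same machinery serves CHARMM-style files and synthetic fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import ConfigurationError

MOLECULE_KINDS = ("POPC", "PE", "water", "ion")

ROLE_LABELS = (
    "phosphate",
    "tail_carbon_last3",
    "tail_hydrogen_last3",
    "water_site",
    "pe_reference",
    "pe_chain",
)

_WATER_RESNAMES = {"SOL", "HOH", "TIP3", "TIP3P", "WAT", "W", "SPC"}
_ION_RESNAMES = {"NA", "CL", "SOD", "CLA", "K", "POT", "CA", "MG", "NA+", "CL-"}
_LIPID_RESNAMES = {"POPC"}

# Approximate atomic masses for center-of-mass work; keyed by leading element
# letter(s) of the atom name.
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06}


def classify_resname(resname: str) -> str:
    """Molecule kind for a residue name: POPC, water, ion, else PE."""
    up = resname.upper()
    if up in _LIPID_RESNAMES:
        return "POPC"
    if up in _WATER_RESNAMES:
        return "water"
    if up in _ION_RESNAMES:
        return "ion"
    return "PE"


def atom_mass(name: str) -> float:
    """Mass guess from an atom name (two-letter element first, then one)."""
    up = name.strip().upper()
    if up[:2] in _MASSES:
        return _MASSES[up[:2]]
    if up[:1] in _MASSES:
        return _MASSES[up[:1]]
    return 12.011


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    mol_id: int
    mol_kind: str
    resname: str


@dataclass
class RoleSpec:
    """Atom-name patterns used to resolve roles.

    Each entry is a regular expression matched against the full atom name.
    The tail-hydrogen role is resolved by proximity to an already-matched
    terminal tail carbon (same molecule, within ``ch_bond_cutoff`` nm in the
    first frame), filtered by ``tail_hydrogen_pattern``; this avoids having to
    enumerate every CHARMM hydrogen name.
    """

    phosphate_pattern: str = r"^P[0-9]*$"
    tail_carbon_pattern: str = r"^(C216|C217|C218|C314|C315|C316)$"
    tail_hydrogen_pattern: str = r"^H[0-9]+[RSTXYZ]$"
    water_site_pattern: str = r"^(OW|OH2|O|W)$"
    pe_reference_pattern: str = r"^(C1|N1|O1)$"
    pe_chain_pattern: str = r"^C[0-9]+$"
    ch_bond_cutoff: float = 0.15


DEFAULT_ROLE_SPEC = RoleSpec()


@dataclass
class Topology:
    """Atoms, role sets, and initial leaflet labels for one system."""

    atoms: Sequence[Atom]
    roles: Mapping[str, frozenset[int]]
    leaflet0: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.roles = {k: frozenset(v) for k, v in self.roles.items()}
        for label in ROLE_LABELS:
            self.roles.setdefault(label, frozenset())
        n = len(self.atoms)
        for label, idx in self.roles.items():
            bad = [i for i in idx if not (0 <= i < n)]
            if bad:
                raise ConfigurationError(f"role {label} references unknown atoms {bad}")
        # exactly one reference site per enhancer
        ref_by_mol: dict[int, int] = {}
        for i in self.roles["pe_reference"]:
            mol = self.atoms[i].mol_id
            ref_by_mol[mol] = ref_by_mol.get(mol, 0) + 1
        for mol in self.molecule_ids("PE"):
            if ref_by_mol.get(mol, 0) != 1:
                raise ConfigurationError(
                    f"PE molecule {mol} must have exactly one pe_reference atom, "
                    f"found {ref_by_mol.get(mol, 0)}"
                )
        for lab in self.leaflet0.values():
            if lab not in ("upper", "lower"):
                raise ConfigurationError(f"leaflet label must be upper/lower, got {lab!r}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def molecule_ids(self, kind: str | None = None) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if kind is None or a.mol_kind == kind:
                seen.setdefault(a.mol_id, None)
        return list(seen)

    def atom_indices(self, mol_id: int) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.mol_id == mol_id], dtype=int)

    def role_indices(self, label: str) -> np.ndarray:
        return np.array(sorted(self.roles[label]), dtype=int)

    def pe_reference_index(self, pe_id: int) -> int:
        for i in self.roles["pe_reference"]:
            if self.atoms[i].mol_id == pe_id:
                return i
        raise KeyError(f"no pe_reference atom for PE molecule {pe_id}")

    def pe_species(self, pe_id: int) -> str:
        for a in self.atoms:
            if a.mol_id == pe_id:
                return a.resname
        raise KeyError(f"unknown molecule {pe_id}")

    def phosphate_of(self, mol_id: int) -> int | None:
        for i in self.roles["phosphate"]:
            if self.atoms[i].mol_id == mol_id:
                return i
        return None

    def masses(self) -> np.ndarray:
        return np.array([atom_mass(a.name) for a in self.atoms])


def resolve_roles(
    atoms: Sequence[Atom],
    xyz0: np.ndarray,
    spec: RoleSpec = DEFAULT_ROLE_SPEC,
) -> dict[str, frozenset[int]]:
    """Resolve role sets from atom-name patterns and first-frame geometry.

    Raises :class:`ConfigurationError` when a role required by the present
    molecule kinds matches zero atoms.
    """
    pat = {
        "phosphate": re.compile(spec.phosphate_pattern),
        "tail_carbon_last3": re.compile(spec.tail_carbon_pattern),
        "tail_hydrogen_last3": re.compile(spec.tail_hydrogen_pattern),
        "water_site": re.compile(spec.water_site_pattern),
        "pe_reference": re.compile(spec.pe_reference_pattern),
        "pe_chain": re.compile(spec.pe_chain_pattern),
    }
    roles: dict[str, set[int]] = {label: set() for label in ROLE_LABELS}
    h_candidates: list[Atom] = []
    for a in atoms:
        if a.mol_kind == "POPC":
            if pat["phosphate"].match(a.name):
                roles["phosphate"].add(a.index)
            elif pat["tail_carbon_last3"].match(a.name):
                roles["tail_carbon_last3"].add(a.index)
            elif pat["tail_hydrogen_last3"].match(a.name):
                h_candidates.append(a)
        elif a.mol_kind == "water":
            if pat["water_site"].match(a.name):
                roles["water_site"].add(a.index)
        elif a.mol_kind == "PE":
            if pat["pe_reference"].match(a.name):
                roles["pe_reference"].add(a.index)
            if pat["pe_chain"].match(a.name):
                roles["pe_chain"].add(a.index)

    # bind candidate tail hydrogens to the nearest terminal carbon of the same
    # molecule; geometry disambiguates names shared across chain positions
    if h_candidates and roles["tail_carbon_last3"]:
        tc = np.array(sorted(roles["tail_carbon_last3"]))
        tc_mol = np.array([atoms[i].mol_id for i in tc])
        for a in h_candidates:
            mine = tc[tc_mol == a.mol_id]
            if mine.size == 0:
                continue
            d = np.linalg.norm(xyz0[mine] - xyz0[a.index], axis=1)
            if d.min() <= spec.ch_bond_cutoff:
                roles["tail_hydrogen_last3"].add(a.index)

    kinds = {a.mol_kind for a in atoms}
    required = []
    if "POPC" in kinds:
        required += ["phosphate", "tail_carbon_last3"]
    if "water" in kinds:
        required += ["water_site"]
    if "PE" in kinds:
        required += ["pe_reference", "pe_chain"]
    for label in required:
        if not roles[label]:
            raise ConfigurationError(
                f"role pattern for {label!r} matched zero atoms; "
                "adjust the RoleSpec to your naming convention"
            )
    return {k: frozenset(v) for k, v in roles.items()}


def assign_initial_leaflets(
    atoms: Sequence[Atom],
    roles: Mapping[str, frozenset[int]],
    xyz0: np.ndarray,
) -> dict[int, str]:
    """Initial leaflet labels from first-frame z of phosphates / PE references.

    Lipids split by the sign of their phosphate z about the median phosphate
    z; enhancers by the z of their reference atom about the same median.
    """
    phos = sorted(roles["phosphate"])
    if not phos:
        return {}
    z_med = float(np.median(xyz0[phos, 2]))
    leaflet0: dict[int, str] = {}
    for i in phos:
        leaflet0[atoms[i].mol_id] = "upper" if xyz0[i, 2] >= z_med else "lower"
    for i in sorted(roles["pe_reference"]):
        leaflet0[atoms[i].mol_id] = "upper" if xyz0[i, 2] >= z_med else "lower"
    return leaflet0
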