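"""Core containers: atoms, topologies, trajectories, and atom selections.

The proton-transfer-chain analyses only ever need heavy-atom identity and a
hydrogen-bonding role per atom, so the topology model is deliberately small:
an ordered list of :class:`AtomRecord` plus a residue index.  Roles are a pure
function of ``(res_name, name)`` via a lookup table covering the polar
side-chain heavy atoms of the chain residues and water oxygen.

Carboxylate oxygens (Asp/Glu) and imidazole nitrogens (His) are classified as
``both``: at the half-channel's working pH these groups are protonatable and
act as proton relay sites, donating as well as accepting, which is what lets
two adjacent acidic residues form a transfer-chain link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError, ValidationError

#: Residue names accepted as water (force-field naming drift).
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL"})

#: Atom names recognized as the water oxygen.
WATER_OXYGEN_NAMES = frozenset({"O", "OH2", "OW"})

ROLE_NONE = "none"
ROLE_DONOR = "donor"
ROLE_ACCEPTOR = "acceptor"
ROLE_BOTH = "both"
ROLE_WATER_OXYGEN = "water_oxygen"

VALID_ROLES = frozenset(
    {ROLE_NONE, ROLE_DONOR, ROLE_ACCEPTOR, ROLE_BOTH, ROLE_WATER_OXYGEN}
)

# (res_name, atom_name) -> role, side-chain polar heavy atoms only.
_SIDECHAIN_ROLE_TABLE: dict[tuple[str, str], str] = {}


def _add_roles(resnames, atom_roles):
    for rn in resnames:
        for an, role in atom_roles.items():
            _SIDECHAIN_ROLE_TABLE[(rn, an)] = role


_add_roles(["ASP"], {"OD1": ROLE_BOTH, "OD2": ROLE_BOTH})
_add_roles(["GLU"], {"OE1": ROLE_BOTH, "OE2": ROLE_BOTH})
# CHARMM histidine tautomer names included alongside the PDB name.
_add_roles(["HIS", "HSD", "HSE", "HSP"], {"ND1": ROLE_BOTH, "NE2": ROLE_BOTH})
_add_roles(["SER"], {"OG": ROLE_BOTH})
_add_roles(["THR"], {"OG1": ROLE_BOTH})
_add_roles(["TYR"], {"OH": ROLE_BOTH})
_add_roles(["ASN"], {"OD1": ROLE_ACCEPTOR, "ND2": ROLE_DONOR})
_add_roles(["GLN"], {"OE1": ROLE_ACCEPTOR, "NE2": ROLE_DONOR})
_add_roles(["ARG"], {"NE": ROLE_DONOR, "NH1": ROLE_DONOR, "NH2": ROLE_DONOR})
_add_roles(["LYS"], {"NZ": ROLE_DONOR})
_add_roles(["TRP"], {"NE1": ROLE_DONOR})

#: Backbone heavy-atom names (standard protein backbone).
BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Atomic masses (amu) by element symbol.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

#: Van der Waals radii (Angstrom) by element, used for SASA.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70


def assign_role(
    res_name: str, atom_name: str, water_resnames=DEFAULT_WATER_RESNAMES
) -> str:
    """Hydrogen-bonding role of an atom, from the ``(res_name, name)`` table.

    Pure function: repeated calls with the same arguments always agree, so
    re-reading a structure never changes roles.
    """
    if res_name in water_resnames:
        return ROLE_WATER_OXYGEN if atom_name in WATER_OXYGEN_NAMES else ROLE_NONE
    return _SIDECHAIN_ROLE_TABLE.get((res_name, atom_name), ROLE_NONE)


def is_donor_capable(role: str) -> bool:
    return role in (ROLE_DONOR, ROLE_BOTH, ROLE_WATER_OXYGEN)


def is_acceptor_capable(role: str) -> bool:
    return role in (ROLE_ACCEPTOR, ROLE_BOTH, ROLE_WATER_OXYGEN)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy (or hydrogen) atom with residue identity and H-bond role."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    role: str = ROLE_NONE

    def __post_init__(self):
        if self.serial <= 0:
            raise ValidationError(f"atom serial must be positive, got {self.serial}")
        if self.role not in VALID_ROLES:
            raise ValidationError(f"unknown role {self.role!r}")


class Topology:
    """Ordered atom list plus a ``(chain_id, res_seq) -> atom indices`` index."""

    def __init__(self, atoms: list[AtomRecord]):
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValidationError("duplicate atom serials in topology")
        self.atoms: list[AtomRecord] = list(atoms)
        self.residues: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self.residues.setdefault((a.chain_id, a.res_seq), []).append(i)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.atoms == other.atoms

    def residue_atoms(self, chain_id: str, res_seq: int) -> list[int]:
        key = (chain_id, res_seq)
        if key not in self.residues:
            raise SelectionError(f"no residue {chain_id}:{res_seq} in topology")
        return self.residues[key]

    # -- selection mini-language -------------------------------------------
    #
    # A selection is a conjunction of clauses joined by "and"; each clause is
    # a keyword followed by one or more values:
    #   chain A | resid 214 219 | resname HOH TIP3 | name OD1 OD2 |
    #   role water_oxygen | backbone | polar
    # "backbone" selects N/CA/C/O; "polar" selects any atom with a non-none
    # role.  This is intentionally the minimal vocabulary the scenario files
    # need, not a general query language.

    def select(self, expression: str) -> np.ndarray:
        """Atom indices matching a selection expression (file order)."""
        if not expression or not expression.strip():
            raise SelectionError("empty selection expression")
        mask = np.ones(len(self.atoms), dtype=bool)
        for clause in expression.split(" and "):
            parts = clause.split()
            if not parts:
                raise SelectionError(f"empty clause in selection {expression!r}")
            key, values = parts[0], parts[1:]
            mask &= self._clause_mask(key, values, expression)
        return np.nonzero(mask)[0]

    def _clause_mask(self, key: str, values: list[str], expr: str) -> np.ndarray:
        atoms = self.atoms
        if key == "backbone":
            if values:
                raise SelectionError(f"'backbone' takes no values in {expr!r}")
            # water "O" atoms share the backbone oxygen name; exclude them
            return np.array(
                [
                    a.name in BACKBONE_NAMES
                    and a.res_name not in DEFAULT_WATER_RESNAMES
                    for a in atoms
                ]
            )
        if key == "polar":
            if values:
                raise SelectionError(f"'polar' takes no values in {expr!r}")
            return np.array([a.role != ROLE_NONE for a in atoms])
        if not values:
            raise SelectionError(f"clause {key!r} needs values in {expr!r}")
        if key == "chain":
            return np.array([a.chain_id in values for a in atoms])
        if key == "resid":
            try:
                ids = {int(v) for v in values}
            except ValueError as exc:
                raise SelectionError(f"non-integer resid in {expr!r}") from exc
            return np.array([a.res_seq in ids for a in atoms])
        if key == "resname":
            return np.array([a.res_name in values for a in atoms])
        if key == "name":
            return np.array([a.name in values for a in atoms])
        if key == "role":
            bad = set(values) - VALID_ROLES
            if bad:
                raise SelectionError(f"unknown role(s) {sorted(bad)} in {expr!r}")
            return np.array([a.role in values for a in atoms])
        raise SelectionError(f"unknown selection keyword {key!r} in {expr!r}")

    def masses(self, indices=None) -> np.ndarray:
        """Atomic masses (amu) for the given atom indices (default: all)."""
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([ATOMIC_MASSES.get(a.element, 12.011) for a in atoms])

    def vdw_radii(self, indices=None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([VDW_RADII.get(a.element, DEFAULT_VDW_RADIUS) for a in atoms])

    def water_oxygen_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.role == ROLE_WATER_OXYGEN],
            dtype=int,
        )


@dataclass
class Trajectory:
    """Topology plus ``F x N x 3`` coordinates in Angstrom.

    ``frame_interval_ps`` is metadata only (the frame recording interval); no
    analysis in this package depends on it beyond bookkeeping.
    """

    topology: Topology
    coordinates: np.ndarray
    frame_interval_ps: float = 2.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError(
                f"coordinates must be F x N x 3, got shape {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValidationError("trajectory needs at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValidationError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("non-finite coordinates in trajectory")
        if self.frame_interval_ps <= 0:
            raise ValidationError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]
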