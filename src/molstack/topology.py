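"""Molecular system descriptions: atoms, molecules, frames, trajectories.

A :class:`Topology` is an ordered list of molecules sharing one global atom
indexing; a :class:`Trajectory` couples it with an ordered list of
:class:`Frame` snapshots (coordinates in Å, orthorhombic box, time in ns).
Topologies are loaded from a YAML config that annotates, per atom, the mass,
element, ring-plane membership and hydrogen-bond role — everything the
contact/stacking/H-bond analyses need and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import SchemaError, TopologyValidationError
from .sar import ATOMIC_WEIGHTS

HBOND_ROLES = ("donor-heavy", "polar-hydrogen", "acceptor", "none")


@dataclass(frozen=True)
class AtomSpec:
    """One atom: label, element, mass and analysis annotations.

    ``hbond_role`` is one of ``donor-heavy`` (heavy atom carrying a polar
    hydrogen), ``polar-hydrogen`` (must name its donor via ``donor_name``),
    ``acceptor`` (optionally tagged with an ``acceptor_class`` label such
    as ``sulfur-bound-oxygen`` or ``intra-ring-oxygen``) or ``none``.
    """

    name: str
    element: str
    mass: float
    is_ring_atom: bool = False
    hbond_role: str = "none"
    donor_name: str | None = None
    acceptor_class: str | None = None

    def __post_init__(self):
        if self.element not in ATOMIC_WEIGHTS:
            raise SchemaError(f"atom {self.name!r}: unknown element {self.element!r}")
        if not self.mass > 0:
            raise SchemaError(f"atom {self.name!r}: mass must be > 0, got {self.mass}")
        if self.hbond_role not in HBOND_ROLES:
            raise SchemaError(
                f"atom {self.name!r}: hbond_role {self.hbond_role!r} not in {HBOND_ROLES}"
            )
        if self.hbond_role == "polar-hydrogen" and not self.donor_name:
            raise SchemaError(f"polar-hydrogen {self.name!r} must name its donor atom")


@dataclass
class MoleculeSpec:
    """One molecular species instance: ordered atoms plus optional formula."""

    species: str
    atoms: list[AtomSpec]
    formula: dict[str, int] | None = None

    def __post_init__(self):
        if not self.atoms:
            raise TopologyValidationError(f"{self.species}: molecule has no atoms")
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise TopologyValidationError(f"{self.species}: duplicate atom names")
        ring_size = len(self.ring_indices)
        if 0 < ring_size < 3:
            raise TopologyValidationError(
                f"{self.species}: ring set has {ring_size} atoms; plane fitting needs >= 3"
            )
        by_name = {a.name: a for a in self.atoms}
        for atom in self.atoms:
            if atom.hbond_role == "polar-hydrogen":
                donor = by_name.get(atom.donor_name)
                if donor is None or donor.hbond_role != "donor-heavy":
                    raise TopologyValidationError(
                        f"{self.species}: polar-hydrogen {atom.name!r} must reference "
                        f"a donor-heavy atom, got {atom.donor_name!r}"
                    )
        if self.formula is not None:
            counted: dict[str, int] = {}
            for atom in self.atoms:
                counted[atom.element] = counted.get(atom.element, 0) + 1
            if counted != dict(self.formula):
                raise TopologyValidationError(
                    f"{self.species}: formula {self.formula} inconsistent with "
                    f"atom list {counted}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def ring_indices(self) -> list[int]:
        """Local indices of the plane-defining ring atoms."""
        return [i for i, a in enumerate(self.atoms) if a.is_ring_atom]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def donors(self) -> list[tuple[int, int]]:
        """(donor-heavy local index, polar-hydrogen local index) pairs."""
        by_name = {a.name: i for i, a in enumerate(self.atoms)}
        return [
            (by_name[a.donor_name], i)
            for i, a in enumerate(self.atoms)
            if a.hbond_role == "polar-hydrogen"
        ]

    @property
    def acceptors(self) -> list[tuple[int, str]]:
        """(acceptor local index, acceptor_class) pairs."""
        return [
            (i, a.acceptor_class or "unclassified")
            for i, a in enumerate(self.atoms)
            if a.hbond_role == "acceptor"
        ]


class Topology:
    """Ordered molecules with global atom offsets."""

    def __init__(self, molecules: list[MoleculeSpec]):
        if not molecules:
            raise TopologyValidationError("topology has no molecules")
        self.molecules = list(molecules)
        self.offsets = np.concatenate(
            [[0], np.cumsum([m.n_atoms for m in self.molecules])]
        ).astype(int)
        self.n_atoms = int(self.offsets[-1])
        self.masses = np.concatenate([m.masses for m in self.molecules])

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def atom_slice(self, mol_index: int) -> slice:
        return slice(int(self.offsets[mol_index]), int(self.offsets[mol_index + 1]))

    def species_of(self, mol_index: int) -> str:
        return self.molecules[mol_index].species

    def molecule_indices(self, species: str) -> list[int]:
        return [i for i, m in enumerate(self.molecules) if m.species == species]

    @property
    def species_names(self) -> list[str]:
        seen: list[str] = []
        for m in self.molecules:
            if m.species not in seen:
                seen.append(m.species)
        return seen


@dataclass
class Frame:
    """One snapshot: per-atom positions (Å), orthorhombic box (Å), time (ns)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0
    replica_id: int | str = 0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TopologyValidationError("coordinates must be (n_atoms, 3)")
        if not np.all(self.box > 0):
            raise TopologyValidationError(f"box edges must be > 0, got {self.box}")


@dataclass
class Trajectory:
    """A topology plus the ordered frames recorded for it."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        for k, frame in enumerate(self.frames):
            if frame.coordinates.shape[0] != self.topology.n_atoms:
                raise TopologyValidationError(
                    f"frame {k}: {frame.coordinates.shape[0]} coordinates for "
                    f"{self.topology.n_atoms} topology atoms"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def _atom_from_entry(entry: dict, species: str) -> AtomSpec:
    if "name" not in entry:
        raise SchemaError(f"{species}: atom entry without a name: {entry}")
    for key in ("element", "mass"):
        if key not in entry:
            raise SchemaError(f"{species}: atom {entry['name']!r} is missing {key!r}")
    return AtomSpec(
        name=str(entry["name"]),
        element=str(entry["element"]),
        mass=float(entry["mass"]),
        is_ring_atom=bool(entry.get("ring", False)),
        hbond_role=str(entry.get("hbond", "none")),
        donor_name=entry.get("donor"),
        acceptor_class=entry.get("acceptor_class"),
    )


def load_topology(path) -> Topology:
    """Load a topology from a YAML config.

    Schema::

        molecules:
          - species: adenine
            count: 44            # optional, default 1
            formula: {C: 5, H: 5, N: 5}   # optional consistency check
            atoms:
              - {name: N1, element: N, mass: 14.007, ring: true}
              - {name: H9, element: H, mass: 1.008,
                 hbond: polar-hydrogen, donor: N9}
              - {name: O1, element: O, mass: 15.999,
                 hbond: acceptor, acceptor_class: sulfur-bound-oxygen}

    Molecules appear in file order, each repeated ``count`` times.
    """
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "molecules" not in config:
        raise SchemaError(f"{path}: expected a mapping with a 'molecules' list")
    molecules: list[MoleculeSpec] = []
    for entry in config["molecules"]:
        species = entry.get("species")
        if not species:
            raise SchemaError(f"{path}: molecule entry without 'species'")
        atoms = [_atom_from_entry(a, species) for a in entry.get("atoms", [])]
        formula = entry.get("formula")
        spec = MoleculeSpec(
            species=species,
            atoms=atoms,
            formula={str(k): int(v) for k, v in formula.items()} if formula else None,
        )
        count = int(entry.get("count", 1))
        if count < 1:
            raise SchemaError(f"{path}: {species}: count must be >= 1")
        molecules.extend(
            [spec] + [MoleculeSpec(species, list(spec.atoms), spec.formula and dict(spec.formula))
                      for _ in range(count - 1)]
        )
    return Topology(molecules)


def dump_topology(topology: Topology, path) -> None:
    """Write a topology back to the YAML schema read by :func:`load_topology`.

    Consecutive identical species are collapsed into one entry with a count.
    """
    entries = []
    for mol in topology.molecules:
        atoms = []
        for a in mol.atoms:
            entry: dict = {"name": a.name, "element": a.element, "mass": float(a.mass)}
            if a.is_ring_atom:
                entry["ring"] = True
            if a.hbond_role != "none":
                entry["hbond"] = a.hbond_role
            if a.donor_name:
                entry["donor"] = a.donor_name
            if a.acceptor_class:
                entry["acceptor_class"] = a.acceptor_class
            atoms.append(entry)
        record = {"species": mol.species, "count": 1, "atoms": atoms}
        if mol.formula:
            record["formula"] = dict(mol.formula)
        if entries and entries[-1]["species"] == mol.species:
            entries[-1]["count"] += 1
        else:
            entries.append(record)
    with open(path, "w") as fh:
        yaml.safe_dump({"molecules": entries}, fh, sort_keys=False)
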