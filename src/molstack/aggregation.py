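"""Contact, aggregate and stacking-angle analysis of periodic trajectories.

Two molecules are in contact when their mass-weighted centres of mass are
closer than a cutoff (default 6.0 Å, i.e. 0.6 nm) under the minimum-image
convention; aggregates are the connected components of the contact graph.
The relative orientation of two planar molecules in contact is summarised
by the acute angle between their least-squares ring-plane normals: near 0°
means ordered π-stacking, a broad distribution means orientational
disorder. Molecules are made whole across the periodic boundary before any
COM or plane fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .errors import GeometryError, MolstackError
from .topology import Frame, Topology, Trajectory

#: Mean pair angle (degrees) between isotropically oriented plane normals:
#: arccos|u·v| averages to exactly 1 radian under the axial isotropic measure.
ISOTROPIC_MEAN_ANGLE = float(np.degrees(1.0))


def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Fold displacement vectors into the primary image of an orthorhombic box."""
    displacement = np.asarray(displacement, dtype=float)
    return displacement - box * np.round(displacement / box)


def make_whole(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap a molecule across the boundary, minimum-image to its first atom."""
    ref = coords[0]
    return ref + minimum_image(coords - ref, box)


def center_of_mass(topology: Topology, frame: Frame, mol_index: int) -> np.ndarray:
    """Mass-weighted centre of a molecule, made whole then wrapped into [0, box)."""
    mol = topology.molecules[mol_index]
    masses = mol.masses
    total = masses.sum()
    if total <= 0:
        raise GeometryError(f"molecule {mol_index}: zero total mass")
    whole = make_whole(frame.coordinates[topology.atom_slice(mol_index)], frame.box)
    com = (masses[:, None] * whole).sum(axis=0) / total
    return com % frame.box


def centers_of_mass(topology: Topology, frame: Frame,
                    mol_indices=None) -> np.ndarray:
    indices = range(topology.n_molecules) if mol_indices is None else mol_indices
    return np.array([center_of_mass(topology, frame, i) for i in indices])


@dataclass(frozen=True)
class ContactSet:
    """Unordered molecule-index pairs in COM contact within one frame."""

    frame_index: int
    pairs: frozenset[tuple[int, int]]
    cutoff: float

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs


def _cell_list_candidate_pairs(points: np.ndarray, box: np.ndarray,
                               cutoff: float) -> set[tuple[int, int]]:
    """Candidate neighbour pairs from a periodic cell list.

    Falls back to all pairs along any axis with fewer than 3 cells, where
    the 27-stencil would double-count periodic images.
    """
    n_cells = np.maximum(np.floor(box / cutoff).astype(int), 1)
    if np.any(n_cells < 3):
        n = len(points)
        return {(i, j) for i in range(n) for j in range(i + 1, n)}
    cell_size = box / n_cells
    cell_of = np.floor((points % box) / cell_size).astype(int)
    cell_of = np.minimum(cell_of, n_cells - 1)
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for idx, cell in enumerate(map(tuple, cell_of)):
        buckets.setdefault(cell, []).append(idx)
    candidates: set[tuple[int, int]] = set()
    offsets = list(itertools.product((-1, 0, 1), repeat=3))
    for cell, members in buckets.items():
        for off in offsets:
            neighbour = tuple((np.array(cell) + off) % n_cells)
            others = buckets.get(neighbour)
            if others is None:
                continue
            for i in members:
                for j in others:
                    if i < j:
                        candidates.add((i, j))
    return candidates


def contact_pairs(topology: Topology, frame: Frame, cutoff: float = 6.0,
                  species=None, frame_index: int = 0) -> ContactSet:
    """All molecule pairs whose minimum-image COM distance is strictly below
    ``cutoff``.

    ``species`` selects participants: ``None`` (all molecules), a species
    name (pairs within that species), or a pair ``(a, b)`` of names —
    ``("adenine", "adenine")`` for monomer–monomer contacts,
    ``("adenine", "USAFDO-38")`` for monomer–inhibitor cross contacts.
    """
    if cutoff <= 0:
        raise MolstackError("cutoff must be > 0")
    if cutoff >= frame.box.min() / 2:
        raise MolstackError(
            f"cutoff {cutoff} Å >= half the smallest box edge "
            f"({frame.box.min() / 2} Å); minimum image is ambiguous")
    if species is None:
        mol_indices = list(range(topology.n_molecules))
        allowed = None
    elif isinstance(species, str):
        mol_indices = topology.molecule_indices(species)
        allowed = {frozenset([species])}
    else:
        a, b = species
        mol_indices = sorted(set(topology.molecule_indices(a))
                             | set(topology.molecule_indices(b)))
        allowed = {frozenset([a, b])}
    coms = centers_of_mass(topology, frame, mol_indices)
    pairs = set()
    for ci, cj in _cell_list_candidate_pairs(coms, frame.box, cutoff):
        i, j = mol_indices[ci], mol_indices[cj]
        if allowed is not None:
            if frozenset([topology.species_of(i), topology.species_of(j)]) not in allowed:
                continue
        delta = minimum_image(coms[ci] - coms[cj], frame.box)
        if float(np.linalg.norm(delta)) < cutoff:
            pairs.add((min(i, j), max(i, j)))
    return ContactSet(frame_index=frame_index, pairs=frozenset(pairs), cutoff=cutoff)


@dataclass(frozen=True)
class AggregateReport:
    """Partition of molecules into aggregates for one frame."""

    frame_index: int
    components: tuple[frozenset[int], ...]
    size_histogram: dict[int, int]

    @property
    def mean_size(self) -> float:
        sizes = [len(c) for c in self.components]
        return float(np.mean(sizes))

    @property
    def largest(self) -> int:
        return max(len(c) for c in self.components)


def aggregates(contacts: ContactSet, molecules) -> AggregateReport:
    """Connected components of the contact graph over the given molecule ids.

    Molecules without contacts appear as singleton aggregates, so the
    components always partition the input set exactly.
    """
    graph = nx.Graph()
    graph.add_nodes_from(molecules)
    graph.add_edges_from(contacts.pairs)
    components = tuple(frozenset(c) for c in nx.connected_components(graph))
    histogram: dict[int, int] = {}
    for comp in components:
        histogram[len(comp)] = histogram.get(len(comp), 0) + 1
    node_set = set(graph.nodes)
    covered = set().union(*components) if components else set()
    assert covered == node_set, "components must cover all molecules"
    assert sum(k * v for k, v in histogram.items()) == len(node_set)
    return AggregateReport(frame_index=contacts.frame_index,
                           components=components, size_histogram=histogram)


def plane_normal(topology: Topology, frame: Frame, mol_index: int) -> np.ndarray:
    """Unit normal of the least-squares plane through a molecule's ring atoms.

    The normal is the smallest-variance principal axis of the centred
    ring-atom coordinates (SVD); its sign is arbitrary.
    """
    mol = topology.molecules[mol_index]
    ring = mol.ring_indices
    if len(ring) < 3:
        raise GeometryError(
            f"molecule {mol_index} ({mol.species}): ring set has {len(ring)} atoms; "
            "plane fitting needs >= 3")
    coords = frame.coordinates[topology.atom_slice(mol_index)][ring]
    whole = make_whole(coords, frame.box)
    centered = whole - whole.mean(axis=0)
    _, singular, vt = np.linalg.svd(centered, full_matrices=False)
    if singular[1] < 1e-8 * max(singular[0], 1e-300):
        raise GeometryError(
            f"molecule {mol_index} ({mol.species}): ring atoms are collinear")
    return vt[-1]


def pair_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Acute angle (degrees, [0, 90]) between two plane normals.

    Normals are axial — a plane has no signed orientation — so antiparallel
    vectors are treated as parallel.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    norm1, norm2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if norm1 < 1e-12 or norm2 < 1e-12:
        raise GeometryError("zero-length normal vector")
    cosine = abs(float(np.dot(n1, n2)) / (norm1 * norm2))
    return float(np.degrees(np.arccos(min(cosine, 1.0))))


@dataclass(frozen=True)
class AngleSample:
    frame_index: int
    pair: tuple[int, int]
    angle: float


@dataclass
class AngleDistribution:
    """Stacking-angle distribution over all in-contact pairs of a trajectory.

    ``dispersion`` is the root-mean-square angular deviation from perfect
    coplanar alignment (0°) in degrees: 0 for ideal stacks, ~65° for
    isotropically oriented planes. ``stacked_fraction`` is the fraction of
    samples below ``stack_threshold``.
    """

    samples: list[AngleSample]
    bin_edges: np.ndarray
    density: np.ndarray
    mean: float
    dispersion: float
    stacked_fraction: float
    stack_threshold: float
    empty: bool = False
    angles: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.samples)


def angle_distribution(traj: Trajectory, species_pair=("adenine", "adenine"),
                       cutoff: float = 6.0, bins: int = 18,
                       stack_threshold: float = 30.0,
                       stride: int = 1) -> AngleDistribution:
    """One angle sample per in-contact pair per analyzed frame.

    A trajectory with no contacts yields an empty, flagged distribution
    rather than an error.
    """
    samples: list[AngleSample] = []
    for frame_index, frame in enumerate(traj.frames):
        if frame_index % stride:
            continue
        contacts = contact_pairs(traj.topology, frame, cutoff=cutoff,
                                 species=species_pair, frame_index=frame_index)
        normals: dict[int, np.ndarray] = {}
        for i, j in sorted(contacts.pairs):
            for k in (i, j):
                if k not in normals:
                    normals[k] = plane_normal(traj.topology, frame, k)
            samples.append(AngleSample(frame_index, (i, j),
                                       pair_angle(normals[i], normals[j])))
    edges = np.linspace(0.0, 90.0, bins + 1)
    if not samples:
        return AngleDistribution(samples=[], bin_edges=edges,
                                 density=np.zeros(bins), mean=np.nan,
                                 dispersion=np.nan, stacked_fraction=np.nan,
                                 stack_threshold=stack_threshold, empty=True,
                                 angles=np.array([]))
    angles = np.array([s.angle for s in samples])
    density, _ = np.histogram(angles, bins=edges, density=True)
    return AngleDistribution(
        samples=samples, bin_edges=edges, density=density,
        mean=float(angles.mean()),
        dispersion=float(np.sqrt(np.mean(angles ** 2))),
        stacked_fraction=float(np.mean(angles < stack_threshold)),
        stack_threshold=stack_threshold,
        angles=angles,
    )


@dataclass(frozen=True)
class HeterogeneityComparison:
    """Directional contrast between two stacking-angle ensembles (b − a)."""

    mean_diff: float
    dispersion_diff: float
    stacked_fraction_diff: float
    ks_statistic: float
    ks_pvalue: float


def heterogeneity_compare(dist_a: AngleDistribution,
                          dist_b: AngleDistribution) -> HeterogeneityComparison:
    """Compare two angle distributions (e.g. pure monomer vs +inhibitor).

    Positive ``mean_diff``/``dispersion_diff`` mean ensemble *b* is more
    orientationally heterogeneous than *a*.
    """
    if dist_a.empty or dist_b.empty:
        raise MolstackError("cannot compare empty angle distributions")
    ks = stats.ks_2samp(dist_a.angles, dist_b.angles, method="asymp")
    return HeterogeneityComparison(
        mean_diff=dist_b.mean - dist_a.mean,
        dispersion_diff=dist_b.dispersion - dist_a.dispersion,
        stacked_fraction_diff=dist_b.stacked_fraction - dist_a.stacked_fraction,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )
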