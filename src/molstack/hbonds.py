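"""Geometric hydrogen-bond detection and occupancy over a metatrajectory.

A donor–hydrogen⋯acceptor triple counts as a hydrogen bond when the
donor-heavy→acceptor minimum-image distance is within ``max_da_distance``
(default 3.5 Å) and the D–H⋯A angle at the hydrogen is at least
``min_dha_angle`` (default 120°) — the common geometric criteria, fully
configurable. Occupancy of an acceptor class is the fraction of analyzed
configurations (frames) containing at least one such bond, which is how a
"~6% of configurations" statement is to be read.

Intermolecular bonds only: donor and acceptor must sit in different
molecules. Species without donor/acceptor annotations simply contribute no
events — a hydrophobic chaperone run reports zero occupancy rather than
failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregation import minimum_image
from .errors import MolstackError
from .topology import Frame, Topology, Trajectory


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance window for a donor–H⋯acceptor triple."""

    max_da_distance: float = 3.5
    min_dha_angle: float = 120.0

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise MolstackError("max_da_distance must be > 0")
        if not 0 < self.min_dha_angle <= 180:
            raise MolstackError("min_dha_angle must be in (0, 180]")


@dataclass(frozen=True)
class HBondEvent:
    """One detected bond; atoms referenced as (molecule index, local atom index)."""

    frame_index: int
    donor: tuple[int, int]
    hydrogen: tuple[int, int]
    acceptor: tuple[int, int]
    acceptor_class: str
    da_distance: float
    dha_angle: float


@dataclass(frozen=True)
class OccupancyResult:
    acceptor_class: str
    n_frames_analyzed: int
    n_frames_with_event: int

    @property
    def occupancy(self) -> float:
        return self.n_frames_with_event / self.n_frames_analyzed


def _donor_triples(topology: Topology, species=None):
    for mol_index, mol in enumerate(topology.molecules):
        if species is not None and mol.species != species:
            continue
        for d_local, h_local in mol.donors:
            yield mol_index, d_local, h_local


def _acceptor_sites(topology: Topology, species=None):
    for mol_index, mol in enumerate(topology.molecules):
        if species is not None and mol.species != species:
            continue
        for a_local, a_class in mol.acceptors:
            yield mol_index, a_local, a_class


def detect_hbonds(topology: Topology, frame: Frame,
                  criteria: HBondCriteria = HBondCriteria(),
                  donor_species: str | None = None,
                  acceptor_species: str | None = None,
                  frame_index: int = 0) -> list[HBondEvent]:
    """All intermolecular D–H⋯A triples satisfying the criteria.

    ``donor_species``/``acceptor_species`` restrict the search; explicitly
    requesting a species with no matching annotations raises, since that
    signals a topology mistake rather than an empty result.
    """
    donors = list(_donor_triples(topology, donor_species))
    acceptors = list(_acceptor_sites(topology, acceptor_species))
    if donor_species is not None and not donors:
        raise MolstackError(f"species {donor_species!r} has no annotated donors")
    if acceptor_species is not None and not acceptors:
        raise MolstackError(f"species {acceptor_species!r} has no annotated acceptors")
    if not donors or not acceptors:
        return []

    coords, box = frame.coordinates, frame.box
    offsets = topology.offsets
    d_pos = np.array([coords[offsets[m] + d] for m, d, _ in donors])
    h_pos = np.array([coords[offsets[m] + h] for m, _, h in donors])
    a_pos = np.array([coords[offsets[m] + a] for m, a, _ in acceptors])

    events: list[HBondEvent] = []
    # Geometry is evaluated in the hydrogen's local frame so that the
    # distance and the angle use one consistent periodic image.
    for di, (d_mol, d_local, h_local) in enumerate(donors):
        hd = minimum_image(d_pos[di] - h_pos[di], box)
        ha = minimum_image(a_pos - h_pos[di], box)
        da = ha - hd
        dists = np.linalg.norm(da, axis=1)
        for ai in np.flatnonzero(dists <= criteria.max_da_distance):
            a_mol, a_local, a_class = acceptors[ai]
            if a_mol == d_mol:
                continue
            # angle at H between H→D and H→A
            cosang = np.dot(hd, ha[ai]) / (np.linalg.norm(hd) * np.linalg.norm(ha[ai]))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle >= criteria.min_dha_angle:
                events.append(HBondEvent(
                    frame_index=frame_index,
                    donor=(d_mol, d_local), hydrogen=(d_mol, h_local),
                    acceptor=(a_mol, a_local), acceptor_class=a_class,
                    da_distance=float(dists[ai]), dha_angle=angle))
    return events


def occupancy(traj: Trajectory, criteria: HBondCriteria = HBondCriteria(),
              acceptor_class: str | None = None,
              donor_species: str | None = None) -> dict[str, OccupancyResult]:
    """Per-class fraction of frames containing at least one bond.

    All classes annotated in the topology are tallied in one pass; classes
    with no events (including ``acceptor_class`` names absent from the
    topology) report zero occupancy. Returns class → result; pass
    ``acceptor_class`` to restrict the output to one class.
    """
    if not traj.frames:
        raise MolstackError("occupancy needs at least one frame")
    classes = sorted({c for _, _, c in _acceptor_sites(traj.topology)})
    if acceptor_class is not None and acceptor_class not in classes:
        classes = classes + [acceptor_class]
    hits = {c: 0 for c in classes}
    for frame_index, frame in enumerate(traj.frames):
        events = detect_hbonds(traj.topology, frame, criteria,
                               donor_species=donor_species,
                               frame_index=frame_index)
        for c in {e.acceptor_class for e in events}:
            hits[c] = hits.get(c, 0) + 1
    results = {
        c: OccupancyResult(acceptor_class=c, n_frames_analyzed=traj.n_frames,
                           n_frames_with_event=n)
        for c, n in hits.items()
    }
    if acceptor_class is not None:
        return {acceptor_class: results[acceptor_class]}
    return results
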