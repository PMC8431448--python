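"""Synthetic trajectories and kinetic curves with known ground truth.

The trajectory generator emulates the statistical structure the analysis
assumes: planar mock molecules arranged as π-stacks with controllable
angular noise, inhibitor-"hijacked" complexes with ideal hydrogen-bond
geometry but orientationally disordered ring planes, free monomers beyond
contact range, and a configurable fraction of frames carrying a planted
intra-ring-oxygen hydrogen bond. Every frame is an independent
configuration; alongside the trajectory the generator returns the exact
ground truth (aggregate partition, in-contact pair angles, planted-bond
frames) so parameter-recovery tests need no external reference data.

Mock geometry is deliberately schematic — a regular 9-gon "purine" ring
for the monomer and a 6-membered ring with two out-of-plane sulfur-bound
oxygens plus one intra-ring oxygen for the inhibitor. Fidelity to the true
molecular geometry is unnecessary for exercising contact, plane-fit and
H-bond machinery, and is not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GenerationError, MolstackError
from .kinetics import KineticCurve, logistic
from .topology import AtomSpec, Frame, MoleculeSpec, Topology, Trajectory

_RING_RADIUS = 1.4          # Å, mock ring circumradius
_NH_BOND = 1.0              # Å, donor-heavy to polar hydrogen
_HB_DA_DISTANCE = 2.9       # Å, planted donor→acceptor distance (ideal)
_COM_CAPTURE = 5.8          # Å, enforced hijack COM distance (< 6 Å cutoff)
_INTRA_RING_MARGIN = 4.2    # Å, min donor→intra-ring-O distance unless planted
_UNIT_CLEARANCE = 7.0       # Å, atom-level clearance between placed units


def monomer_spec(species: str = "adenine") -> MoleculeSpec:
    """Mock planar monomer: 9-atom ring (purine-like N/C masses) plus one
    ring-nitrogen donor with its polar hydrogen."""
    elements = ["N", "C", "N", "C", "C", "C", "N", "C", "N"]
    masses = {"N": 14.007, "C": 12.011}
    atoms = []
    for k, el in enumerate(elements):
        atoms.append(AtomSpec(name=f"{el}{k + 1}", element=el, mass=masses[el],
                              is_ring_atom=True,
                              hbond_role="donor-heavy" if k == 8 else "none"))
    atoms.append(AtomSpec(name="H9", element="H", mass=1.008,
                          hbond_role="polar-hydrogen", donor_name="N9"))
    return MoleculeSpec(species=species, atoms=atoms)


def inhibitor_spec(species: str = "USAFDO-38") -> MoleculeSpec:
    """Mock cyclic sulfone-ether: 6-ring with S, an intra-ring O acceptor,
    and two out-of-plane sulfur-bound O acceptors."""
    ring_elements = ["S", "C", "C", "O", "C", "C"]
    masses = {"S": 32.06, "C": 12.011, "O": 15.999}
    atoms = []
    for k, el in enumerate(ring_elements):
        role = "acceptor" if el == "O" else "none"
        atoms.append(AtomSpec(
            name=f"{el}{k + 1}", element=el, mass=masses[el], is_ring_atom=True,
            hbond_role=role,
            acceptor_class="intra-ring-oxygen" if el == "O" else None))
    for tag, sign in (("A", 1.0), ("B", -1.0)):
        atoms.append(AtomSpec(name=f"OS{tag}", element="O", mass=masses["O"],
                              hbond_role="acceptor",
                              acceptor_class="sulfur-bound-oxygen"))
    return MoleculeSpec(species=species, atoms=atoms)


def _template_coords(spec: MoleculeSpec) -> np.ndarray:
    """COM-centred template coordinates in the molecule's atom order."""
    n_ring = len(spec.ring_indices)
    angles = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring = np.column_stack([_RING_RADIUS * np.cos(angles),
                            _RING_RADIUS * np.sin(angles),
                            np.zeros(n_ring)])
    extras = []
    for atom in spec.atoms[n_ring:]:
        if atom.hbond_role == "polar-hydrogen":
            # radially outward from the donor ring atom
            donor_pos = ring[8]
            extras.append(donor_pos * ((_RING_RADIUS + _NH_BOND) / _RING_RADIUS))
        else:
            # sulfur-bound oxygens, off-plane from the ring sulfur (index 0)
            sign = 1.0 if atom.name.endswith("A") else -1.0
            extras.append(ring[0] + np.array([0.92, 0.0, sign * 1.10]))
    coords = np.vstack([ring] + [np.asarray(e)[None, :] for e in extras]) \
        if extras else ring
    masses = spec.masses
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    return coords - com


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (normalised Gaussian quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


@dataclass
class TrajectoryGenConfig:
    """Study conditions for the trajectory generator.

    Defaults mirror the simulated systems: 44 monomers (40 + 5 inhibitors
    when an inhibitor is present) in a 100 Å cubic box, 3.4 Å stacking
    rise. ``stack_angle_sigma`` is the Gaussian angular noise (degrees) of
    each stacked molecule's tilt relative to its neighbour;
    ``hijack_fraction`` is the fraction of monomers sequestered into
    inhibitor-capped disordered complexes (two monomers per inhibitor);
    ``hbond_plant_rate`` is the per-frame probability of a planted
    intra-ring-oxygen hydrogen bond.
    """

    n_monomer: int = 44
    n_inhibitor: int = 0
    box_edge: float = 100.0
    n_frames: int = 100
    stack_mean_size: float = 5.0
    stack_angle_sigma: float = 10.0
    hijack_fraction: float = 0.0
    hbond_plant_rate: float = 0.0
    stack_rise: float = 3.4
    frame_spacing: float = 1.0   # ns between frames
    seed: int = 0
    replica_id: int | str = 0
    monomer_species: str = "adenine"
    inhibitor_species: str = "USAFDO-38"

    def __post_init__(self):
        if self.n_monomer < 0 or self.n_inhibitor < 0 or self.n_frames < 1:
            raise MolstackError("counts must be non-negative, n_frames >= 1")
        for name in ("hijack_fraction", "hbond_plant_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise MolstackError(f"{name} must be in [0, 1], got {value}")
        if self.stack_angle_sigma < 0 or self.stack_rise <= 0:
            raise MolstackError("stack_angle_sigma >= 0 and stack_rise > 0 required")
        if self.box_edge < 4 * (_RING_RADIUS + _NH_BOND):
            raise MolstackError(f"box_edge {self.box_edge} Å too small for the mock molecules")


@dataclass
class FrameTruth:
    """Exact construction record for one generated frame."""

    partition: list[frozenset[int]]
    #: (i, j, COM distance Å, plane-normal angle deg) for every
    #: monomer–monomer pair constructed inside one unit.
    aa_pairs: list[tuple[int, int, float, float]]
    planted: bool
    hijacked: frozenset[int]


@dataclass
class TrajectoryTruth:
    config: TrajectoryGenConfig
    frames: list[FrameTruth] = field(default_factory=list)

    @property
    def n_planted(self) -> int:
        return sum(f.planted for f in self.frames)

    def contact_aa_pairs(self, frame_index: int, cutoff: float = 6.0):
        """Truth monomer pairs within the contact cutoff, with their angles."""
        return [(i, j, ang) for i, j, dist, ang
                in self.frames[frame_index].aa_pairs if dist < cutoff]


def make_topology(config: TrajectoryGenConfig) -> Topology:
    mono = monomer_spec(config.monomer_species)
    inh = inhibitor_spec(config.inhibitor_species)
    molecules = (
        [MoleculeSpec(mono.species, list(mono.atoms)) for _ in range(config.n_monomer)]
        + [MoleculeSpec(inh.species, list(inh.atoms)) for _ in range(config.n_inhibitor)]
    )
    return Topology(molecules)


class _Unit:
    """A rigid group of molecules placed together: local coords + truth."""

    def __init__(self):
        self.molecules: list[tuple[int, np.ndarray]] = []  # (mol id, local coords)
        self.aa_pairs: list[tuple[int, int, float, float]] = []
        self.members: set[int] = set()

    def add(self, mol_id: int, coords: np.ndarray):
        self.molecules.append((mol_id, coords))
        self.members.add(mol_id)

    @property
    def radius(self) -> float:
        return max(float(np.linalg.norm(c, axis=1).max())
                   for _, c in self.molecules)


def _build_stack(mol_ids, template, sigma_deg, rise, rng) -> _Unit:
    unit = _Unit()
    base = _random_rotation(rng)
    orientation = base
    k = len(mol_ids)
    for slot, mol_id in enumerate(mol_ids):
        if slot > 0:
            theta = abs(rng.normal(0.0, np.radians(sigma_deg))) if sigma_deg > 0 else 0.0
            alpha = rng.uniform(0.0, 2.0 * np.pi)
            spin = rng.uniform(0.0, 2.0 * np.pi)
            tilt = _rotation_about([np.cos(alpha), np.sin(alpha), 0.0], theta)
            spin_rot = _rotation_about([0.0, 0.0, 1.0], spin)
            orientation = orientation @ tilt @ spin_rot
            # adjacent plane-normal angle equals the drawn tilt exactly,
            # folded into [0, 90] the way axial pair angles are
            angle = np.degrees(theta) % 180.0
            angle = min(angle, 180.0 - angle)
            unit.aa_pairs.append((mol_ids[slot - 1], mol_id, rise, angle))
        center = base @ np.array([0.0, 0.0, (slot - (k - 1) / 2.0) * rise])
        unit.add(mol_id, (orientation @ template.T).T + center)
    return unit


def _attach_monomer(template, d_local, h_local, acceptor_pos, avoid, com_anchor,
                    rng, max_attempts=500):
    """Place a monomer with ideal D–H⋯A geometry onto ``acceptor_pos``.

    Orientation is fully random; draws are rejected until the monomer COM
    is within capture range of ``com_anchor`` and its donor stays clear of
    every position in ``avoid``. Returns (coords, com, normal, donor_pos).
    """
    h_dir_local = (h_local - d_local) / np.linalg.norm(h_local - d_local)
    for _ in range(max_attempts):
        rot = _random_rotation(rng)
        h_dir = rot @ h_dir_local
        donor_pos = acceptor_pos - _HB_DA_DISTANCE * h_dir
        com = donor_pos - rot @ d_local
        if np.linalg.norm(com - com_anchor) >= _COM_CAPTURE:
            continue
        if any(np.linalg.norm(donor_pos - p) < _INTRA_RING_MARGIN for p in avoid):
            continue
        return (rot @ template.T).T + com, com, rot @ np.array([0.0, 0.0, 1.0]), donor_pos
    raise GenerationError("could not realise hydrogen-bond geometry; "
                          "check molecule templates")


def _build_hijack_triple(mono_ids, inh_id, mono_template, mono_spec,
                         inh_template, rng) -> _Unit:
    """One inhibitor capping two monomers via its sulfur-bound oxygens.

    Donor→acceptor geometry is ideal (2.9 Å, 180°) but ring-plane
    orientation is isotropic, and accidental intra-ring-oxygen bond
    geometry is rejected so only planted frames carry that class.
    """
    unit = _Unit()
    rot_i = _random_rotation(rng)
    inh_coords = (rot_i @ inh_template.T).T
    unit.add(inh_id, inh_coords)
    o_sulfur = [inh_coords[6], inh_coords[7]]
    o_intra = inh_coords[3]
    d_idx, h_idx = mono_spec.donors[0]
    placed = []
    for mono_id, acceptor in zip(mono_ids, o_sulfur):
        coords, com, normal, _ = _attach_monomer(
            mono_template, mono_template[d_idx], mono_template[h_idx],
            acceptor, avoid=[o_intra], com_anchor=np.zeros(3), rng=rng)
        unit.add(mono_id, coords)
        placed.append((mono_id, com, normal))
    if len(placed) == 2:
        (ia, ca, na), (ib, cb, nb) = placed
        cosine = min(abs(float(np.dot(na, nb))), 1.0)
        unit.aa_pairs.append((min(ia, ib), max(ia, ib),
                              float(np.linalg.norm(ca - cb)),
                              float(np.degrees(np.arccos(cosine)))))
    return unit


def _build_planted_pair(mono_id, inh_id, mono_template, mono_spec,
                        inh_template, rng) -> _Unit:
    """Probe monomer hydrogen-bonded to the inhibitor's intra-ring oxygen."""
    unit = _Unit()
    rot_i = _random_rotation(rng)
    inh_coords = (rot_i @ inh_template.T).T
    unit.add(inh_id, inh_coords)
    d_idx, h_idx = mono_spec.donors[0]
    coords, _, _, _ = _attach_monomer(
        mono_template, mono_template[d_idx], mono_template[h_idx],
        inh_coords[3], avoid=[inh_coords[6], inh_coords[7]],
        com_anchor=np.zeros(3), rng=rng)
    unit.add(mono_id, coords)
    return unit


def _free_unit(mol_id, template, rng) -> _Unit:
    unit = _Unit()
    unit.add(mol_id, (_random_rotation(rng) @ template.T).T)
    return unit


def _place_units(units: list[_Unit], box: float, rng,
                 max_attempts: int = 5000) -> list[np.ndarray]:
    """Rejection-sample unit centres so any two units keep atom-level
    clearance under the minimum image."""
    centers: list[np.ndarray] = []
    radii = [u.radius for u in units]
    for k in range(len(units)):
        for _ in range(max_attempts):
            candidate = rng.uniform(0.0, box, size=3)
            ok = True
            for c, r in zip(centers, radii[:len(centers)]):
                delta = candidate - c
                delta -= box * np.round(delta / box)
                if np.linalg.norm(delta) < radii[k] + r + _UNIT_CLEARANCE:
                    ok = False
                    break
            if ok:
                centers.append(candidate)
                break
        else:
            raise GenerationError(
                f"could not place unit {k} of {len(units)} without overlap "
                f"after {max_attempts} attempts; increase box_edge")
    return centers


def _stack_sizes(n: int, mean_size: float, rng) -> list[int]:
    sizes = []
    remaining = n
    while remaining > 0:
        size = 1 + (rng.poisson(mean_size - 1.0) if mean_size > 1 else 0)
        size = int(min(size, remaining, 12))
        sizes.append(size)
        remaining -= size
    return sizes


def generate_trajectory(config: TrajectoryGenConfig,
                        seed_seq: np.random.SeedSequence | None = None
                        ) -> tuple[Trajectory, TrajectoryTruth]:
    """Generate an independent-frame trajectory plus its ground truth.

    Monomers are partitioned per frame into π-stacks (sizes ~1 + Poisson
    around ``stack_mean_size``), hijacked inhibitor complexes, and a
    reserved probe monomer used for hydrogen-bond planting; units are
    placed beyond contact range of each other, so the truth partition is
    exactly the unit membership.
    """
    topology = make_topology(config)
    mono_spec_obj = monomer_spec(config.monomer_species)
    mono_template = _template_coords(mono_spec_obj)
    inh_template = _template_coords(inhibitor_spec(config.inhibitor_species))
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    frame_seeds = seed_seq.spawn(config.n_frames)
    box = np.full(3, config.box_edge)

    planting = config.hbond_plant_rate > 0 and config.n_inhibitor > 0 \
        and config.n_monomer > 0
    probe_id = 0 if planting else None
    plant_inh_id = config.n_monomer + config.n_inhibitor - 1 if planting else None

    frames: list[Frame] = []
    truth = TrajectoryTruth(config=config)
    for frame_index, fs in enumerate(frame_seeds):
        rng = np.random.default_rng(fs)
        planted = planting and bool(rng.random() < config.hbond_plant_rate)

        mono_ids = [i for i in range(config.n_monomer) if i != probe_id]
        inh_ids = [config.n_monomer + k for k in range(config.n_inhibitor)
                   if config.n_monomer + k != plant_inh_id]
        n_hijack = int(round(config.hijack_fraction * config.n_monomer))
        n_hijack = min(n_hijack - n_hijack % 2, 2 * len(inh_ids), len(mono_ids))
        n_hijack -= n_hijack % 2

        units: list[_Unit] = []
        hijacked: set[int] = set()
        for t in range(n_hijack // 2):
            pair = mono_ids[2 * t:2 * t + 2]
            units.append(_build_hijack_triple(
                pair, inh_ids[t], mono_template, mono_spec_obj, inh_template, rng))
            hijacked.update(pair)
        free_monos = mono_ids[n_hijack:]
        for size in _stack_sizes(len(free_monos), config.stack_mean_size, rng):
            ids, free_monos = free_monos[:size], free_monos[size:]
            if size == 1:
                units.append(_free_unit(ids[0], mono_template, rng))
            else:
                units.append(_build_stack(ids, mono_template,
                                          config.stack_angle_sigma,
                                          config.stack_rise, rng))
        for inh_id in inh_ids[n_hijack // 2:]:
            units.append(_free_unit(inh_id, inh_template, rng))
        if planting:
            if planted:
                units.append(_build_planted_pair(
                    probe_id, plant_inh_id, mono_template, mono_spec_obj,
                    inh_template, rng))
            else:
                units.append(_free_unit(probe_id, mono_template, rng))
                units.append(_free_unit(plant_inh_id, inh_template, rng))

        centers = _place_units(units, config.box_edge, rng)
        coords = np.empty((topology.n_atoms, 3))
        partition: list[frozenset[int]] = []
        aa_pairs: list[tuple[int, int, float, float]] = []
        for unit, center in zip(units, centers):
            partition.append(frozenset(unit.members))
            aa_pairs.extend(unit.aa_pairs)
            for mol_id, local in unit.molecules:
                coords[topology.atom_slice(mol_id)] = (local + center) % box
        frames.append(Frame(coordinates=coords, box=box,
                            time=frame_index * config.frame_spacing,
                            replica_id=config.replica_id))
        truth.frames.append(FrameTruth(partition=partition, aa_pairs=aa_pairs,
                                       planted=planted,
                                       hijacked=frozenset(hijacked)))
    return Trajectory(topology, frames), truth


def generate_replica_set(config: TrajectoryGenConfig, n_replicas: int
                         ) -> tuple[list[Trajectory], list[TrajectoryTruth]]:
    """Independent replicas from one master seed (stable substreams)."""
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(n_replicas)
    trajectories, truths = [], []
    for r, ss in enumerate(seeds):
        cfg = replace(config, replica_id=r)
        traj, truth = generate_trajectory(cfg, seed_seq=ss)
        trajectories.append(traj)
        truths.append(truth)
    return trajectories, truths


@dataclass
class KineticGenConfig:
    """Generative model for a plate-reader inhibition assay.

    The control follows a logistic growth curve; each dose scales the
    amplitude by ``1 - inhibition/100`` so the true baseline-subtracted
    endpoint inhibition equals the configured value exactly, then i.i.d.
    Gaussian noise is added per time point and replicate.
    """

    baseline: float = 10.0
    amplitude: float = 100.0
    rate: float = 0.02          # 1/min
    t_half: float = 500.0       # min
    noise_sigma: float = 5.0    # a.u., 5% of the default amplitude
    doses: list[float] = field(default_factory=lambda: [1.0])
    inhibition_map: dict[float, float] = field(default_factory=lambda: {1.0: 50.0})
    n_replicates: int = 3
    t_max: float = 1200.0       # min
    dt: float = 10.0            # min
    compound: str = "compound"
    control_label: str = "control"
    seed: int = 0

    def __post_init__(self):
        if self.amplitude <= 0:
            raise MolstackError("amplitude must be > 0")
        for dose in self.doses:
            inh = self.inhibition_map.get(dose)
            if inh is None:
                raise MolstackError(f"dose {dose} mM missing from inhibition_map")
            if not -100.0 < inh <= 100.0:
                raise MolstackError(f"inhibition {inh}% out of (-100, 100]")
        if self.n_replicates < 1 or self.dt <= 0 or self.t_max <= self.dt:
            raise MolstackError("need n_replicates >= 1 and 0 < dt < t_max")


def generate_kinetics(config: KineticGenConfig
                      ) -> tuple[list[KineticCurve], dict[float, float]]:
    """Control plus per-dose curves with replicate noise; returns the
    curves and the true dose → endpoint-inhibition map."""
    times = np.arange(0.0, config.t_max + config.dt / 2.0, config.dt)
    root = np.random.SeedSequence(config.seed)
    streams = iter(root.spawn((len(config.doses) + 1) * config.n_replicates))
    curves: list[KineticCurve] = []
    clean_control = logistic(times, config.baseline, config.amplitude,
                             config.rate, config.t_half)
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(next(streams))
        noise = rng.normal(0.0, config.noise_sigma, times.size) \
            if config.noise_sigma > 0 else 0.0
        curves.append(KineticCurve(times=times, signal=clean_control + noise,
                                   compound=config.control_label,
                                   concentration=0.0, replicate_id=rep))
    for dose in config.doses:
        inh = config.inhibition_map[dose]
        clean = logistic(times, config.baseline,
                         config.amplitude * (1.0 - inh / 100.0),
                         config.rate, config.t_half)
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(next(streams))
            noise = rng.normal(0.0, config.noise_sigma, times.size) \
                if config.noise_sigma > 0 else 0.0
            curves.append(KineticCurve(times=times, signal=clean + noise,
                                       compound=config.compound,
                                       concentration=dose, replicate_id=rep))
    return curves, dict(config.inhibition_map)
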