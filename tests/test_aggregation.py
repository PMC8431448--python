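"""Contacts, aggregates and stacking-angle geometry, checked against
brute-force oracles and closed-form cases."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from molstack.aggregation import (
    AngleDistribution,
    aggregates,
    angle_distribution,
    center_of_mass,
    contact_pairs,
    ContactSet,
    heterogeneity_compare,
    make_whole,
    minimum_image,
    pair_angle,
    plane_normal,
)
from molstack.errors import GeometryError, MolstackError
from molstack.synthetic import TrajectoryGenConfig, generate_trajectory, monomer_spec
from molstack.topology import AtomSpec, Frame, MoleculeSpec, Topology

from conftest import frame_of, point_topology


def two_atom_molecule(m1, m2):
    return Topology([MoleculeSpec("dim", [AtomSpec("A", "C", m1),
                                          AtomSpec("B", "C", m2)])])


class TestCenterOfMass:
    def test_equal_masses_midpoint(self):
        topo = two_atom_molecule(12.0, 12.0)
        com = center_of_mass(topo, frame_of([[0, 0, 0], [2, 0, 0]]), 0)
        np.testing.assert_allclose(com, [1, 0, 0], atol=1e-12)

    def test_boundary_straddling_molecule_unwrapped_first(self):
        # atoms at x=1 and x=99 in a 100 Å box are 2 Å apart through the
        # boundary; the COM is at x=0, not at the naive x=50
        topo = two_atom_molecule(12.0, 12.0)
        com = center_of_mass(topo, frame_of([[1, 5, 5], [99, 5, 5]]), 0)
        np.testing.assert_allclose(com, [0, 5, 5], atol=1e-12)

    def test_mass_weighting(self):
        topo = two_atom_molecule(1.0, 3.0)
        com = center_of_mass(topo, frame_of([[0, 0, 0], [4, 0, 0]]), 0)
        np.testing.assert_allclose(com, [3, 0, 0], atol=1e-12)


def brute_force_contacts(points, box, cutoff):
    """All-pairs minimum-image oracle."""
    pairs = set()
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            delta = np.asarray(points[i]) - np.asarray(points[j])
            delta = delta - box * np.round(delta / box)
            if np.sqrt((delta ** 2).sum()) < cutoff:
                pairs.add((i, j))
    return pairs


class TestContacts:
    def test_cutoff_is_a_strict_inequality(self):
        topo = point_topology(2)
        below = contact_pairs(topo, frame_of([[0, 0, 0], [5.9, 0, 0]]))
        at = contact_pairs(topo, frame_of([[0, 0, 0], [6.0, 0, 0]]))
        assert (0, 1) in below.pairs
        assert not at.pairs

    def test_cutoff_beyond_half_box_rejected(self):
        topo = point_topology(2)
        with pytest.raises(MolstackError, match="half"):
            contact_pairs(topo, frame_of([[0, 0, 0], [1, 0, 0]], box=10.0),
                          cutoff=5.0)

    def test_cell_list_matches_brute_force_on_random_configs(self, rng):
        for trial in range(100):
            n = int(rng.integers(2, 31))
            box = 20.0
            points = rng.uniform(0, box, size=(n, 3))
            topo = point_topology(n)
            ours = contact_pairs(topo, frame_of(points, box=box), cutoff=6.0)
            assert ours.pairs == brute_force_contacts(points, box, 6.0), \
                f"trial {trial}"

    def test_translation_and_wrap_invariance(self, rng):
        n, box = 20, 30.0
        points = rng.uniform(0, box, size=(n, 3))
        topo = point_topology(n)
        reference = contact_pairs(topo, frame_of(points, box=box)).pairs
        shift = rng.uniform(-50, 50, size=3)
        shifted = (points + shift) % box
        assert contact_pairs(topo, frame_of(shifted, box=box)).pairs == reference
        # wrapping one molecule by a whole box vector changes nothing
        wrapped = points.copy()
        wrapped[3] += np.array([box, -box, 2 * box])
        assert contact_pairs(topo, frame_of(wrapped, box=box)).pairs == reference

    def test_species_filter_selects_cross_pairs(self):
        mono = MoleculeSpec("a", [AtomSpec("X", "C", 12.0)])
        inh = MoleculeSpec("b", [AtomSpec("Y", "N", 14.0)])
        topo = Topology([mono, MoleculeSpec("a", list(mono.atoms)), inh])
        frame = frame_of([[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        aa = contact_pairs(topo, frame, species=("a", "a"))
        ab = contact_pairs(topo, frame, species=("a", "b"))
        assert aa.pairs == {(0, 1)}
        assert ab.pairs == {(0, 2), (1, 2)}


def union_find_components(n, pairs):
    """Brute-force transitive-closure oracle."""
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestAggregates:
    def test_chain_forms_one_component(self):
        contacts = ContactSet(0, frozenset({(0, 1), (1, 2)}), 6.0)
        report = aggregates(contacts, range(5))
        assert frozenset({0, 1, 2}) in report.components
        assert report.size_histogram == {3: 1, 1: 2}

    def test_empty_contacts_give_singletons(self):
        report = aggregates(ContactSet(0, frozenset(), 6.0), range(7))
        assert report.size_histogram == {1: 7}

    def test_random_graph_matches_transitive_closure_oracle(self, rng):
        for _ in range(25):
            n = 15
            pairs = {(int(i), int(j)) for i, j in
                     rng.integers(0, n, size=(10, 2)) if i < j}
            report = aggregates(ContactSet(0, frozenset(pairs), 6.0), range(n))
            assert set(report.components) == union_find_components(n, pairs)


def ring_frame(rotation=None, perturb=None, box=100.0):
    spec = monomer_spec()
    angles = 2 * np.pi * np.arange(9) / 9
    ring = np.column_stack([1.4 * np.cos(angles), 1.4 * np.sin(angles),
                            np.zeros(9)])
    coords = np.vstack([ring, ring[8] * (2.4 / 1.4)])
    if rotation is not None:
        coords = coords @ np.asarray(rotation).T
    if perturb is not None:
        coords = coords + perturb
    coords += 50.0
    topo = Topology([spec])
    return topo, Frame(coordinates=coords, box=np.full(3, box))


def rot_x(deg):
    r = np.radians(deg)
    return np.array([[1, 0, 0],
                     [0, np.cos(r), -np.sin(r)],
                     [0, np.sin(r), np.cos(r)]])


class TestPlaneNormal:
    def test_planar_ring_normal_is_z(self):
        topo, frame = ring_frame()
        normal = plane_normal(topo, frame, 0)
        assert pair_angle(normal, [0, 0, 1]) < 1e-8

    def test_rotated_ring_normal_follows_rotation(self):
        topo, frame = ring_frame(rotation=rot_x(30.0))
        normal = plane_normal(topo, frame, 0)
        assert abs(pair_angle(normal, [0, 0, 1]) - 30.0) < 1e-8

    def test_small_perturbation_moves_normal_less_than_a_degree(self, rng):
        perturb = np.zeros((10, 3))
        perturb[4] = [0.0, 0.0, 0.01]
        topo, clean = ring_frame()
        _, noisy = ring_frame(perturb=perturb)
        assert pair_angle(plane_normal(topo, clean, 0),
                          plane_normal(topo, noisy, 0)) < 1.0

    def test_collinear_ring_is_a_geometry_error(self):
        spec = MoleculeSpec("rod", [
            AtomSpec(f"C{i}", "C", 12.011, is_ring_atom=True) for i in range(3)])
        topo = Topology([spec])
        frame = Frame(coordinates=np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                                           dtype=float), box=[50, 50, 50])
        with pytest.raises(GeometryError, match="collinear"):
            plane_normal(topo, frame, 0)


class TestPairAngle:
    @pytest.mark.parametrize("n1,n2,expected", [
        ([0, 0, 1], [0, 0, 1], 0.0),
        ([1, 0, 0], [0, 1, 0], 90.0),
        ([0, 0, 1], [0, 0, -1], 0.0),  # axial folding
    ])
    def test_reference_angles(self, n1, n2, expected):
        assert pair_angle(n1, n2) == pytest.approx(expected, abs=1e-10)

    def test_zero_vector_rejected(self):
        with pytest.raises(GeometryError):
            pair_angle([0, 0, 0], [0, 0, 1])

    @given(st.lists(st.floats(-1, 1), min_size=6, max_size=6))
    def test_range_symmetry_and_folding(self, values):
        n1, n2 = np.array(values[:3]), np.array(values[3:])
        if np.linalg.norm(n1) < 1e-3 or np.linalg.norm(n2) < 1e-3:
            return
        angle = pair_angle(n1, n2)
        assert 0.0 <= angle <= 90.0
        assert pair_angle(n2, n1) == pytest.approx(angle, abs=1e-9)
        assert pair_angle(-n1, n2) == pytest.approx(angle, abs=1e-9)


class TestAngleDistribution:
    def test_perfect_stacks_have_zero_mean_and_full_stacked_fraction(self):
        cfg = TrajectoryGenConfig(n_monomer=10, n_frames=5, box_edge=60.0,
                                  stack_mean_size=5.0, stack_angle_sigma=0.0,
                                  seed=0)
        traj, _ = generate_trajectory(cfg)
        dist = angle_distribution(traj)
        assert dist.n > 0
        assert dist.mean == pytest.approx(0.0, abs=1e-6)
        assert dist.stacked_fraction == 1.0

    def test_histogram_integrates_to_one(self):
        cfg = TrajectoryGenConfig(n_monomer=12, n_frames=5, box_edge=60.0,
                                  stack_angle_sigma=25.0, seed=1)
        traj, _ = generate_trajectory(cfg)
        dist = angle_distribution(traj)
        widths = np.diff(dist.bin_edges)
        assert float((dist.density * widths).sum()) == pytest.approx(1.0)

    def test_stacked_fraction_monotone_in_angular_noise(self):
        fractions = []
        for sigma in (0.0, 10.0, 25.0, 45.0):
            cfg = TrajectoryGenConfig(n_monomer=30, n_frames=30, box_edge=90.0,
                                      stack_angle_sigma=sigma, seed=99)
            traj, _ = generate_trajectory(cfg)
            fractions.append(angle_distribution(traj).stacked_fraction)
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))
        assert fractions[0] == 1.0
        assert fractions[-1] < fractions[0]

    def test_no_contacts_yields_flagged_empty_distribution(self):
        cfg = TrajectoryGenConfig(n_monomer=4, n_frames=2, box_edge=80.0,
                                  stack_mean_size=1.0, seed=5)
        traj, _ = generate_trajectory(cfg)
        dist = angle_distribution(traj)
        assert dist.empty and dist.n == 0 and np.isnan(dist.mean)

    def test_angles_invariant_under_global_rotation(self):
        # Embed the configuration in a box large enough that every pair
        # distance stays below half the edge: the minimum image then equals
        # the Euclidean distance, which a rigid rotation preserves exactly.
        cfg = TrajectoryGenConfig(n_monomer=16, n_frames=3, box_edge=70.0,
                                  stack_angle_sigma=20.0, seed=8)
        traj, _ = generate_trajectory(cfg)
        big_box = np.full(3, 300.0)
        for frame in traj.frames:
            coords = frame.coordinates
            for m in range(traj.topology.n_molecules):
                sl = traj.topology.atom_slice(m)
                coords[sl] = make_whole(coords[sl], frame.box)
            frame.coordinates = coords + 115.0
            frame.box = big_box
        reference = angle_distribution(traj)
        rot = rot_x(37.0)
        center = np.full(3, 150.0)
        for frame in traj.frames:
            frame.coordinates = (frame.coordinates - center) @ rot.T + center
        rotated = angle_distribution(traj)
        assert rotated.n == reference.n > 0
        np.testing.assert_allclose(
            np.sort(rotated.angles), np.sort(reference.angles), atol=1e-6)


class TestHeterogeneityCompare:
    def test_self_comparison_is_null(self):
        cfg = TrajectoryGenConfig(n_monomer=12, n_frames=4, box_edge=60.0, seed=2)
        traj, _ = generate_trajectory(cfg)
        dist = angle_distribution(traj)
        comp = heterogeneity_compare(dist, dist)
        assert comp.mean_diff == 0 and comp.dispersion_diff == 0
        assert comp.ks_statistic == 0

    def test_delta_vs_uniform_ks_approaches_one(self):
        n = 4000
        delta = _dist_from(np.zeros(n))
        uniform = _dist_from(np.random.default_rng(0).uniform(0, 90, n))
        comp = heterogeneity_compare(delta, uniform)
        assert comp.ks_statistic > 0.95

    def test_dispersion_contrast_recovers_generative_difference(self):
        dists = {}
        for sigma in (5.0, 40.0):
            cfg = TrajectoryGenConfig(n_monomer=40, n_frames=60, box_edge=100.0,
                                      stack_angle_sigma=sigma, seed=21)
            traj, _ = generate_trajectory(cfg)
            dists[sigma] = angle_distribution(traj)
        measured = dists[40.0].dispersion - dists[5.0].dispersion
        assert abs(measured - 35.0) / 35.0 < 0.2

    def test_empty_input_rejected(self):
        good = _dist_from(np.array([1.0, 2.0]))
        empty = AngleDistribution(samples=[], bin_edges=np.linspace(0, 90, 19),
                                  density=np.zeros(18), mean=np.nan,
                                  dispersion=np.nan, stacked_fraction=np.nan,
                                  stack_threshold=30.0, empty=True,
                                  angles=np.array([]))
        with pytest.raises(MolstackError):
            heterogeneity_compare(good, empty)


def _dist_from(angles):
    edges = np.linspace(0, 90, 19)
    density, _ = np.histogram(angles, bins=edges, density=True)
    return AngleDistribution(samples=[], bin_edges=edges, density=density,
                             mean=float(angles.mean()),
                             dispersion=float(np.sqrt(np.mean(angles ** 2))),
                             stacked_fraction=float(np.mean(angles < 30)),
                             stack_threshold=30.0, angles=np.asarray(angles))


def test_minimum_image_bounds():
    box = np.array([10.0, 10.0, 10.0])
    delta = minimum_image(np.array([[9.0, -9.0, 21.0]]), box)
    np.testing.assert_allclose(delta, [[-1.0, 1.0, 1.0]])
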