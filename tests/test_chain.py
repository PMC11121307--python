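"""Hydrogen-bond graph edges, path connectivity, and chain verdicts."""

import numpy as np
import pytest

from halfchannel.chain import (
    HBondCriteria,
    connectivity_fraction,
    detect_hbond_edges,
    frame_connected,
    pairwise_min_distance_series,
)
from halfchannel.core import Topology, Trajectory
from halfchannel.errors import ValidationError
from halfchannel.synthetic import (
    _exhaustive_connected,
    generate_toy_trajectory,
    make_fixture_spec,
    scenario_for_fixture,
)

from conftest import protein_atom, water_topology


def test_two_waters_within_cutoff_form_edge():
    top = water_topology(2)
    frame = np.array([[0.0, 0, 0], [2.7, 0, 0]])
    edges = detect_hbond_edges(frame, np.arange(2), top)
    assert edges == [(0, 1)]


def test_pair_beyond_cutoff_no_edge():
    atoms = [
        protein_atom(1, "OE1", "GLU", 219),
        protein_atom(2, "O", "HOH", 300, chain_id="W", element="O"),
    ]
    top = Topology(atoms)
    frame = np.array([[0.0, 0, 0], [3.2, 0, 0]])
    assert detect_hbond_edges(frame, np.arange(2), top) == []


def test_donor_donor_pairs_do_not_bond():
    atoms = [
        protein_atom(1, "NH1", "ARG", 10),
        protein_atom(2, "NZ", "LYS", 20),
    ]
    top = Topology(atoms)
    frame = np.array([[0.0, 0, 0], [2.5, 0, 0]])
    assert detect_hbond_edges(frame, np.arange(2), top) == []


def test_edges_match_brute_force():
    from halfchannel.core import is_acceptor_capable, is_donor_capable

    rng = np.random.default_rng(12)
    names = [
        ("SER", "OG"), ("ASN", "OD1"), ("ASN", "ND2"),
        ("ARG", "NH1"), ("GLU", "OE1"), ("HOH", "O"),
    ]
    atoms = []
    for i in range(30):
        res_name, name = names[i % len(names)]
        chain = "W" if res_name == "HOH" else "A"
        atoms.append(
            protein_atom(i + 1, name, res_name, i + 1, chain_id=chain,
                         element=name[0])
        )
    top = Topology(atoms)
    frame = rng.uniform(0, 10, size=(30, 3))
    got = set(detect_hbond_edges(frame, np.arange(30), top))
    brute = set()
    for i in range(30):
        for j in range(i + 1, 30):
            a, b = top.atoms[i], top.atoms[j]
            if (a.chain_id, a.res_seq) == (b.chain_id, b.res_seq):
                continue
            if np.linalg.norm(frame[i] - frame[j]) > 3.0:
                continue
            if (is_donor_capable(a.role) and is_acceptor_capable(b.role)) or (
                is_donor_capable(b.role) and is_acceptor_capable(a.role)
            ):
                brute.add((i, j))
    assert got == brute


def test_edge_monotone_in_cutoff():
    rng = np.random.default_rng(13)
    top = water_topology(15)
    frame = rng.uniform(0, 8, size=(15, 3))
    small = set(detect_hbond_edges(frame, np.arange(15), top,
                                   HBondCriteria(2.5)))
    large = set(detect_hbond_edges(frame, np.arange(15), top,
                                   HBondCriteria(3.5)))
    assert small <= large


class TestFrameConnected:
    def _wire(self, n, spacing=2.7):
        top = water_topology(n)
        frame = np.zeros((n, 3))
        frame[:, 0] = spacing * np.arange(n)
        return top, frame

    def test_linear_wire_connects(self):
        top, frame = self._wire(6)
        ok, path = frame_connected(frame, top, [0], [5])
        assert ok
        assert path == [0, 1, 2, 3, 4, 5]

    def test_gap_disconnects(self):
        top, frame = self._wire(6)
        frame = np.delete(frame, 3, axis=0)
        top = water_topology(5)
        ok, path = frame_connected(frame, top, [0], [4])
        assert not ok and path is None

    def test_source_sink_overlap_rejected(self):
        top, frame = self._wire(4)
        with pytest.raises(ValidationError, match="overlap"):
            frame_connected(frame, top, [0, 1], [1, 3])

    def test_matches_exhaustive_search_on_random_geometries(self):
        """50 random 20-node systems against the exhaustive DFS oracle."""
        rng = np.random.default_rng(14)
        n = 20
        top = water_topology(n)
        active = np.ones(n, dtype=bool)
        agree = 0
        for _ in range(50):
            frame = rng.uniform(0, 9, size=(n, 3))
            ok, _ = frame_connected(frame, top, [0], [n - 1])
            brute = _exhaustive_connected(
                frame, top, active, np.array([0]), np.array([n - 1])
            )
            assert ok == brute
            agree += 1
        assert agree == 50

    def test_witness_is_deterministic(self):
        rng = np.random.default_rng(15)
        top = water_topology(12)
        frame = rng.uniform(0, 6, size=(12, 3))
        r1 = frame_connected(frame, top, [0], [11])
        r2 = frame_connected(frame, top, [0], [11])
        assert r1 == r2


class TestConnectivityVerdicts:
    @pytest.mark.parametrize(
        "label,expected",
        [("aH245G", "interrupted"), ("aH245S", "preserved")],
    )
    def test_mutant_fixture_verdicts(self, label, expected):
        traj, _ = generate_toy_trajectory(make_fixture_spec(label, 80, seed=17))
        verdict = connectivity_fraction(traj, scenario_for_fixture(label))
        assert verdict.verdict == expected

    def test_fully_wired_system_100_percent(self):
        spec = make_fixture_spec("WT", n_frames=40, seed=18)
        for m in spec.cluster_models.values():
            m.presence_prob = 1.0
        traj, _ = generate_toy_trajectory(spec)
        verdict = connectivity_fraction(traj, scenario_for_fixture("WT"))
        assert verdict.connectivity_fraction_pct == 100.0
        assert verdict.verdict == "preserved"
        assert verdict.broken_links == []
        assert verdict.witness_path is not None

    def test_agrees_with_generator_ground_truth(self, wt_system):
        traj, truth, scenario = wt_system
        verdict = connectivity_fraction(traj, scenario)
        assert np.array_equal(verdict.per_frame_connected, truth.connectivity)

    def test_broken_links_name_missing_relay(self):
        traj, _ = generate_toy_trajectory(make_fixture_spec("aN214L", 60, seed=19))
        verdict = connectivity_fraction(traj, scenario_for_fixture("aN214L"))
        assert "W2/W3-aN214" in verdict.broken_links
        assert "aN214-W1" in verdict.broken_links


class TestPairwiseMinDistance:
    def test_static_value(self):
        top = water_topology(2)
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = 4.0
        series, mean, mn = pairwise_min_distance_series(
            Trajectory(top, coords), [0], [1]
        )
        assert mean == 4.0 and mn == 4.0

    def test_two_frame_mean_and_min(self):
        top = water_topology(2)
        coords = np.zeros((2, 2, 3))
        coords[0, 1, 0] = 3.0
        coords[1, 1, 0] = 5.0
        _, mean, mn = pairwise_min_distance_series(
            Trajectory(top, coords), [0], [1]
        )
        assert mean == 4.0 and mn == 3.0

    def test_matches_brute_force_cross_pairs(self):
        rng = np.random.default_rng(16)
        top = water_topology(9)
        coords = rng.uniform(0, 10, size=(5, 9, 3))
        traj = Trajectory(top, coords)
        sel_a, sel_b = np.array([0, 1, 2, 3]), np.array([4, 5, 6, 7, 8])
        series, _, _ = pairwise_min_distance_series(traj, sel_a, sel_b)
        for f in range(5):
            brute = min(
                np.linalg.norm(coords[f, i] - coords[f, j])
                for i in sel_a for j in sel_b
            )
            assert series[f] == pytest.approx(brute, abs=1e-12)

    def test_empty_selection_rejected(self, static_trajectory):
        with pytest.raises(ValidationError):
            pairwise_min_distance_series(static_trajectory, [], [0])
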