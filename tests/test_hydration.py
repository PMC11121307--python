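"""Water-cluster occupancy, capacity, and cross-scenario comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from halfchannel.core import Topology, Trajectory
from halfchannel.errors import SelectionError, ValidationError
from halfchannel.hydration import (
    ClusterRegionSpec,
    cluster_stats,
    compare_cluster_stats,
    count_waters_in_region,
    resolve_region_center,
)
from halfchannel.synthetic import (
    generate_toy_trajectory,
    make_fixture_spec,
    scenario_for_fixture,
)

from conftest import protein_atom, water_topology


def _two_anchor_topology():
    atoms = [
        protein_atom(1, "CA", "GLY", 1),
        protein_atom(2, "CA", "GLY", 2),
    ]
    return Topology(atoms)


def _region(radius=3.5):
    return ClusterRegionSpec(
        name="W1",
        anchor_a="resid 1 and name CA",
        anchor_b="resid 2 and name CA",
        radius=radius,
    )


def test_center_is_anchor_midpoint():
    top = _two_anchor_topology()
    frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    np.testing.assert_allclose(
        resolve_region_center(frame, _region(), top), [1.0, 0, 0]
    )


def test_center_of_coincident_anchors():
    top = _two_anchor_topology()
    frame = np.array([[1.0, 2, 3], [1.0, 2, 3]])
    np.testing.assert_allclose(
        resolve_region_center(frame, _region(), top), [1.0, 2, 3]
    )


def test_center_multi_atom_anchors_hand_computed():
    atoms = [
        protein_atom(1, "CA", "GLY", 1),
        protein_atom(2, "N", "GLY", 1),
        protein_atom(3, "CA", "GLY", 2),
    ]
    top = Topology(atoms)
    frame = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 4.0, 0]])
    region = ClusterRegionSpec("r", "resid 1", "resid 2")
    # centroid A = (1,0,0); centroid B = (4,4,0); midpoint = (2.5,2,0)
    np.testing.assert_allclose(
        resolve_region_center(frame, region, top), [2.5, 2.0, 0.0]
    )


def test_unresolvable_anchor_named():
    top = _two_anchor_topology()
    region = ClusterRegionSpec("W9", "resid 77", "resid 2")
    with pytest.raises(SelectionError, match="W9"):
        resolve_region_center(np.zeros((2, 3)), region, top)


def test_no_waters_counts_zero():
    top = _two_anchor_topology()
    frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    assert count_waters_in_region(frame, _region(), top) == 0


def test_boundary_counting():
    """Waters just inside the radius count; just outside do not."""
    radius = 3.5
    anchors = [protein_atom(1, "CA", "GLY", 1), protein_atom(2, "CA", "GLY", 2)]
    waters = water_topology(5).atoms
    waters = [
        type(w)(w.serial + 2, w.name, w.element, w.res_name, w.res_seq, w.chain_id,
                w.role)
        for w in waters
    ]
    top = Topology(anchors + waters)
    frame = np.zeros((7, 3))
    frame[1] = [2.0, 0, 0]  # center (1,0,0)
    for k in range(3):
        frame[2 + k] = [1.0 + radius - 0.1, 0, 0.0 + 0.01 * k]
    for k in range(2):
        frame[5 + k] = [1.0 + radius + 0.1, 0, 0.01 * k]
    assert count_waters_in_region(frame, _region(radius), top) == 3


def test_count_matches_brute_force():
    rng = np.random.default_rng(11)
    anchors = [protein_atom(1, "CA", "GLY", 1), protein_atom(2, "CA", "GLY", 2)]
    n_w = 40
    waters = [
        protein_atom(3 + i, "O", "HOH", 100 + i, chain_id="W", element="O")
        for i in range(n_w)
    ]
    top = Topology(anchors + waters)
    frame = rng.uniform(-5, 5, size=(2 + n_w, 3))
    center = 0.5 * (frame[0] + frame[1])
    brute = sum(
        1 for i in range(2, 2 + n_w)
        if np.linalg.norm(frame[i] - center) <= 3.5
    )
    assert count_waters_in_region(frame, _region(), top) == brute


def test_cluster_stats_direct_definition():
    """Counts [0,1,2,1] -> occupancy 75%, pdf {0:1/4, 1:1/2, 2:1/4}."""
    anchors = [protein_atom(1, "CA", "GLY", 1), protein_atom(2, "CA", "GLY", 2)]
    waters = [
        protein_atom(3 + i, "O", "HOH", 100 + i, chain_id="W", element="O")
        for i in range(2)
    ]
    top = Topology(anchors + waters)
    far = np.array([100.0, 0, 0])
    near = np.array([1.0, 0, 0])
    coords = np.zeros((4, 4, 3))
    coords[:, 1, :] = [2.0, 0, 0]
    placements = [(far, far), (near, far), (near, near), (far, near)]
    for f, (w1, w2) in enumerate(placements):
        coords[f, 2, :] = w1
        coords[f, 3, :] = w2
    stats = cluster_stats(Trajectory(top, coords), _region())
    assert stats.occupancy_pct == 75.0
    assert stats.capacity_pdf == {0: 0.25, 1: 0.5, 2: 0.25}
    assert list(stats.count_series) == [0, 1, 2, 1]


def test_always_occupied_is_100_percent(wt_system):
    traj, _, scenario = wt_system
    spec = make_fixture_spec("WT", n_frames=30, seed=2)
    for m in spec.cluster_models.values():
        m.presence_prob = 1.0
    full, _ = generate_toy_trajectory(spec)
    for region in scenario.regions:
        assert cluster_stats(full, region).occupancy_pct == 100.0


def test_occupancy_pdf_identity_and_normalization(wt_system):
    traj, _, scenario = wt_system
    for region in scenario.regions:
        stats = cluster_stats(traj, region)
        assert sum(stats.capacity_pdf.values()) == pytest.approx(1.0, abs=1e-12)
        assert stats.occupancy_pct == pytest.approx(
            100.0 * (1.0 - stats.capacity_pdf[0]), abs=1e-12
        )


@given(radius=st.floats(min_value=0.5, max_value=8.0))
def test_enlarging_radius_never_decreases_counts(wt_system, radius):
    traj, _, scenario = wt_system
    base = scenario.regions[0]
    small = ClusterRegionSpec(base.name, base.anchor_a, base.anchor_b, radius)
    big = ClusterRegionSpec(base.name, base.anchor_a, base.anchor_b, radius + 1.0)
    sub = Trajectory(traj.topology, traj.coordinates[:25])
    s_small = cluster_stats(sub, small)
    s_big = cluster_stats(sub, big)
    assert (s_big.count_series >= s_small.count_series).all()
    assert s_big.occupancy_pct >= s_small.occupancy_pct


def _stats_for(label, n_frames=200, seed=13):
    traj, _ = generate_toy_trajectory(make_fixture_spec(label, n_frames, seed))
    scen = scenario_for_fixture(label)
    return {r.name: cluster_stats(traj, r) for r in scen.regions}


def test_compare_flags_cluster_disappearance():
    stats = {"WT": _stats_for("WT"), "aH245G": _stats_for("aH245G")}
    rows = compare_cluster_stats(stats, reference="WT")
    flagged = {
        (r["region"], r["scenario"]): r["cluster_absent"] for r in rows
    }
    assert flagged[("W2/W3", "aH245G")] is True
    assert flagged[("W2/W3", "WT")] is False
    assert flagged[("W1", "aH245G")] is False  # reduced, not absent


def test_compare_identical_inputs_zero_deltas():
    wt = _stats_for("WT")
    rows = compare_cluster_stats({"A": wt, "B": wt}, reference="A")
    assert all(r["delta_occupancy_pct"] == 0.0 for r in rows)
    assert all(r["delta_max_count"] == 0 for r in rows)


def test_compare_detects_occupancy_drop_binomial():
    """p=0.9 vs p=0.3 should show ~-60 point occupancy delta."""
    n = 400
    spec_hi = make_fixture_spec("WT", n_frames=n, seed=31)
    spec_lo = make_fixture_spec("WT", n_frames=n, seed=32)
    spec_hi.cluster_models["W1"].presence_prob = 0.9
    spec_lo.cluster_models["W1"].presence_prob = 0.3
    scen = scenario_for_fixture("WT")
    out = {}
    for name, spec in (("hi", spec_hi), ("lo", spec_lo)):
        traj, _ = generate_toy_trajectory(spec)
        out[name] = {r.name: cluster_stats(traj, r) for r in scen.regions}
    rows = compare_cluster_stats(out, reference="hi")
    delta = next(
        r["delta_occupancy_pct"] for r in rows
        if r["region"] == "W1" and r["scenario"] == "lo"
    )
    se = 100 * np.sqrt(0.9 * 0.1 / n + 0.3 * 0.7 / n)
    assert abs(delta - (-60.0)) <= 3 * se


def test_compare_mismatched_regions_rejected():
    wt = _stats_for("WT")
    partial = {"W1": wt["W1"]}
    with pytest.raises(ValidationError, match="regions"):
        compare_cluster_stats({"A": wt, "B": partial})
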