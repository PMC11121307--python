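"""Per-frame hydrogen-bond graph and proton-transfer-chain continuity.

The transfer chain is modeled as a graph whose nodes are the polar
side-chain heavy atoms of the chain residues plus the water oxygens inside
the analysis zone, with an edge whenever a donor-capable atom and an
acceptor-capable atom lie within the heavy-atom cutoff (~3 Angstrom, the
approximate hydrogen-bond length; water counts as both).  The chain is
continuous in a frame when any path connects a source atom to a sink atom.
A scenario's verdict is "interrupted" when the fraction of connected frames
falls below a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import (
    ROLE_NONE,
    ROLE_WATER_OXYGEN,
    Topology,
    Trajectory,
    is_acceptor_capable,
    is_donor_capable,
)
from .errors import SelectionError, ValidationError
from .hydration import resolve_region_center
from .io import ScenarioSpec

#: Connectivity fraction (percent) below which the chain counts as interrupted.
DEFAULT_INTERRUPTION_THRESHOLD_PCT = 5.0

#: Radius of the water corridor around canonical chain residues (Angstrom).
DEFAULT_CORRIDOR_RADIUS = 6.0


@dataclass(frozen=True)
class HBondCriteria:
    """Heavy-atom distance criterion for a hydrogen bond.

    ``optional_angle_min`` is accepted for completeness but the default
    criterion is purely distance-based, matching a heavy-atom-only analysis
    (no explicit hydrogens are required).
    """

    max_heavy_distance: float = 3.0
    optional_angle_min: float | None = None

    def __post_init__(self):
        if self.max_heavy_distance <= 0:
            raise ValidationError("max_heavy_distance must be positive")


@dataclass
class ChainGraph:
    """Node atom indices and symmetric H-bond edges for one frame."""

    frame_index: int
    nodes: np.ndarray
    edges: list[tuple[int, int]]

    def as_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(int(i) for i in self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class ChainVerdict:
    """Continuity verdict for one scenario."""

    label: str
    connectivity_fraction_pct: float
    verdict: str  # "preserved" | "interrupted"
    broken_links: list[str]
    per_frame_connected: np.ndarray
    witness_path: list[int] | None = None
    threshold_pct: float = DEFAULT_INTERRUPTION_THRESHOLD_PCT

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "connectivity_fraction_pct": round(self.connectivity_fraction_pct, 1),
            "verdict": self.verdict,
            "broken_links": list(self.broken_links),
            "threshold_pct": self.threshold_pct,
            "witness_path": list(self.witness_path) if self.witness_path else None,
        }


def chain_nodes(
    frame: np.ndarray,
    topology: Topology,
    scenario: ScenarioSpec | None = None,
    corridor_radius: float = DEFAULT_CORRIDOR_RADIUS,
) -> np.ndarray:
    """Atom indices participating in the frame's H-bond graph.

    All polar (non-water) atoms are nodes.  Water oxygens are restricted to
    the analysis zone: inside any cluster-region sphere or within the
    corridor radius of a canonical chain residue atom.  Without a scenario,
    every water oxygen is a node.
    """
    polar = [
        i
        for i, a in enumerate(topology.atoms)
        if a.role not in (ROLE_NONE, ROLE_WATER_OXYGEN)
    ]
    waters = topology.water_oxygen_indices()
    if scenario is None or len(waters) == 0:
        return np.array(polar + list(waters), dtype=int)

    keep = np.zeros(len(waters), dtype=bool)
    wpts = frame[waters]
    for region in scenario.regions:
        center = resolve_region_center(frame, region, topology)
        keep |= np.linalg.norm(wpts - center, axis=1) <= region.radius
    anchor_idx: list[int] = []
    for step in scenario.canonical_chain:
        if step.kind == "residue" and step.selection:
            try:
                anchor_idx.extend(topology.select(step.selection))
            except SelectionError:
                continue  # substituted-away residue: no corridor contribution
    if anchor_idx:
        d = np.linalg.norm(
            wpts[:, None, :] - frame[np.array(anchor_idx)][None, :, :], axis=2
        )
        keep |= (d <= corridor_radius).any(axis=1)
    return np.array(polar + list(waters[keep]), dtype=int)


def detect_hbond_edges(
    frame: np.ndarray,
    nodes: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[tuple[int, int]]:
    """H-bond edges among the given node atoms (atom-index pairs, i < j).

    An edge requires the heavy-atom distance to be within the cutoff and one
    side donor-capable, the other acceptor-capable; intra-residue pairs are
    excluded.
    """
    nodes = np.asarray(nodes, dtype=int)
    if len(nodes) < 2:
        return []
    pts = np.asarray(frame, dtype=float)[nodes]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(criteria.max_heavy_distance, output_type="ndarray")
    edges = []
    for a_loc, b_loc in pairs:
        i, j = int(nodes[a_loc]), int(nodes[b_loc])
        a, b = topology.atoms[i], topology.atoms[j]
        if (a.chain_id, a.res_seq) == (b.chain_id, b.res_seq):
            continue
        ok = (is_donor_capable(a.role) and is_acceptor_capable(b.role)) or (
            is_donor_capable(b.role) and is_acceptor_capable(a.role)
        )
        if ok:
            edges.append((min(i, j), max(i, j)))
    edges.sort()
    return edges


def frame_connected(
    frame: np.ndarray,
    topology: Topology,
    source_nodes,
    sink_nodes,
    criteria: HBondCriteria = HBondCriteria(),
    nodes: np.ndarray | None = None,
):
    """Whether any H-bond path joins a source atom to a sink atom.

    Returns ``(connected, witness_path)``; the witness is a hop-count
    shortest path found by breadth-first search with sorted neighbor order,
    so it is deterministic for a given frame.
    """
    source = sorted(int(i) for i in np.atleast_1d(source_nodes))
    sink = set(int(i) for i in np.atleast_1d(sink_nodes))
    if not source or not sink:
        raise ValidationError("source and sink node sets must be non-empty")
    if set(source) & sink:
        raise ValidationError("source and sink node sets overlap")
    if nodes is None:
        nodes = np.array(
            sorted(set(source) | sink | set(
                i for i, a in enumerate(topology.atoms) if a.role != ROLE_NONE
            )),
            dtype=int,
        )
    edges = detect_hbond_edges(frame, nodes, topology, criteria)
    adjacency: dict[int, list[int]] = {int(i): [] for i in nodes}
    for i, j in edges:
        adjacency[i].append(j)
        adjacency[j].append(i)
    for neigh in adjacency.values():
        neigh.sort()

    parent: dict[int, int | None] = {s: None for s in source if s in adjacency}
    queue = [s for s in source if s in adjacency]
    while queue:
        nxt = []
        for u in queue:
            if u in sink:
                path = [u]
                while parent[path[-1]] is not None:
                    path.append(parent[path[-1]])
                return True, path[::-1]
            for v in adjacency[u]:
                if v not in parent:
                    parent[v] = u
                    nxt.append(v)
        queue = nxt
    return False, None


def _step_atom_sets(
    frame: np.ndarray, topology: Topology, scenario: ScenarioSpec
) -> list[set[int]]:
    """Atom set of every canonical-chain step for one frame."""
    waters = topology.water_oxygen_indices()
    wpts = frame[waters] if len(waters) else None
    region_by_name = {r.name: r for r in scenario.regions}
    sets = []
    for step in scenario.canonical_chain:
        if step.kind == "residue":
            try:
                idx = topology.select(step.selection) if step.selection else []
            except SelectionError:
                idx = []
            sets.append(set(int(i) for i in idx))
        else:
            members: set[int] = set()
            if wpts is not None:
                for name in step.regions:
                    region = region_by_name[name]
                    center = resolve_region_center(frame, region, topology)
                    inside = np.linalg.norm(wpts - center, axis=1) <= region.radius
                    members.update(int(i) for i in waters[inside])
            sets.append(members)
    return sets


def connectivity_fraction(
    traj: Trajectory,
    scenario: ScenarioSpec,
    criteria: HBondCriteria = HBondCriteria(),
    threshold_pct: float = DEFAULT_INTERRUPTION_THRESHOLD_PCT,
    corridor_radius: float = DEFAULT_CORRIDOR_RADIUS,
) -> ChainVerdict:
    """Aggregate per-frame source-to-sink connectivity into a verdict.

    ``broken_links`` lists consecutive canonical-chain segments that are
    bridged in no frame at all (e.g. after a polar residue is substituted
    away, or when a cluster region stays dry).
    """
    if traj.n_frames < 1:
        raise ValidationError("empty trajectory")
    top = traj.topology
    source = top.select(scenario.source_selection)
    sink = top.select(scenario.sink_selection)
    if len(source) == 0:
        raise SelectionError(
            f"source selection {scenario.source_selection!r} matched no atoms"
        )
    if len(sink) == 0:
        raise SelectionError(
            f"sink selection {scenario.sink_selection!r} matched no atoms"
        )

    connected = np.zeros(traj.n_frames, dtype=bool)
    witness: list[int] | None = None
    n_steps = len(scenario.canonical_chain)
    segment_bridged = np.zeros(max(n_steps - 1, 0), dtype=bool)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        nodes = chain_nodes(frame, top, scenario, corridor_radius)
        edges = detect_hbond_edges(frame, nodes, top, criteria)
        ok, path = frame_connected(
            frame, top, source, sink, criteria, nodes=nodes
        )
        connected[f] = ok
        if ok and witness is None:
            witness = path
        if n_steps >= 2 and not segment_bridged.all():
            step_sets = _step_atom_sets(frame, top, scenario)
            edge_set = set(edges)
            for s in range(n_steps - 1):
                if segment_bridged[s]:
                    continue
                a_set, b_set = step_sets[s], step_sets[s + 1]
                for i, j in edge_set:
                    if (i in a_set and j in b_set) or (j in a_set and i in b_set):
                        segment_bridged[s] = True
                        break

    fraction = 100.0 * float(connected.sum()) / traj.n_frames
    broken = [
        f"{scenario.canonical_chain[s].label}-{scenario.canonical_chain[s + 1].label}"
        for s in range(n_steps - 1)
        if not segment_bridged[s]
    ]
    verdict = "interrupted" if fraction < threshold_pct else "preserved"
    return ChainVerdict(
        label=scenario.label,
        connectivity_fraction_pct=fraction,
        verdict=verdict,
        broken_links=broken,
        per_frame_connected=connected,
        witness_path=witness,
        threshold_pct=threshold_pct,
    )


def pairwise_min_distance_series(
    traj: Trajectory, sel_a: np.ndarray, sel_b: np.ndarray
):
    """Per-frame minimum cross-pair distance (Angstrom), its mean and minimum."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValidationError("both selections must be non-empty")
    a = traj.coordinates[:, sel_a, :]
    b = traj.coordinates[:, sel_b, :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=3)
    series = d.reshape(traj.n_frames, -1).min(axis=1)
    return series, float(series.mean()), float(series.min())
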