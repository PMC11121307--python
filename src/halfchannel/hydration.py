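"""Structural water clusters W1-W3: counts, occupancy, capacity.

A cluster region is a sphere whose center is re-resolved every frame as the
midpoint of two anchor-group centroids, so the region tracks residue motion.
Occupancy is the percentage of frames with at least one water oxygen inside
the sphere; capacity is the per-frame water count, summarized as a
probability distribution over integer counts taken over *all* frames (zeros
included), which makes ``occupancy = 100 * (1 - pdf[0])`` an identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Topology, Trajectory
from .errors import SelectionError, ValidationError

#: Occupancy below which a cluster is reported as absent ("disappeared").
ABSENCE_THRESHOLD_PCT = 5.0


@dataclass
class ClusterRegionSpec:
    """Named spherical region anchored to two residue atom groups."""

    name: str
    anchor_a: str
    anchor_b: str
    radius: float = 3.5
    center_rule: str = "midpoint_of_anchor_centroids"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError(f"region {self.name!r}: radius must be positive")
        if self.center_rule != "midpoint_of_anchor_centroids":
            raise ValidationError(
                f"region {self.name!r}: unknown center rule {self.center_rule!r}"
            )


@dataclass
class ClusterStats:
    """Occupancy, capacity distribution and count series for one region."""

    name: str
    occupancy_pct: float
    capacity_pdf: dict[int, float]
    count_series: np.ndarray

    def max_count(self) -> int:
        return int(self.count_series.max()) if len(self.count_series) else 0

    def capacity_mode(self) -> int:
        """Most probable nonzero count (0 if the region is never occupied)."""
        nonzero = {k: v for k, v in self.capacity_pdf.items() if k > 0}
        if not nonzero:
            return 0
        best = max(nonzero.values())
        return min(k for k, v in nonzero.items() if v == best)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "occupancy_pct": round(self.occupancy_pct, 1),
            "capacity_pdf": {str(k): v for k, v in sorted(self.capacity_pdf.items())},
            "max_count": self.max_count(),
            "capacity_mode": self.capacity_mode(),
        }


def _anchor_indices(topology: Topology, region: ClusterRegionSpec):
    out = []
    for label, sel in (("anchor_a", region.anchor_a), ("anchor_b", region.anchor_b)):
        idx = topology.select(sel)
        if len(idx) == 0:
            raise SelectionError(
                f"region {region.name!r}: {label} selection {sel!r} matched no atoms"
            )
        out.append(idx)
    return out


def resolve_region_center(
    frame: np.ndarray, region: ClusterRegionSpec, topology: Topology
) -> np.ndarray:
    """Region center for one frame: midpoint of the two anchor centroids."""
    idx_a, idx_b = _anchor_indices(topology, region)
    centroid_a = frame[idx_a].mean(axis=0)
    centroid_b = frame[idx_b].mean(axis=0)
    return 0.5 * (centroid_a + centroid_b)


def count_waters_in_region(
    frame: np.ndarray,
    region: ClusterRegionSpec,
    topology: Topology,
    water_indices: np.ndarray | None = None,
) -> int:
    """Number of water oxygens within ``region.radius`` of the frame's center."""
    if water_indices is None:
        water_indices = topology.water_oxygen_indices()
    if len(water_indices) == 0:
        return 0
    center = resolve_region_center(frame, region, topology)
    d = np.linalg.norm(frame[water_indices] - center, axis=1)
    return int(np.count_nonzero(d <= region.radius))


def cluster_stats(traj: Trajectory, region: ClusterRegionSpec) -> ClusterStats:
    """Per-frame water counts in a region, with occupancy and capacity PDF."""
    top = traj.topology
    waters = top.water_oxygen_indices()
    idx_a, idx_b = _anchor_indices(top, region)
    counts = np.zeros(traj.n_frames, dtype=int)
    if len(waters):
        coords = traj.coordinates
        centers = 0.5 * (
            coords[:, idx_a, :].mean(axis=1) + coords[:, idx_b, :].mean(axis=1)
        )
        d = np.linalg.norm(coords[:, waters, :] - centers[:, None, :], axis=2)
        counts = (d <= region.radius).sum(axis=1).astype(int)
    occupancy = 100.0 * float(np.count_nonzero(counts >= 1)) / traj.n_frames
    values, freq = np.unique(counts, return_counts=True)
    pdf = {int(v): float(c) / traj.n_frames for v, c in zip(values, freq)}
    if 0 not in pdf:
        pdf[0] = 0.0
    return ClusterStats(
        name=region.name,
        occupancy_pct=occupancy,
        capacity_pdf=dict(sorted(pdf.items())),
        count_series=counts,
    )


def compare_cluster_stats(
    stats_by_scenario: dict[str, dict[str, ClusterStats]],
    reference: str | None = None,
    absence_threshold_pct: float = ABSENCE_THRESHOLD_PCT,
) -> list[dict]:
    """Per-region occupancy/capacity comparison of scenarios to a reference.

    Returns rows sorted by region name then scenario label, each with the
    occupancy delta relative to the reference scenario, the change in
    capacity support (max observed count), and a ``cluster_absent`` flag for
    occupancies below the absence threshold.
    """
    if len(stats_by_scenario) < 2:
        raise ValidationError("need at least two scenarios to compare")
    labels = list(stats_by_scenario)
    region_sets = {lbl: set(d.keys()) for lbl, d in stats_by_scenario.items()}
    first = region_sets[labels[0]]
    for lbl, names in region_sets.items():
        if names != first:
            raise ValidationError(
                f"scenario {lbl!r} regions {sorted(names)} do not match "
                f"{sorted(first)}"
            )
    if reference is None:
        reference = labels[0]
    if reference not in stats_by_scenario:
        raise ValidationError(f"reference scenario {reference!r} not present")

    rows = []
    for region in sorted(first):
        ref = stats_by_scenario[reference][region]
        for label in sorted(labels):
            st = stats_by_scenario[label][region]
            rows.append(
                {
                    "region": region,
                    "scenario": label,
                    "occupancy_pct": round(st.occupancy_pct, 1),
                    "delta_occupancy_pct": round(
                        st.occupancy_pct - ref.occupancy_pct, 1
                    ),
                    "max_count": st.max_count(),
                    "delta_max_count": st.max_count() - ref.max_count(),
                    "cluster_absent": st.occupancy_pct < absence_threshold_pct,
                }
            )
    return rows
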