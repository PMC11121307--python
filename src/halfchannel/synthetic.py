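"""Synthetic half-channel systems with known ground truth.

The generator builds a toy version of the inlet half-channel bottleneck:
pseudo-residues whose polar side-chain atoms sit on a line from the gate to
the proton-accepting aspartate, two water-cluster regions between them, a
side chain that hops among a few stable spatial modes, and backbone atoms
with Gaussian jitter.  Spacings are chosen so that consecutive polar sites
are within hydrogen-bond reach (2.7 Angstrom) where residues link directly,
and out of reach (5.4 Angstrom) where the link must be bridged by a water
inside a cluster region.  Water placement radii are small enough (0.3
Angstrom) that any water present in a region bridges its flanking sites by
construction, so source-to-sink connectivity per frame is exactly
"every bridging region occupied (and every relay side chain present)".

Ground truth (per-frame water counts, side-chain mode labels, connectivity
flags) is recorded at generation time; connectivity is verified with an
exhaustive depth-first path search implemented independently of the graph
analyzer.

The ten packaged fixtures (wild type plus nine substitutions) encode the
study's qualitative per-mutant hydration outcomes: printed occupancies are
used where available (wild type W1 92%, H245G 44%, N214L 36%), capacity
supports follow the narrative (wild type W2/W3 holds at most two waters,
Q252L up to four, H245G loses W2/W3 entirely, H245Y loses W1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AtomRecord,
    Topology,
    Trajectory,
    assign_role,
    is_acceptor_capable,
    is_donor_capable,
)
from .errors import ValidationError
from .io import ScenarioSpec, scenario_from_dict

HBOND_CUTOFF = 3.0

# x-coordinates (Angstrom) of the toy transfer chain, gate to sink.
_X_E219, _X_D119, _X_H245 = 0.0, 2.7, 5.4
_X_W23, _X_N214, _X_W1, _X_D61 = 8.1, 10.8, 13.5, 16.2

# backbone heavy-atom offsets relative to the residue's CA position
_BACKBONE_TEMPLATE = {
    "N": np.array([-0.7, -0.5, 0.3]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.7, -0.5, -0.3]),
    "O": np.array([1.0, 0.2, -0.9]),
}

_PARK_BASE = np.array([500.0, 0.0, 0.0])  # absent waters parked far away
_PARK_SPACING = 10.0


@dataclass
class PolarSite:
    """One pseudo-residue: backbone anchor plus optional polar side-chain atoms."""

    chain_id: str
    res_seq: int
    res_name: str
    sidechain_atoms: list[tuple[str, np.ndarray]] = field(default_factory=list)
    ca_position: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class ClusterModel:
    """Water statistics for one region: presence probability and capacity."""

    presence_prob: float
    capacity_dist: dict[int, float]
    placement_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    placement_radius: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValidationError(
                f"presence probability must be in [0, 1], got {self.presence_prob}"
            )
        total = sum(self.capacity_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"capacity distribution must sum to 1, got {total}"
            )
        if any(k < 0 for k in self.capacity_dist):
            raise ValidationError("capacity support must be nonnegative")
        if self.placement_radius <= 0:
            raise ValidationError("placement radius must be positive")

    def k_max(self) -> int:
        return max(self.capacity_dist)


@dataclass
class SpModel:
    """Stable-spatial-mode model for one tracked side-chain terminal atom."""

    atom_name: str
    mode_centers: np.ndarray  # k x 3
    mode_weights: np.ndarray
    switch_prob: float = 0.04
    sigma: float = 0.25

    def __post_init__(self):
        self.mode_centers = np.asarray(self.mode_centers, dtype=float)
        self.mode_weights = np.asarray(self.mode_weights, dtype=float)
        if abs(self.mode_weights.sum() - 1.0) > 1e-9:
            raise ValidationError("mode weights must sum to 1")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValidationError("switch probability must be in [0, 1]")
        k = len(self.mode_centers)
        for i in range(k):
            for j in range(i + 1, k):
                d = np.linalg.norm(self.mode_centers[i] - self.mode_centers[j])
                if d < 2.0:
                    raise ValidationError(
                        f"mode centers {i} and {j} are {d:.2f} A apart; "
                        "need >= 2 A separation"
                    )


@dataclass
class ToySystemSpec:
    """Complete description of one synthetic half-channel system."""

    label: str
    site_layout: list[PolarSite]
    cluster_models: dict[str, ClusterModel]
    sp_models: dict[tuple[str, int], SpModel] = field(default_factory=dict)
    backbone_jitter: float = 0.15
    n_frames: int = 600
    frame_interval_ps: float = 2.0
    seed: int = 0
    source_selection: str = "chain A and resid 119 and polar"
    sink_selection: str = "chain C and resid 61 and polar"

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.frame_interval_ps <= 0:
            raise ValidationError("frame_interval_ps must be positive")
        if self.backbone_jitter < 0:
            raise ValidationError("backbone jitter must be nonnegative")


@dataclass
class GroundTruth:
    """Generator-side truth: counts, mode labels, connectivity per frame."""

    region_counts: dict[str, np.ndarray]
    sp_labels: dict[tuple[str, int], np.ndarray]
    connectivity: np.ndarray

    def occupancy_pct(self, region: str) -> float:
        counts = self.region_counts[region]
        return 100.0 * float(np.count_nonzero(counts >= 1)) / len(counts)


# ---------------------------------------------------------------------------
# Water schedules


def generate_water_schedule(
    p: float,
    capacity_dist: dict[int, float],
    n_frames: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-frame water counts: zero with probability 1-p, else >= 1 from the
    capacity distribution restricted to its nonzero support."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"presence probability must be in [0, 1], got {p}")
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    total = sum(capacity_dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"capacity distribution must sum to 1, got {total}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    support = sorted(k for k in capacity_dist if k >= 1)
    if support:
        probs = np.array([capacity_dist[k] for k in support], dtype=float)
        probs = probs / probs.sum()
    present = rng.random(n_frames) < p
    counts = np.zeros(n_frames, dtype=int)
    if support and present.any():
        draws = rng.choice(support, size=int(present.sum()), p=probs)
        counts[present] = draws
    return counts


# ---------------------------------------------------------------------------
# Topology assembly


def _element_of(atom_name: str) -> str:
    return next((c for c in atom_name if c.isalpha()), "C").upper()


def build_topology(spec: ToySystemSpec):
    """Topology, template coordinates, and per-atom bookkeeping for a spec.

    Returns ``(topology, template, jitter_sigma, sp_atom_index,
    water_indices_by_region)``.  Template coordinates hold side-chain site
    positions, backbone positions, and parked water positions; the per-frame
    generator perturbs them.
    """
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    sigmas: list[float] = []
    serial = 1
    sp_atom_index: dict[tuple[str, int], int] = {}
    for site in spec.site_layout:
        for name in ("N", "CA", "C", "O"):
            pos = np.asarray(site.ca_position) + _BACKBONE_TEMPLATE[name]
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=_element_of(name),
                    res_name=site.res_name,
                    res_seq=site.res_seq,
                    chain_id=site.chain_id,
                    role=assign_role(site.res_name, name),
                )
            )
            coords.append(pos)
            sigmas.append(spec.backbone_jitter)
            serial += 1
        for name, pos in site.sidechain_atoms:
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=_element_of(name),
                    res_name=site.res_name,
                    res_seq=site.res_seq,
                    chain_id=site.chain_id,
                    role=assign_role(site.res_name, name),
                )
            )
            coords.append(np.asarray(pos, dtype=float))
            sigmas.append(0.0)  # chain-link geometry stays exact
            key = (site.chain_id, site.res_seq)
            if key in spec.sp_models and spec.sp_models[key].atom_name == name:
                sp_atom_index[key] = len(atoms) - 1
            serial += 1

    for key, model in spec.sp_models.items():
        if key not in sp_atom_index:
            raise ValidationError(
                f"SP model for {key} names atom {model.atom_name!r} absent from "
                "the site layout"
            )

    water_indices_by_region: dict[str, list[int]] = {}
    water_counter = 0
    res_seq = 1001
    for region_name, model in spec.cluster_models.items():
        idx_list = []
        for _ in range(model.k_max()):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name="O",
                    element="O",
                    res_name="HOH",
                    res_seq=res_seq,
                    chain_id="W",
                    role=assign_role("HOH", "O"),
                )
            )
            coords.append(_PARK_BASE + np.array([_PARK_SPACING * water_counter, 0, 0]))
            sigmas.append(0.0)
            idx_list.append(len(atoms) - 1)
            serial += 1
            res_seq += 1
            water_counter += 1
        water_indices_by_region[region_name] = idx_list

    names = list(spec.cluster_models)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = spec.cluster_models[names[i]], spec.cluster_models[names[j]]
            d = np.linalg.norm(a.placement_center - b.placement_center)
            if d < a.placement_radius + b.placement_radius:
                warnings.warn(
                    f"regions {names[i]!r} and {names[j]!r} overlap "
                    f"(centers {d:.2f} A apart)",
                    stacklevel=2,
                )

    return (
        Topology(atoms),
        np.array(coords, dtype=float),
        np.array(sigmas, dtype=float),
        sp_atom_index,
        water_indices_by_region,
    )


def _uniform_in_sphere(rng: np.random.Generator, center, radius: float, n: int):
    directions = rng.normal(size=(n, 3))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    radii = radius * rng.random(n) ** (1.0 / 3.0)
    return np.asarray(center) + directions / norms * radii[:, None]


# ---------------------------------------------------------------------------
# Independent connectivity oracle


def _exhaustive_connected(
    coords: np.ndarray,
    topology: Topology,
    active: np.ndarray,
    source: np.ndarray,
    sink: np.ndarray,
    cutoff: float = HBOND_CUTOFF,
) -> bool:
    """Depth-first exhaustive path search over the generated geometry.

    Deliberately independent of the graph analyzer: adjacency is evaluated
    on the fly with plain pairwise distances and the same chemical rule
    (donor-capable against acceptor-capable, different residues).
    """
    nodes = [i for i in np.nonzero(active)[0]]
    node_set = set(nodes)
    sink_set = set(int(i) for i in sink)

    def linked(i: int, j: int) -> bool:
        a, b = topology.atoms[i], topology.atoms[j]
        if (a.chain_id, a.res_seq) == (b.chain_id, b.res_seq):
            return False
        if np.linalg.norm(coords[i] - coords[j]) > cutoff:
            return False
        return (is_donor_capable(a.role) and is_acceptor_capable(b.role)) or (
            is_donor_capable(b.role) and is_acceptor_capable(a.role)
        )

    stack = [int(i) for i in source if int(i) in node_set]
    visited = set(stack)
    while stack:
        u = stack.pop()
        if u in sink_set:
            return True
        for v in nodes:
            if v not in visited and linked(u, v):
                visited.add(v)
                stack.append(v)
    return False


# ---------------------------------------------------------------------------
# Trajectory generation


def generate_toy_trajectory(spec: ToySystemSpec):
    """Realize a spec into a :class:`Trajectory` plus its :class:`GroundTruth`.

    A single RNG stream keyed by ``spec.seed`` drives every random choice, so
    identical specs produce bitwise-identical trajectories.
    """
    topology, template, sigmas, sp_atom_index, waters_by_region = build_topology(spec)
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames

    schedules = {
        name: generate_water_schedule(
            model.presence_prob, model.capacity_dist, n_frames, rng
        )
        for name, model in spec.cluster_models.items()
    }

    sp_labels: dict[tuple[str, int], np.ndarray] = {}
    for key, model in spec.sp_models.items():
        k = len(model.mode_centers)
        labels = np.empty(n_frames, dtype=int)
        mode = int(rng.choice(k, p=model.mode_weights))
        for f in range(n_frames):
            if f > 0 and rng.random() < model.switch_prob:
                mode = int(rng.choice(k, p=model.mode_weights))
            labels[f] = mode
        sp_labels[key] = labels

    jitter_idx = np.nonzero(sigmas > 0)[0]
    coords = np.empty((n_frames, len(template), 3))
    for f in range(n_frames):
        frame = template.copy()
        if len(jitter_idx):
            frame[jitter_idx] += (
                rng.normal(size=(len(jitter_idx), 3)) * sigmas[jitter_idx, None]
            )
        for key, model in spec.sp_models.items():
            idx = sp_atom_index[key]
            center = model.mode_centers[sp_labels[key][f]]
            frame[idx] = center + rng.normal(size=3) * model.sigma
        for name, model in spec.cluster_models.items():
            count = int(schedules[name][f])
            if count:
                placed = _uniform_in_sphere(
                    rng, model.placement_center, model.placement_radius, count
                )
                for w, wi in enumerate(waters_by_region[name][:count]):
                    frame[wi] = placed[w]
        coords[f] = frame

    source = topology.select(spec.source_selection)
    sink = topology.select(spec.sink_selection)
    connectivity = np.zeros(n_frames, dtype=bool)
    active = np.array([a.role != "none" for a in topology.atoms])
    water_owner = {
        wi: name for name, idxs in waters_by_region.items() for wi in idxs
    }
    for f in range(n_frames):
        frame_active = active.copy()
        for name, idxs in waters_by_region.items():
            count = int(schedules[name][f])
            for pos, wi in enumerate(idxs):
                if pos >= count:
                    frame_active[wi] = False
        connectivity[f] = _exhaustive_connected(
            coords[f], topology, frame_active, source, sink
        )

    truth = GroundTruth(
        region_counts={name: schedules[name].copy() for name in schedules},
        sp_labels=sp_labels,
        connectivity=connectivity,
    )
    traj = Trajectory(topology, coords, frame_interval_ps=spec.frame_interval_ps)
    return traj, truth


# ---------------------------------------------------------------------------
# Packaged per-mutant fixtures


def _wt_sites() -> list[PolarSite]:
    def bb(x, y=0.0, dy=2.0):
        return np.array([x, y + dy, 0.0])

    return [
        PolarSite("A", 219, "GLU", [("OE1", np.array([_X_E219, 0.0, 0.0]))],
                  bb(_X_E219)),
        PolarSite("A", 119, "ASP", [("OD1", np.array([_X_D119, 0.0, 0.0]))],
                  bb(_X_D119)),
        PolarSite("A", 140, "ARG", [("NH1", np.array([_X_D119, -2.5, 0.0]))],
                  np.array([_X_D119, -4.5, 0.0])),
        PolarSite("A", 245, "HIS", [("NE2", np.array([_X_H245, 0.0, 0.0]))],
                  bb(_X_H245)),
        PolarSite(
            "A",
            214,
            "ASN",
            [
                ("OD1", np.array([_X_N214, 0.0, 0.0])),
                ("ND2", np.array([9.0, 1.2, 1.0])),
            ],
            bb(_X_N214),
        ),
        PolarSite("A", 252, "GLN", [("OE1", np.array([_X_N214, 2.9, 0.0]))],
                  np.array([_X_N214, 4.9, 0.0])),
        PolarSite("C", 61, "ASP", [("OD1", np.array([_X_D61, 0.0, 0.0]))],
                  bb(_X_D61)),
    ]


_N214_SP_MODEL = dict(
    mode_centers=np.array([[9.0, 1.2, 1.0], [10.8, 1.8, 1.8], [12.6, 1.2, 1.0]]),
    mode_weights=np.array([0.40, 0.35, 0.25]),
    switch_prob=0.04,
    sigma=0.25,
)

_R140_SP_MODEL = dict(
    mode_centers=np.array([[_X_D119, -2.5, 0.0], [_X_D119, -4.5, 0.0]]),
    mode_weights=np.array([0.90, 0.10]),
    switch_prob=0.05,
    sigma=0.15,
)

# per-fixture hydration parameters; printed occupancies used where the study
# reports them (WT 92%, aH245G 44%, aN214L 36%), qualitative encodings
# elsewhere.
_FIXTURE_HYDRATION: dict[str, dict] = {
    "WT": dict(w1_p=0.92, w1_cap={1: 0.50, 2: 0.35, 3: 0.15},
               w23_p=0.85, w23_cap={1: 0.60, 2: 0.40}),
    "aE219G": dict(w1_p=0.80, w1_cap={1: 0.50, 2: 0.35, 3: 0.15},
                   w23_p=0.85, w23_cap={1: 0.50, 2: 0.40, 3: 0.10}),
    "aE219Q": dict(w1_p=0.78, w1_cap={1: 0.50, 2: 0.35, 3: 0.15},
                   w23_p=0.85, w23_cap={1: 0.50, 2: 0.40, 3: 0.10}),
    "aH245G": dict(w1_p=0.44, w1_cap={1: 0.40, 2: 0.35, 3: 0.25},
                   w23_p=0.0, w23_cap={1: 1.0}),
    "aH245S": dict(w1_p=0.92, w1_cap={1: 0.50, 2: 0.35, 3: 0.15},
                   w23_p=0.95, w23_cap={2: 0.50, 3: 0.50}),
    "aH245Y": dict(w1_p=0.0, w1_cap={1: 1.0},
                   w23_p=0.85, w23_cap={1: 0.60, 2: 0.40}),
    "aE219H/aH245E": dict(w1_p=0.96, w1_cap={1: 0.35, 2: 0.40, 3: 0.25},
                          w23_p=0.92, w23_cap={1: 0.40, 2: 0.45, 3: 0.15}),
    "aN214L": dict(w1_p=0.36, w1_cap={1: 1.0},
                   w23_p=0.85, w23_cap={1: 0.60, 2: 0.40}),
    "aN214H": dict(w1_p=0.90, w1_cap={1: 0.70, 2: 0.30},
                   w23_p=0.85, w23_cap={1: 0.60, 2: 0.40}),
    "aQ252L": dict(w1_p=0.92, w1_cap={1: 0.50, 2: 0.35, 3: 0.15},
                   w23_p=0.95, w23_cap={1: 0.20, 2: 0.35, 3: 0.30, 4: 0.15}),
}

_FIXTURE_SUBSTITUTIONS: dict[str, list[tuple[str, int, str, str]]] = {
    "WT": [],
    "aE219G": [("A", 219, "GLU", "GLY")],
    "aE219Q": [("A", 219, "GLU", "GLN")],
    "aH245G": [("A", 245, "HIS", "GLY")],
    "aH245S": [("A", 245, "HIS", "SER")],
    "aH245Y": [("A", 245, "HIS", "TYR")],
    "aE219H/aH245E": [("A", 219, "GLU", "HIS"), ("A", 245, "HIS", "GLU")],
    "aN214L": [("A", 214, "ASN", "LEU")],
    "aN214H": [("A", 214, "ASN", "HIS")],
    "aQ252L": [("A", 252, "GLN", "LEU")],
}

FIXTURE_LABELS = tuple(_FIXTURE_SUBSTITUTIONS)

# replacement side-chain atoms by (residue number, new residue name)
_MUTANT_SIDECHAINS: dict[tuple[int, str], list[tuple[str, float | None]]] = {
    (219, "GLY"): [],
    (219, "GLN"): [("OE1", None)],  # None -> keep the wild-type site position
    (219, "HIS"): [("NE2", None)],
    (245, "GLY"): [],
    (245, "SER"): [("OG", None)],
    (245, "TYR"): [("OH", None)],
    (245, "GLU"): [("OE1", None)],
    (214, "LEU"): [],
    (214, "HIS"): [("NE2", None)],
    (252, "LEU"): [],
}


def _apply_substitutions(
    sites: list[PolarSite], substitutions
) -> list[PolarSite]:
    out = []
    subs = {(c, r): t for (c, r, _f, t) in substitutions}
    for site in sites:
        key = (site.chain_id, site.res_seq)
        if key not in subs:
            out.append(site)
            continue
        new_res = subs[key]
        spec_atoms = _MUTANT_SIDECHAINS.get((site.res_seq, new_res))
        if spec_atoms is None:
            raise ValidationError(
                f"no side-chain template for {site.res_seq}->{new_res}"
            )
        anchor = site.sidechain_atoms[0][1] if site.sidechain_atoms else None
        new_atoms = [
            (name, np.array(anchor) if pos is None else np.asarray(pos))
            for name, pos in spec_atoms
        ]
        out.append(
            PolarSite(site.chain_id, site.res_seq, new_res, new_atoms,
                      site.ca_position)
        )
    return out


def make_fixture_spec(
    label: str, n_frames: int = 600, seed: int = 11
) -> ToySystemSpec:
    """The synthetic system spec for one named scenario fixture."""
    if label not in _FIXTURE_HYDRATION:
        raise ValidationError(f"unknown fixture label {label!r}")
    params = _FIXTURE_HYDRATION[label]
    substitutions = _FIXTURE_SUBSTITUTIONS[label]
    sites = _apply_substitutions(_wt_sites(), substitutions)

    cluster_models = {
        "W2/W3": ClusterModel(
            presence_prob=params["w23_p"],
            capacity_dist=params["w23_cap"],
            placement_center=np.array([_X_W23, 0.0, 0.0]),
        ),
        "W1": ClusterModel(
            presence_prob=params["w1_p"],
            capacity_dist=params["w1_cap"],
            placement_center=np.array([_X_W1, 0.0, 0.0]),
        ),
    }
    sp_models = {("A", 140): SpModel(atom_name="NH1", **_R140_SP_MODEL)}
    res214 = next(s for s in sites if (s.chain_id, s.res_seq) == ("A", 214))
    if any(name == "ND2" for name, _ in res214.sidechain_atoms):
        sp_models[("A", 214)] = SpModel(atom_name="ND2", **_N214_SP_MODEL)

    offset = sorted(_FIXTURE_HYDRATION).index(label)
    return ToySystemSpec(
        label=label,
        site_layout=sites,
        cluster_models=cluster_models,
        sp_models=sp_models,
        n_frames=n_frames,
        seed=seed + offset,
    )


def make_paper_scenario_fixtures(
    n_frames: int = 600, seed: int = 11
) -> dict[str, ToySystemSpec]:
    """All ten fixture specs (wild type plus nine substitutions)."""
    return {
        label: make_fixture_spec(label, n_frames=n_frames, seed=seed)
        for label in FIXTURE_LABELS
    }


def scenario_for_fixture(label: str) -> ScenarioSpec:
    """The analysis scenario matching a fixture's geometry and naming."""
    if label not in _FIXTURE_SUBSTITUTIONS:
        raise ValidationError(f"unknown fixture label {label!r}")
    data = {
        "label": label,
        "source_selection": "chain A and resid 119 and polar",
        "sink_selection": "chain C and resid 61 and polar",
        "substitutions": [
            {"chain": c, "res_seq": r, "from_res": f, "to_res": t}
            for (c, r, f, t) in _FIXTURE_SUBSTITUTIONS[label]
        ],
        "regions": [
            {
                "name": "W1",
                "anchor_a": "chain C and resid 61 and name CA",
                "anchor_b": "chain A and resid 214 and name CA",
                "radius": 3.5,
            },
            {
                "name": "W2/W3",
                "anchor_a": "chain A and resid 245 and name CA",
                "anchor_b": "chain A and resid 214 and name CA",
                "radius": 3.5,
            },
        ],
        "gate_residues": [
            {"chain": "A", "res_seq": 140},
            {"chain": "A", "res_seq": 119},
            {"chain": "A", "res_seq": 219},
            {"chain": "A", "res_seq": 245},
        ],
        "md_metadata": {
            "temperature_K": 310,
            "pressure_bar": 1,
            "ensemble": "NPT",
            "engine": "NAMD 2.14",
            "force_field": "CHARMM36",
            "production_ns": 150,
            "frame_interval_ps": 2,
            "note": "simulation parameters recorded as metadata only",
        },
    }
    return scenario_from_dict(data)
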