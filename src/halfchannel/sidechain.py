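"""Side-chain stable spatial positions (SP), gate contacts, Ca-Ca distances.

A tracked side chain's terminal-atom centroid, expressed in a local frame
obtained by superposing the surrounding backbone (the residue's own helix
segment, +/- 4 residues) onto a reference, is clustered into a small number
of recurrent spatial modes.  These modes are the residue's stable spatial
positions SP1..SPk; up to three are allowed by default.  The number of
states is selected by silhouette score; frames far from every state center
remain unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import BACKBONE_NAMES, Trajectory
from .errors import (
    InsufficientFramesError,
    SelectionError,
    StructureError,
    ValidationError,
)
from .stability import apply_transform, superpose

#: Minimum silhouette for accepting a multi-state split over a single state.
SILHOUETTE_MIN = 0.5

#: Unassigned cutoff, as a multiple of the within-state RMS spread.
UNASSIGNED_SPREAD_FACTOR = 2.0


@dataclass
class SpAssignment:
    """Per-frame SP state labels and state occupancies for one residue."""

    residue: tuple[str, int]
    labels: np.ndarray  # per-frame state index, -1 = unassigned
    centers: np.ndarray  # k x 3, Angstrom, ordered by first appearance
    occupancy_pct: np.ndarray  # per state, percent of frames
    unassigned_pct: float

    @property
    def n_states(self) -> int:
        return len(self.centers)

    def to_dict(self) -> dict:
        return {
            "residue": {"chain": self.residue[0], "res_seq": self.residue[1]},
            "n_states": self.n_states,
            "occupancy_pct": [round(float(o), 2) for o in self.occupancy_pct],
            "unassigned_pct": round(float(self.unassigned_pct), 2),
            "centers": [[round(float(x), 3) for x in c] for c in self.centers],
        }


@dataclass
class ContactStats:
    """Fraction of frames two groups come within a strict distance cutoff."""

    pair_label: str
    contact_fraction_pct: float
    cutoff: float

    def to_dict(self) -> dict:
        return {
            "pair": self.pair_label,
            "contact_fraction_pct": round(self.contact_fraction_pct, 1),
            "cutoff_A": self.cutoff,
        }


def _local_backbone_indices(traj: Trajectory, chain_id: str, res_seq: int, span: int = 4):
    top = traj.topology
    idx = []
    for rs in range(res_seq - span, res_seq + span + 1):
        key = (chain_id, rs)
        if key in top.residues:
            idx.extend(
                i for i in top.residues[key] if top.atoms[i].name in BACKBONE_NAMES
            )
    if len(idx) < 3:
        raise StructureError(
            f"not enough local backbone atoms around {chain_id}:{res_seq}"
        )
    return np.array(sorted(idx), dtype=int)


def sp_features(
    traj: Trajectory,
    chain_id: str,
    res_seq: int,
    terminal_atom_names: tuple[str, ...],
) -> np.ndarray:
    """Terminal-atom centroid per frame, in the local-backbone frame.

    Each frame is rigidly superposed on the first frame using the backbone
    of residues within +/- 4 positions, isolating side-chain motion from
    helix drift.
    """
    top = traj.topology
    res_atoms = top.residue_atoms(chain_id, res_seq)
    term = [i for i in res_atoms if top.atoms[i].name in terminal_atom_names]
    if not term:
        raise SelectionError(
            f"terminal atoms {terminal_atom_names} not found in "
            f"{chain_id}:{res_seq}"
        )
    term = np.array(term, dtype=int)
    backbone = _local_backbone_indices(traj, chain_id, res_seq)
    reference = traj.coordinates[0]
    feats = np.empty((traj.n_frames, 3))
    for f in range(traj.n_frames):
        rot, tr, _ = superpose(traj.coordinates[f], reference, backbone)
        centroid = traj.coordinates[f][term].mean(axis=0)
        feats[f] = apply_transform(centroid, rot, tr)
    return feats


def _order_by_first_appearance(labels: np.ndarray, k: int) -> np.ndarray:
    """Relabeling map: cluster id -> rank of its first frame of appearance."""
    first = np.full(k, np.iinfo(np.int64).max, dtype=np.int64)
    for f, lbl in enumerate(labels):
        if first[lbl] == np.iinfo(np.int64).max:
            first[lbl] = f
    order = np.argsort(first, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap


def classify_sp(
    traj: Trajectory,
    chain_id: str,
    res_seq: int,
    terminal_atom_names: tuple[str, ...],
    k_max: int = 3,
    seed: int = 0,
) -> SpAssignment:
    """Cluster a side chain's terminal-atom positions into SP states.

    k is chosen over 1..k_max by silhouette score (a split must score at
    least ``SILHOUETTE_MIN`` to beat the single-state model).  States are
    numbered by first appearance; frames farther than twice the within-state
    RMS spread from every center are left unassigned.
    """
    if traj.n_frames < 10:
        raise InsufficientFramesError("SP classification needs >= 10 frames")
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    feats = sp_features(traj, chain_id, res_seq, terminal_atom_names)

    best_k, best_labels, best_centers = 1, np.zeros(len(feats), dtype=int), feats.mean(
        axis=0, keepdims=True
    )
    best_score = -np.inf
    n_unique = len(np.unique(feats.round(6), axis=0))
    for k in range(2, k_max + 1):
        if k > n_unique:
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(feats)
        if len(np.unique(labels)) < k:
            continue
        score = silhouette_score(feats, labels)
        if score > best_score:
            best_score = score
            best_k, best_labels, best_centers = k, labels, km.cluster_centers_
    if best_score < SILHOUETTE_MIN:
        best_k = 1
        best_labels = np.zeros(len(feats), dtype=int)
        best_centers = feats.mean(axis=0, keepdims=True)

    remap = _order_by_first_appearance(best_labels, best_k)
    labels = remap[best_labels]
    centers = np.empty_like(best_centers)
    centers[remap] = best_centers

    # unassigned: farther than a spread-scaled cutoff from every center
    dists = np.linalg.norm(feats[:, None, :] - centers[None, :, :], axis=2)
    spread = np.empty(best_k)
    for s in range(best_k):
        member = dists[labels == s, s]
        spread[s] = np.sqrt(np.mean(member**2)) if len(member) else 0.0
    cutoffs = np.where(spread > 0, UNASSIGNED_SPREAD_FACTOR * spread, np.inf)
    assigned = (dists <= cutoffs[None, :]).any(axis=1)
    final = np.where(assigned, labels, -1)

    n = len(final)
    occ = np.array(
        [100.0 * float(np.count_nonzero(final == s)) / n for s in range(best_k)]
    )
    return SpAssignment(
        residue=(chain_id, res_seq),
        labels=final,
        centers=centers,
        occupancy_pct=occ,
        unassigned_pct=100.0 - float(occ.sum()),
    )


def contact_fraction(
    traj: Trajectory,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    cutoff: float = 3.0,
    pair_label: str = "",
) -> ContactStats:
    """Percent of frames with minimum cross-pair distance strictly below cutoff."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValidationError("both selections must be non-empty")
    a = traj.coordinates[:, sel_a, :]
    b = traj.coordinates[:, sel_b, :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=3)
    mins = d.reshape(traj.n_frames, -1).min(axis=1)
    frac = 100.0 * float(np.count_nonzero(mins < cutoff)) / traj.n_frames
    return ContactStats(
        pair_label=pair_label, contact_fraction_pct=frac, cutoff=cutoff
    )


def ca_distance_pdf(
    traj: Trajectory,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    bin_width: float = 0.2,
):
    """Probability density of the Ca-Ca distance between two residues.

    Returns ``(bin_edges, density, distances)``; the density integrates to 1
    over the bins.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    top = traj.topology

    def ca_index(res):
        chain_id, res_seq = res
        atoms = top.residue_atoms(chain_id, res_seq)
        for i in atoms:
            if top.atoms[i].name == "CA":
                return i
        raise StructureError(f"residue {chain_id}:{res_seq} has no CA atom")

    ia, ib = ca_index(res_a), ca_index(res_b)
    d = np.linalg.norm(
        traj.coordinates[:, ia, :] - traj.coordinates[:, ib, :], axis=1
    )
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    density, edges = np.histogram(d, bins=edges, density=True)
    return edges, density, d
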