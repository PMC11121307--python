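"""Conformational-stability battery: RMSD, RMSF, RG, SASA, H-bond counts.

Superposition uses the Kabsch algorithm (SVD with reflection correction);
RMSD series are referenced to the first frame; RMSF is the fluctuation about
the time-mean structure after a two-pass superposition.  SASA is computed
with the Shrake-Rupley rotation-free quadrature: a deterministic
golden-spiral point set on each solvent-extended sphere, points removed when
buried inside a neighbor's extended sphere.

The packaged stability table (one row per system: wild type plus nine
a-subunit mutants, columns RMSD/RG/SASA/Hbond plus an imported
structure-prediction RMSD) ships with the package and is summarized with
``summarize_stability_table``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .chain import HBondCriteria
from .core import Topology, Trajectory, is_acceptor_capable, is_donor_capable
from .core import ROLE_WATER_OXYGEN
from .errors import (
    DegenerateGeometryError,
    InsufficientFramesError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Superposition and RMSD


def superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None
):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference over the
    selected atoms.  The rotation is proper (det = +1, Kabsch reflection
    correction).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.arange(len(mobile))
    selection = np.asarray(selection, dtype=int)
    if len(selection) < 3:
        raise ValidationError("superposition needs a selection of >= 3 atoms")
    m = mobile[selection]
    r = reference[selection]
    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    m0 = m - mc
    r0 = r - rc
    # collinearity check: centered points must span a plane
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        raise DegenerateGeometryError(
            "selection is collinear or coincident; superposition is ill-posed"
        )
    h = m0.T @ r0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = rc - rotation @ mc
    fitted = m @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray):
    return coords @ rotation.T + translation


def rmsd_series(traj: Trajectory, selection: np.ndarray):
    """Per-frame RMSD (Angstrom) to frame 0 after superposition, and its mean."""
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValidationError("empty selection for RMSD")
    reference = traj.coordinates[0]
    values = np.empty(traj.n_frames)
    values[0] = 0.0  # frame 0 is the reference by definition
    for f in range(1, traj.n_frames):
        _, _, values[f] = superpose(traj.coordinates[f], reference, selection)
    return values, float(values.mean())


@dataclass
class RmsfProfile:
    """Per-residue fluctuation (Angstrom), keyed by residue number."""

    res_seqs: np.ndarray
    rmsf: np.ndarray

    def mean(self) -> float:
        return float(self.rmsf.mean())

    def as_rows(self) -> list[dict]:
        return [
            {"res_seq": int(r), "rmsf_A": float(v)}
            for r, v in zip(self.res_seqs, self.rmsf)
        ]


def rmsf_profile(traj: Trajectory, selection: np.ndarray) -> RmsfProfile:
    """Per-residue RMSF about the time-mean structure (two-pass superposition).

    Pass 1 aligns every frame to frame 0 and forms the mean structure; pass 2
    re-aligns every frame to that mean and accumulates squared deviations.
    Per-atom mean-square fluctuations are averaged within each residue before
    the square root, so the profile is one value per selected residue.
    """
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValidationError("empty selection for RMSF")
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")

    def aligned_to(target):
        out = np.empty((traj.n_frames, len(selection), 3))
        for f in range(traj.n_frames):
            rot, tr, _ = superpose(traj.coordinates[f], target, selection)
            out[f] = apply_transform(traj.coordinates[f][selection], rot, tr)
        return out

    # seed the mean structure from frame 0, then refine it twice so the
    # profile is (numerically) independent of which frame came first
    aligned = aligned_to(traj.coordinates[0])
    mean_structure = np.array(traj.coordinates[0])
    for _ in range(2):
        mean_structure[selection] = aligned.mean(axis=0)
        aligned = aligned_to(mean_structure)
    mean_final = aligned.mean(axis=0)
    msf_atom = np.mean(np.sum((aligned - mean_final) ** 2, axis=2), axis=0)

    res_keys = [
        (traj.topology.atoms[i].chain_id, traj.topology.atoms[i].res_seq)
        for i in selection
    ]
    order: list[tuple[str, int]] = []
    groups: dict[tuple[str, int], list[int]] = {}
    for j, key in enumerate(res_keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(j)
    res_seqs = np.array([k[1] for k in order])
    rmsf = np.array([np.sqrt(np.mean(msf_atom[groups[k]])) for k in order])
    return RmsfProfile(res_seqs=res_seqs, rmsf=rmsf)


# ---------------------------------------------------------------------------
# Radius of gyration and SASA


def radius_of_gyration(
    frame: np.ndarray, selection: np.ndarray, masses: np.ndarray
) -> float:
    """Mass-weighted RMS distance from the center of mass (Angstrom)."""
    selection = np.asarray(selection, dtype=int)
    masses = np.asarray(masses, dtype=float)
    if len(selection) != len(masses):
        raise ValidationError("selection and masses lengths differ")
    total = masses.sum()
    if total <= 0:
        raise ValidationError("total mass must be positive")
    pts = np.asarray(frame, dtype=float)[selection]
    com = (masses[:, None] * pts).sum(axis=0) / total
    sq = np.sum((pts - com) ** 2, axis=1)
    return float(np.sqrt((masses * sq).sum() / total))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    frame: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
):
    """Shrake-Rupley solvent-accessible surface area.

    Returns ``(per_atom, total)`` in Angstrom^2.  Each atom's extended sphere
    (vdW radius + probe) is sampled with ``n_points`` golden-spiral points; a
    point is accessible when outside every neighbor's extended sphere, and
    the atom's area is the accessible fraction times the sphere area.
    """
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius <= 0:
        raise ValidationError("probe radius must be positive")
    if np.any(radii <= 0):
        raise ValidationError("all atomic radii must be positive")
    if n_points < 96:
        raise ValidationError("n_points must be >= 96 for usable quadrature")
    n = len(frame)
    ext = radii + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(frame)
    per_atom = np.empty(n)
    max_ext = ext.max()
    for i in range(n):
        pts = frame[i] + ext[i] * unit
        neighbors = [
            j for j in tree.query_ball_point(frame[i], ext[i] + max_ext) if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - frame[j], axis=1)
            buried = d < ext[j] - 1e-9
            if j < i:
                # boundary contact (degenerate coincident spheres) is
                # attributed to the lower-index atom, deterministically
                buried |= np.abs(d - ext[j]) <= 1e-9
            accessible &= ~buried
        per_atom[i] = accessible.mean() * 4.0 * np.pi * ext[i] ** 2
    return per_atom, float(per_atom.sum())


# ---------------------------------------------------------------------------
# Intramolecular hydrogen bonds


def count_intramolecular_hbonds(
    frame: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
) -> int:
    """Protein-protein donor/acceptor pairs within the distance cutoff.

    Counts unordered heavy-atom pairs where one side is donor-capable and the
    other acceptor-capable, excluding water and pairs within one residue.
    """
    idx = [
        i
        for i, a in enumerate(topology.atoms)
        if a.role not in ("none", ROLE_WATER_OXYGEN)
    ]
    if len(idx) < 2:
        return 0
    pts = np.asarray(frame, dtype=float)[idx]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(criteria.max_heavy_distance, output_type="ndarray")
    count = 0
    for a_loc, b_loc in pairs:
        a = topology.atoms[idx[a_loc]]
        b = topology.atoms[idx[b_loc]]
        if (a.chain_id, a.res_seq) == (b.chain_id, b.res_seq):
            continue
        ok = (is_donor_capable(a.role) and is_acceptor_capable(b.role)) or (
            is_donor_capable(b.role) and is_acceptor_capable(a.role)
        )
        if ok:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Stability table summarization


@dataclass
class StabilityRow:
    """One system's stability metrics (averages over its production run)."""

    label: str
    rmsd_A: float
    rg_A: float
    sasa_1e4_A2: float
    n_hbond: int
    rmsd_alphafold_A: float | None = None

    def __post_init__(self):
        for name in ("rmsd_A", "rg_A", "sasa_1e4_A2", "n_hbond"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be nonnegative, got {v}")


_METRICS = ("rmsd_A", "rg_A", "sasa_1e4_A2", "n_hbond", "rmsd_alphafold_A")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching printed-table conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_stability_table(
    rows: list[StabilityRow],
    wt_label: str = "WT",
    printed_precision: int | None = None,
) -> dict:
    """Mean/min/max of every metric, overall and mutants-only.

    The ``mutants_only`` subgroup excludes the wild-type row.  With
    ``printed_precision`` set, means are rounded half-up to that many
    decimals (printed-table style); min/max are reported as stored.
    """
    if not rows:
        raise ValidationError("stability table is empty")
    labels = [r.label for r in rows]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate labels in stability table")

    def stats(group: list[StabilityRow]) -> dict:
        out: dict = {"n": len(group)}
        for metric in _METRICS:
            values = [getattr(r, metric) for r in group if getattr(r, metric) is not None]
            if not values:
                out[metric] = None
                continue
            mean = float(np.mean(values))
            if printed_precision is not None:
                mean = round_half_up(mean, printed_precision)
            out[metric] = {
                "mean": mean,
                "min": float(min(values)),
                "max": float(max(values)),
            }
        return out

    mutants = [r for r in rows if r.label != wt_label]
    summary = {"overall": stats(rows)}
    summary["mutants_only"] = stats(mutants) if mutants else None
    return summary


def load_packaged_stability_table() -> list[StabilityRow]:
    """The stability table fixture shipped with the package (10 systems)."""
    ref = resources.files("halfchannel.data") / "stability_table.csv"
    with ref.open(newline="") as fh:
        rows = []
        for rec in csv.DictReader(fh):
            rows.append(
                StabilityRow(
                    label=rec["label"],
                    rmsd_A=float(rec["rmsd_A"]),
                    rg_A=float(rec["rg_A"]),
                    sasa_1e4_A2=float(rec["sasa_1e4_A2"]),
                    n_hbond=int(rec["n_hbond"]),
                    rmsd_alphafold_A=float(rec["rmsd_alphafold_A"]),
                )
            )
    return rows
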