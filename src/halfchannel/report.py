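"""Scenario orchestration: run the full analysis stack and compare mutants.

``run_scenario`` executes the stability battery, cluster hydration
statistics, transfer-chain verdict, side-chain state classification and gate
contacts for one system and bundles them, with provenance, into a
:class:`ScenarioReport`.  ``compare_report`` lines up several reports into
the per-mutant comparison table and the verdict matrix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .chain import (
    DEFAULT_CORRIDOR_RADIUS,
    DEFAULT_INTERRUPTION_THRESHOLD_PCT,
    ChainVerdict,
    HBondCriteria,
    connectivity_fraction,
)
from .core import BACKBONE_NAMES, Trajectory
from .errors import HalfChannelError, ValidationError
from .hydration import ABSENCE_THRESHOLD_PCT, cluster_stats
from .io import ScenarioSpec
from .sidechain import classify_sp, contact_fraction
from .stability import (
    count_intramolecular_hbonds,
    radius_of_gyration,
    rmsd_series,
    rmsf_profile,
    sasa,
)

logger = logging.getLogger("halfchannel")

#: Side-chain terminal atom names tried, in order, for SP classification.
SP_TERMINAL_CANDIDATES = ("ND2", "ND1", "NE2", "OG", "OH", "OE1", "OD1")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters shared across scenarios."""

    hbond_cutoff: float = 3.0
    region_radius: float | None = None  # override all region radii when set
    connectivity_threshold_pct: float = DEFAULT_INTERRUPTION_THRESHOLD_PCT
    corridor_radius: float = DEFAULT_CORRIDOR_RADIUS
    contact_cutoff: float = 3.0
    absence_threshold_pct: float = ABSENCE_THRESHOLD_PCT
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    sasa_stride: int = 10  # SASA is quadrature-heavy; evaluate every Nth frame
    sp_residue: tuple[str, int] = ("A", 214)
    sp_k_max: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "hbond_cutoff": self.hbond_cutoff,
            "region_radius": self.region_radius,
            "connectivity_threshold_pct": self.connectivity_threshold_pct,
            "corridor_radius": self.corridor_radius,
            "contact_cutoff": self.contact_cutoff,
            "absence_threshold_pct": self.absence_threshold_pct,
            "sasa_probe_radius": self.sasa_probe_radius,
            "sasa_n_points": self.sasa_n_points,
            "sasa_stride": self.sasa_stride,
            "sp_residue": list(self.sp_residue),
            "sp_k_max": self.sp_k_max,
            "seed": self.seed,
        }


@dataclass
class ScenarioReport:
    """All per-scenario analysis outputs plus provenance."""

    label: str
    stability: dict
    clusters: dict[str, dict]
    verdict: dict
    sp: dict | None
    contacts: list[dict]
    provenance: dict
    partial: bool = False
    failed_stages: list[str] = field(default_factory=list)
    schema_version: int = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "label": self.label,
            "stability": self.stability,
            "clusters": self.clusters,
            "verdict": self.verdict,
            "sp": self.sp,
            "contacts": self.contacts,
            "partial": self.partial,
            "failed_stages": self.failed_stages,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _provenance(scenario: ScenarioSpec, config: AnalysisConfig, traj: Trajectory):
    payload = json.dumps(
        {"scenario": scenario.to_dict(), "config": config.to_dict()},
        sort_keys=True,
    )
    return {
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_frames": traj.n_frames,
        "n_atoms": traj.n_atoms,
        "frame_interval_ps": traj.frame_interval_ps,
    }


def _residue_sidechain_selection(chain_id: str, res_seq: int) -> str:
    return f"chain {chain_id} and resid {res_seq}"


def _stability_stage(traj: Trajectory, config: AnalysisConfig) -> dict:
    top = traj.topology
    backbone = top.select("backbone")
    protein = np.array(
        [i for i, a in enumerate(top.atoms) if a.chain_id != "W"], dtype=int
    )
    _, rmsd_mean = rmsd_series(traj, backbone)
    rmsf = rmsf_profile(traj, backbone) if traj.n_frames >= 2 else None
    masses = top.masses(protein)
    rg_values = [
        radius_of_gyration(traj.coordinates[f], protein, masses)
        for f in range(traj.n_frames)
    ]
    radii = top.vdw_radii(protein)
    frames = range(0, traj.n_frames, max(config.sasa_stride, 1))
    sasa_totals = [
        sasa(
            traj.coordinates[f][protein],
            radii,
            probe_radius=config.sasa_probe_radius,
            n_points=config.sasa_n_points,
        )[1]
        for f in frames
    ]
    criteria = HBondCriteria(max_heavy_distance=config.hbond_cutoff)
    hbond_counts = [
        count_intramolecular_hbonds(traj.coordinates[f], top, criteria)
        for f in range(traj.n_frames)
    ]
    return {
        "rmsd_mean_A": round(rmsd_mean, 3),
        "rmsf_mean_A": round(rmsf.mean(), 3) if rmsf is not None else None,
        "rg_mean_A": round(float(np.mean(rg_values)), 3),
        "sasa_mean_A2": round(float(np.mean(sasa_totals)), 1),
        "hbond_mean": round(float(np.mean(hbond_counts)), 2),
    }


def _sp_stage(traj: Trajectory, scenario, config: AnalysisConfig) -> dict | None:
    chain_id, res_seq = config.sp_residue
    top = traj.topology
    if (chain_id, res_seq) not in top.residues:
        return None
    names = {top.atoms[i].name for i in top.residues[(chain_id, res_seq)]}
    terminal = tuple(n for n in SP_TERMINAL_CANDIDATES if n in names)
    if not terminal:
        return None  # nonpolar substitution: no side-chain states to track
    assignment = classify_sp(
        traj, chain_id, res_seq, terminal[:1], k_max=config.sp_k_max,
        seed=config.seed,
    )
    return assignment.to_dict()


def run_scenario(
    scenario: ScenarioSpec, traj: Trajectory, config: AnalysisConfig | None = None
) -> ScenarioReport:
    """Run every analysis stage for one scenario.

    Stage failures do not abort the run: the report is marked partial and
    names the failing stages.
    """
    config = config or AnalysisConfig()
    regions = scenario.regions
    if config.region_radius is not None:
        from dataclasses import replace

        regions = [replace(r, radius=config.region_radius) for r in regions]
        scenario = ScenarioSpec(
            label=scenario.label,
            source_selection=scenario.source_selection,
            sink_selection=scenario.sink_selection,
            substitutions=scenario.substitutions,
            regions=regions,
            gate_residues=scenario.gate_residues,
            canonical_chain=scenario.canonical_chain,
            md_metadata=scenario.md_metadata,
        )

    stages: dict[str, dict | None] = {}
    failed: list[str] = []

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            stages[name] = fn()
            logger.info(
                "scenario=%s stage=%s seconds=%.2f",
                scenario.label, name, time.perf_counter() - t0,
            )
        except HalfChannelError as exc:
            logger.warning("scenario=%s stage=%s failed: %s", scenario.label,
                           name, exc)
            stages[name] = None
            failed.append(name)

    run_stage("stability", lambda: _stability_stage(traj, config))
    run_stage(
        "clusters",
        lambda: {r.name: cluster_stats(traj, r).to_dict() for r in regions},
    )
    criteria = HBondCriteria(max_heavy_distance=config.hbond_cutoff)
    run_stage(
        "verdict",
        lambda: connectivity_fraction(
            traj,
            scenario,
            criteria,
            threshold_pct=config.connectivity_threshold_pct,
            corridor_radius=config.corridor_radius,
        ).to_dict(),
    )
    run_stage("sp", lambda: _sp_stage(traj, scenario, config))

    def contacts_stage():
        out = []
        top = traj.topology
        for (ca, ra), (cb, rb) in scenario.gate_contact_pairs():
            sel_a = [
                i for i in top.residues.get((ca, ra), [])
                if top.atoms[i].name not in BACKBONE_NAMES
            ]
            sel_b = [
                i for i in top.residues.get((cb, rb), [])
                if top.atoms[i].name not in BACKBONE_NAMES
            ]
            if not sel_a or not sel_b:
                continue
            st = contact_fraction(
                traj, np.array(sel_a), np.array(sel_b),
                cutoff=config.contact_cutoff,
                pair_label=f"{ca}{ra}-{cb}{rb}",
            )
            out.append(st.to_dict())
        return out

    run_stage("contacts", contacts_stage)

    return ScenarioReport(
        label=scenario.label,
        stability=stages.get("stability") or {},
        clusters=stages.get("clusters") or {},
        verdict=stages.get("verdict") or {},
        sp=stages.get("sp"),
        contacts=stages.get("contacts") or [],
        provenance=_provenance(scenario, config, traj),
        partial=bool(failed),
        failed_stages=failed,
    )


# canonical listing order for the studied systems
CANONICAL_ORDER = (
    "WT", "aE219G", "aE219Q", "aH245G", "aH245S", "aH245Y",
    "aE219H/aH245E", "aN214L", "aN214H", "aQ252L",
)


def compare_report(reports: list[ScenarioReport]) -> dict:
    """Comparison table plus verdict matrix for a set of scenario reports.

    Rows follow the canonical mutant listing where labels are recognized;
    unknown labels are appended alphabetically.
    """
    if len(reports) < 2:
        raise ValidationError("need at least two reports to compare")
    labels = [r.label for r in reports]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate report labels: {labels}")

    def sort_key(r: ScenarioReport):
        if r.label in CANONICAL_ORDER:
            return (0, CANONICAL_ORDER.index(r.label), r.label)
        return (1, 0, r.label)

    rows = []
    for r in sorted(reports, key=sort_key):
        row: dict = {
            "label": r.label,
            "verdict": r.verdict.get("verdict"),
            "connectivity_fraction_pct": r.verdict.get(
                "connectivity_fraction_pct"
            ),
        }
        absent = []
        for name in sorted(r.clusters):
            st = r.clusters[name]
            row[f"occupancy_pct[{name}]"] = st["occupancy_pct"]
            row[f"capacity_mode[{name}]"] = st["capacity_mode"]
            if st["occupancy_pct"] < ABSENCE_THRESHOLD_PCT:
                absent.append(name)
        row["clusters_absent"] = ";".join(absent)
        rows.append(row)

    verdict_matrix = {
        r.label: r.verdict.get("verdict") for r in sorted(reports, key=sort_key)
    }
    return {"rows": rows, "verdict_matrix": verdict_matrix}
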