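"""Structure/trajectory readers and writers, scenario configs, result tables.

The multi-model PDB dialect is the mandatory trajectory interchange format:
one ``MODEL``/``ENDMDL`` block per frame, identical atom lists in every
block, coordinates in Angstrom at the format's 3-decimal precision.  DCD
(CHARMM-style binary) is supported as an optional dialect through MDAnalysis.

Parsing is strict where it matters for reproducible analysis: duplicate atom
serials and insertion codes are rejected (author residue numbering is used
verbatim, so insertion codes would make residue keys ambiguous), and
alternate locations are collapsed to the highest-occupancy conformer with a
warning.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import AtomRecord, Topology, Trajectory, assign_role, DEFAULT_WATER_RESNAMES
from .errors import ParseError, StructureError, ValidationError
from .hydration import ClusterRegionSpec

# ---------------------------------------------------------------------------
# Scenario configuration


@dataclass
class ChainStep:
    """One step of the canonical transfer chain.

    ``kind`` is ``"residue"`` (selection resolves to the residue's polar
    atoms) or ``"region"`` (the step is bridged by waters currently inside
    any of the named cluster regions).
    """

    kind: str
    label: str
    selection: str | None = None
    regions: tuple[str, ...] = ()


@dataclass
class ScenarioSpec:
    """One mutant system: substitutions, chain endpoints, regions, gates."""

    label: str
    source_selection: str
    sink_selection: str
    substitutions: list[tuple[str, int, str, str]] = field(default_factory=list)
    regions: list[ClusterRegionSpec] = field(default_factory=list)
    gate_residues: list[tuple[str, int]] = field(default_factory=list)
    canonical_chain: list[ChainStep] = field(default_factory=list)
    md_metadata: dict = field(default_factory=dict)

    def gate_contact_pairs(self) -> list[tuple[tuple[str, int], tuple[str, int]]]:
        """Consecutive gate-residue pairs whose contact fraction is reported."""
        if len(self.gate_residues) < 2:
            return []
        return [(self.gate_residues[0], self.gate_residues[1])]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "source_selection": self.source_selection,
            "sink_selection": self.sink_selection,
            "substitutions": [
                {"chain": c, "res_seq": r, "from_res": f, "to_res": t}
                for (c, r, f, t) in self.substitutions
            ],
            "regions": [
                {
                    "name": r.name,
                    "anchor_a": r.anchor_a,
                    "anchor_b": r.anchor_b,
                    "radius": r.radius,
                    "center_rule": r.center_rule,
                }
                for r in self.regions
            ],
            "gate_residues": [
                {"chain": c, "res_seq": r} for (c, r) in self.gate_residues
            ],
            "canonical_chain": [
                {
                    "kind": s.kind,
                    "label": s.label,
                    "selection": s.selection,
                    "regions": list(s.regions),
                }
                for s in self.canonical_chain
            ],
            "md_metadata": dict(self.md_metadata),
        }


def _default_regions() -> list[ClusterRegionSpec]:
    # W1 sits near cD61; W2 and W3 both lie between aH245 and aN214 and are
    # indistinguishable without explicit geometry, so they share the default
    # anchor midpoint and are usually analyzed jointly.
    w2w3 = dict(
        anchor_a="chain A and resid 245 and name CA",
        anchor_b="chain A and resid 214 and name CA",
    )
    return [
        ClusterRegionSpec(
            name="W1",
            anchor_a="chain C and resid 61 and name CA",
            anchor_b="chain A and resid 214 and name CA",
        ),
        ClusterRegionSpec(name="W2", **w2w3),
        ClusterRegionSpec(name="W3", **w2w3),
    ]


def _default_canonical_chain(region_names: list[str]) -> list[ChainStep]:
    mid_regions = tuple(n for n in region_names if n in ("W2", "W3", "W2/W3"))
    w1_regions = tuple(n for n in region_names if n == "W1")
    return [
        ChainStep("residue", "aE219", "chain A and resid 219 and polar"),
        ChainStep("residue", "aD119", "chain A and resid 119 and polar"),
        ChainStep("residue", "aH245", "chain A and resid 245 and polar"),
        ChainStep("region", "W2/W3", regions=mid_regions),
        ChainStep("residue", "aN214", "chain A and resid 214 and polar"),
        ChainStep("region", "W1", regions=w1_regions),
        ChainStep("residue", "cD61", "chain C and resid 61 and polar"),
    ]


def scenario_from_dict(data: dict) -> ScenarioSpec:
    missing = [
        k for k in ("label", "source_selection", "sink_selection") if not data.get(k)
    ]
    if missing:
        raise ValidationError(f"scenario config missing required keys: {missing}")

    regions_cfg = data.get("regions")
    if regions_cfg:
        regions = [
            ClusterRegionSpec(
                name=r["name"],
                anchor_a=r["anchor_a"],
                anchor_b=r["anchor_b"],
                radius=float(r.get("radius", 3.5)),
            )
            for r in regions_cfg
        ]
    else:
        regions = _default_regions()
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate region names in scenario: {names}")

    chain_cfg = data.get("canonical_chain")
    if chain_cfg:
        chain = [
            ChainStep(
                kind=s["kind"],
                label=s["label"],
                selection=s.get("selection"),
                regions=tuple(s.get("regions", ())),
            )
            for s in chain_cfg
        ]
    else:
        chain = _default_canonical_chain(names)
    for step in chain:
        if step.kind not in ("residue", "region"):
            raise ValidationError(f"unknown canonical-chain step kind {step.kind!r}")
        if step.kind == "region":
            unknown = set(step.regions) - set(names)
            if unknown:
                raise ValidationError(
                    f"canonical-chain step {step.label!r} references unknown "
                    f"regions {sorted(unknown)}"
                )

    return ScenarioSpec(
        label=str(data["label"]),
        source_selection=data["source_selection"],
        sink_selection=data["sink_selection"],
        substitutions=[
            (s["chain"], int(s["res_seq"]), s["from_res"], s["to_res"])
            for s in data.get("substitutions", [])
        ],
        regions=regions,
        gate_residues=[
            (g["chain"], int(g["res_seq"])) for g in data.get("gate_residues", [])
        ],
        canonical_chain=chain,
        md_metadata=dict(data.get("md_metadata", {})),
    )


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Load a scenario configuration (YAML) into a :class:`ScenarioSpec`.

    Absent ``regions`` default to the three cluster spheres W1, W2, W3;
    an absent ``canonical_chain`` defaults to the inlet half-channel chain
    aE219 - aD119 - aH245 - W2/W3 - aN214 - W1 - cD61.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValidationError(f"scenario config {path} is not a mapping")
    return scenario_from_dict(data)


def write_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def load_packaged_scenario(label: str) -> ScenarioSpec:
    """One of the ten scenario configs shipped with the package."""
    from importlib import resources

    stem = label.replace("/", "_")
    ref = resources.files("halfchannel.data") / "scenarios" / f"{stem}.yaml"
    if not ref.is_file():
        raise ValidationError(f"no packaged scenario named {label!r}")
    return scenario_from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# PDB reading


def _parse_pdb_atom_line(line: str, line_number: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        res_name = line[17:20].strip()
        chain_id = line[21:22].strip() or " "
        res_seq = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record: {line.rstrip()!r}",
                         line_number) from exc
    occ_field = line[54:60].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the first alphabetic character of the atom name
        element = next((c for c in name if c.isalpha()), "C").upper()
    if icode:
        raise ParseError(
            f"insertion code {icode!r} not supported (residue numbering must be "
            "unambiguous)", line_number,
        )
    return serial, name, altloc, res_name, chain_id, res_seq, (x, y, z), occupancy, element


def _read_pdb_models(path: Path, water_resnames):
    """All MODEL blocks as (atom metadata list, coordinate array) pairs."""
    models = []
    current_atoms: list = []
    current_coords: list = []
    in_model = False
    seen_any_model_kw = False
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                if in_model:
                    raise ParseError("nested MODEL record", line_number)
                in_model = True
                seen_any_model_kw = True
                current_atoms, current_coords = [], []
            elif rec.startswith("ENDMDL"):
                if not in_model:
                    raise ParseError("ENDMDL without MODEL", line_number)
                in_model = False
                models.append((current_atoms, current_coords))
            elif rec in ("ATOM  ", "HETATM"):
                parsed = _parse_pdb_atom_line(line, line_number)
                current_atoms.append(parsed)
                current_coords.append(parsed[6])
    if in_model:
        raise ParseError("unterminated MODEL block at end of file")
    if not seen_any_model_kw:
        if not current_atoms:
            raise ValidationError(f"no ATOM/HETATM records in {path}")
        models.append((current_atoms, current_coords))
    if not models or not models[0][0]:
        raise ValidationError(f"no ATOM/HETATM records in {path}")
    return models


def _topology_from_parsed(parsed_atoms, water_resnames) -> tuple[Topology, np.ndarray]:
    """Build a Topology, collapsing altlocs to the highest-occupancy conformer."""
    keep: dict[tuple, int] = {}  # (chain, res_seq, res_name, name) -> index
    occupancies: dict[tuple, float] = {}
    records = []
    coords = []
    had_altloc = False
    serials_seen = set()
    for serial, name, altloc, res_name, chain_id, res_seq, xyz, occ, element in parsed_atoms:
        key = (chain_id, res_seq, res_name, name)
        if altloc:
            had_altloc = True
            if key in keep:
                if occ > occupancies[key]:
                    idx = keep[key]
                    records[idx] = (serial, name, element, res_name, res_seq, chain_id)
                    coords[idx] = xyz
                    occupancies[key] = occ
                continue
            occupancies[key] = occ
            keep[key] = len(records)
        if serial in serials_seen:
            raise ParseError(f"duplicate atom serial {serial}")
        serials_seen.add(serial)
        records.append((serial, name, element, res_name, res_seq, chain_id))
        coords.append(xyz)
    if had_altloc:
        warnings.warn(
            "alternate locations present; keeping highest-occupancy conformers",
            stacklevel=3,
        )
    atoms = [
        AtomRecord(
            serial=s,
            name=n,
            element=e,
            res_name=rn,
            res_seq=rs,
            chain_id=c,
            role=assign_role(rn, n, water_resnames),
        )
        for (s, n, e, rn, rs, c) in records
    ]
    return Topology(atoms), np.array(coords, dtype=float)


def read_structure(
    path: str | Path,
    dialect: str = "pdb",
    water_resnames=DEFAULT_WATER_RESNAMES,
) -> Topology:
    """Read a structure file into a :class:`Topology` (first model only)."""
    if dialect != "pdb":
        raise ValidationError(f"unknown structure dialect {dialect!r}")
    path = Path(path)
    models = _read_pdb_models(path, water_resnames)
    topology, _ = _topology_from_parsed(models[0][0], water_resnames)
    return topology


def read_trajectory(
    topology: Topology,
    path: str | Path,
    dialect: str = "pdb",
    frame_interval_ps: float = 2.0,
    water_resnames=DEFAULT_WATER_RESNAMES,
) -> Trajectory:
    """Read a trajectory (multi-model PDB or DCD) against a known topology."""
    path = Path(path)
    if dialect == "pdb":
        models = _read_pdb_models(path, water_resnames)
        frames = []
        for i, (atoms, coords) in enumerate(models):
            if len(atoms) != topology.n_atoms:
                raise StructureError(
                    f"model {i + 1} has {len(atoms)} atoms, topology has "
                    f"{topology.n_atoms}"
                )
            frames.append(np.array(coords, dtype=float))
        coords = np.stack(frames)
    elif dialect == "dcd":
        coords = _read_dcd(path, topology.n_atoms)
    else:
        raise ValidationError(f"unknown trajectory dialect {dialect!r}")
    return Trajectory(topology, coords, frame_interval_ps=frame_interval_ps)


def _read_dcd(path: Path, n_atoms: int) -> np.ndarray:
    import MDAnalysis as mda

    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.load_new(str(path))
    frames = [ts.positions.astype(float).copy() for ts in u.trajectory]
    coords = np.stack(frames)
    if coords.shape[1] != n_atoms:
        raise StructureError(
            f"DCD has {coords.shape[1]} atoms, topology has {n_atoms}"
        )
    return coords


# ---------------------------------------------------------------------------
# PDB / DCD writing


def _format_pdb_atom(atom: AtomRecord, xyz) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
    return (
        f"ATOM  {atom.serial:>5} {name:<4} {atom.res_name:>3} {atom.chain_id}"
        f"{atom.res_seq:>4}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2}"
    )


def write_structure(topology: Topology, coordinates, path: str | Path) -> None:
    """Write a single-frame PDB."""
    coordinates = np.asarray(coordinates, dtype=float)
    lines = [
        _format_pdb_atom(a, coordinates[i]) for i, a in enumerate(topology.atoms)
    ]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path, dialect: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB or DCD."""
    path = Path(path)
    if dialect == "pdb":
        chunks = []
        for f in range(traj.n_frames):
            chunks.append(f"MODEL     {f + 1:>4}")
            frame = traj.coordinates[f]
            for i, atom in enumerate(traj.topology.atoms):
                chunks.append(_format_pdb_atom(atom, frame[i]))
            chunks.append("ENDMDL")
        chunks.append("END")
        path.write_text("\n".join(chunks) + "\n")
    elif dialect == "dcd":
        _write_dcd(traj, path)
    else:
        raise ValidationError(f"unknown trajectory dialect {dialect!r}")


def _write_dcd(traj: Trajectory, path: Path) -> None:
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    with mda.Writer(str(path), n_atoms=traj.n_atoms) as writer:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coordinates[f]
            writer.write(u.atoms)


# ---------------------------------------------------------------------------
# Result tables


def _check_schema(rows: list[dict]) -> list[str]:
    if not rows:
        return []
    keys = list(rows[0].keys())
    for i, row in enumerate(rows):
        if list(row.keys()) != keys:
            raise ValidationError(
                f"row {i} schema {list(row.keys())} differs from first row {keys}"
            )
    return keys


def write_results(
    rows: list[dict], path: str | Path, dialect: str = "csv", fieldnames=None
) -> None:
    """Write a homogeneous table of result rows as CSV (RFC 4180) or JSON.

    The JSON dialect round-trips losslessly; CSV stringifies values.  An
    empty table with explicit ``fieldnames`` produces a header-only CSV.
    """
    keys = _check_schema(rows)
    if not keys and fieldnames:
        keys = list(fieldnames)
    path = Path(path)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(rows)
    elif dialect == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2, sort_keys=False)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown results dialect {dialect!r}")


def read_results(path: str | Path, dialect: str = "csv") -> list[dict]:
    path = Path(path)
    if dialect == "csv":
        with open(path, newline="") as fh:
            return [dict(row) for row in csv.DictReader(fh)]
    if dialect == "json":
        with open(path) as fh:
            return json.load(fh)
    raise ValidationError(f"unknown results dialect {dialect!r}")
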