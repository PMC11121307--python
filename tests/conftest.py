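"""Shared fixtures: small synthetic systems and helper topologies."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from halfchannel.core import AtomRecord, Topology, Trajectory, assign_role
from halfchannel.synthetic import (
    generate_toy_trajectory,
    make_fixture_spec,
    scenario_for_fixture,
)

settings.register_profile("repeatable", derandomize=True, max_examples=50)
settings.load_profile("repeatable")


def water_topology(n: int) -> Topology:
    """n single-oxygen water molecules, one residue each."""
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="O",
            element="O",
            res_name="HOH",
            res_seq=100 + i,
            chain_id="W",
            role=assign_role("HOH", "O"),
        )
        for i in range(n)
    ]
    return Topology(atoms)


def protein_atom(serial, name, res_name, res_seq, chain_id="A", element=None):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element or name[0],
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        role=assign_role(res_name, name),
    )


@pytest.fixture(scope="session")
def wt_system():
    """Wild-type toy system: trajectory, ground truth, matching scenario."""
    spec = make_fixture_spec("WT", n_frames=150, seed=5)
    traj, truth = generate_toy_trajectory(spec)
    return traj, truth, scenario_for_fixture("WT")


@pytest.fixture(scope="session")
def static_trajectory():
    """A 5-frame trajectory with identical frames (20 peptide-like atoms)."""
    rng = np.random.default_rng(42)
    atoms = []
    serial = 1
    for res in range(5):
        for name in ("N", "CA", "C", "O"):
            atoms.append(protein_atom(serial, name, "ALA", res + 1))
            serial += 1
    top = Topology(atoms)
    frame = rng.normal(scale=3.0, size=(len(atoms), 3))
    coords = np.repeat(frame[None], 5, axis=0)
    return Trajectory(top, coords)
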