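"""Shared fixtures: tiny hand-built topologies and trajectories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from memtool.trajectory import Topology, Trajectory

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_topology(rows, selections=None):
    """Build a Topology from (name, resname, resid, group, q, sigma, eps, mass, parent) rows."""
    atoms = pd.DataFrame(
        rows,
        columns=[
            "name",
            "resname",
            "resid",
            "group",
            "charge_e",
            "sigma_A",
            "epsilon_kcal",
            "mass_amu",
            "parent",
        ],
    )
    return Topology(atoms=atoms, selections=selections or {})


def make_trajectory(coords, box=100.0):
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    boxes = np.full((coords.shape[0], 3), float(box))
    return Trajectory(coordinates=coords, box=boxes)


@pytest.fixture
def oh_probe_topology():
    """A hydroxyl donor (O with bonded H) plus two single-atom acceptors."""
    return make_topology(
        [
            ("O1", "DOX", 1, "OH", -0.6, 3.07, 0.17, 15.999, -1),
            ("H1", "DOX", 1, "OH", 0.45, 0.0, 0.0, 1.008, 0),
            ("OA1", "ACP", 2, "A1", -0.5, 3.07, 0.17, 15.999, -1),
            ("OA2", "ACP", 3, "A2", -0.5, 3.07, 0.17, 15.999, -1),
        ],
        selections={"donors": [0], "acceptors": [2, 3]},
    )
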