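from __future__ import annotations

import numpy as np
import pytest

from acylsel._masses import mass_of
from acylsel.traj_io import AtomRecord, Trajectory
from acylsel.synthetic import SyntheticSpec, generate_trajectory, make_benchmark_suite


def toy_trajectory(coords, names=None, elements=None, resnames=None,
                   resids=None, chains=None, boxes=None, times=None):
    """Build a small Trajectory from raw arrays for geometry-level tests."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    names = names or [f"X{i+1}" for i in range(n)]
    elements = elements or ["C"] * n
    resnames = resnames or ["UNK"] * n
    resids = resids or [1] * n
    chains = chains or ["A"] * n
    topology = [
        AtomRecord(serial=i + 1, name=names[i], element=elements[i],
                   residue_name=resnames[i], residue_number=resids[i],
                   chain_id=chains[i], mass=mass_of(elements[i]))
        for i in range(n)
    ]
    return Trajectory(topology=topology, coordinates=coords, boxes=boxes,
                      times=times)


@pytest.fixture(scope="session")
def small_system():
    """A 300-frame synthetic C16 system with its ground-truth ledger."""
    spec = SyntheticSpec(n_frames=300, seed=11)
    return generate_trajectory(spec)


@pytest.fixture(scope="session")
def benchmark_suite():
    """The five-chain-length benchmark at full size (5000 frames, seed 1)."""
    return make_benchmark_suite(1, n_frames=5000)


@pytest.fixture()
def toy():
    return toy_trajectory
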