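"""Shared fixtures: reference model, small ensembles, helper geometry."""

import numpy as np
import pytest

from bir2sim import cg_remd as cg
from bir2sim import traj_metrics as tm


@pytest.fixture(scope="session")
def reference_fold():
    return cg.reference_fold()


@pytest.fixture(scope="session")
def wt_model(reference_fold):
    coords, ids, names = reference_fold
    return cg.build_cg_model(coords, ids, residue_names_in=names)


@pytest.fixture(scope="session")
def toy_chain_model():
    """A 6-bead zig-zag chain: cheap enough for long REMD diagnostics."""
    rng = np.random.default_rng(5)
    coords = np.stack([np.arange(6) * 3.0,
                       1.5 * (np.arange(6) % 2),
                       0.2 * rng.normal(size=6)], axis=1)
    return cg.build_cg_model(coords, np.arange(1, 7), contact_cutoff=6.5,
                             contact_eps=0.8)


@pytest.fixture(scope="session")
def wt_short_ensemble(wt_model):
    """Short WT production ensemble at the default ladder (shared)."""
    ladder = cg.ReplicaLadder(exchange_interval=200)
    res = cg.run_remd(wt_model, ladder, cg.LangevinParams(seed=3),
                      n_steps=6000, stride=50)
    return res


def ideal_helix(n, radius=2.3, rise=1.5, turn_deg=100.0, start_id=1):
    """C-alpha trace of an ideal right-handed alpha-helix."""
    t = np.arange(n) * np.radians(turn_deg)
    coords = np.stack([radius * np.cos(t), radius * np.sin(t),
                       1.5 * np.arange(n) * (rise / 1.5)], axis=1)
    return tm.Trajectory(coords[None], np.arange(start_id, start_id + n))


def ideal_strand(n, start_id=1):
    """C-alpha trace of an ideal extended beta strand (planar zig-zag)."""
    coords = np.stack([3.3 * np.arange(n), 0.95 * (np.arange(n) % 2),
                       np.zeros(n)], axis=1)
    return tm.Trajectory(coords[None], np.arange(start_id, start_id + n))
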