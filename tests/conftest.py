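"""Shared fixtures: toy systems with exactly enumerable statistics."""

import numpy as np
import pytest

from lassocap.cg_model import EnergyParams, Interactions, SystemState
from lassocap.order_params import BinTable, default_bin_table
from lassocap.sampler import MoveParams


def make_state(pos, chain_id, box, seed=0):
    return SystemState(np.asarray(pos, dtype=float),
                       np.asarray(chain_id, dtype=np.int64),
                       box, np.random.default_rng(seed))


@pytest.fixture(scope="session")
def pair_toy():
    """Two single-bead chains with one Go pair used for both arms.

    The relative coordinate is a free particle in the periodic box feeling
    only the square hybridization well, so every bin probability is an
    exact 3-D integral over the box -- the enumeration oracle for the
    umbrella machinery.
    """
    box = 14.0
    params = EnergyParams(ev_epsilon=0.0, el_amplitude=0.0, bend_k=0.0,
                          hyb_epsilon=2.0, hyb_range=0.85)
    bins = default_bin_table().scaled(0.1)
    inter = Interactions.from_pairs(2, [(0, 1)], [(0, 1)])
    move = MoveParams(max_translation=0.6, max_rotation=0.3, seed=5)

    def new_state(seed=0):
        return make_state([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]], [0, 1],
                          box, seed)

    return {"box": box, "params": params, "bins": bins, "inter": inter,
            "move": move, "new_state": new_state}


def enumerate_pair_bins(params, bins, box, n_grid=240):
    """Exact bin probabilities for the two-bead toy.

    Shell volumes with an outer radius inside box/2 are spheres and taken
    analytically (a grid badly under-resolves the sub-nm bound bins); only
    shells touching the cube geometry are integrated on a grid.  The
    square-well Boltzmann factor is constant on each bin (the toys align
    the well edge with a bin edge), applied per bin.
    """
    edges = list(bins.as_array()) + [np.inf]
    n = bins.n_intervals
    vols = np.zeros(n)
    analytic = [i for i in range(n) if edges[i + 1] <= box / 2]
    for i in analytic:
        vols[i] = 4.0 / 3.0 * np.pi * (edges[i + 1] ** 3 - edges[i] ** 3)
    r_grid = edges[analytic[-1] + 1] if analytic else 0.0
    h = box / n_grid
    x = (np.arange(n_grid) + 0.5) * h - box / 2
    X, Y = np.meshgrid(x, x, indexing="ij")
    for z in x:
        r = np.sqrt(X * X + Y * Y + z * z)
        sel = r >= r_grid
        q = np.searchsorted(edges[:-1], r[sel], side="right") - 1
        vols += h ** 3 * np.bincount(q, minlength=n)
    boltz = np.ones(n)
    for i in range(n):
        lo, hi = edges[i], edges[i + 1]
        assert hi <= params.hyb_range + 1e-9 or lo >= params.hyb_range - 1e-9, \
            "well edge must align with a bin edge for the exact oracle"
        if hi <= params.hyb_range + 1e-9:
            boltz[i] = np.exp(params.hyb_epsilon)
    probs = vols * boltz
    return probs / probs.sum()


@pytest.fixture(scope="session")
def pair_toy_exact(pair_toy):
    return enumerate_pair_bins(pair_toy["params"], pair_toy["bins"],
                               pair_toy["box"])


@pytest.fixture(scope="session")
def four_bead_toy():
    """Two 2-bead chains with one Go pair per arm; full energy model."""
    box = 12.0
    params = EnergyParams(hyb_epsilon=3.0)
    bins = default_bin_table().scaled(0.1)
    inter = Interactions.from_pairs(4, [(0, 2)], [(1, 3)])
    move = MoveParams(max_translation=0.5, max_rotation=0.4, seed=9)

    def new_state(seed=0):
        return make_state([[1.0, 1.0, 1.0], [1.65, 1.0, 1.0],
                           [1.0, 1.7, 1.0], [1.65, 1.7, 1.0]],
                          [0, 0, 1, 1], box, seed)

    return {"box": box, "params": params, "bins": bins, "inter": inter,
            "move": move, "new_state": new_state}


def corner_alternations(hist):
    """Number of transitions between the two corner states along the
    recorded OP trajectory (a round-trip/mixing diagnostic)."""
    qe = np.asarray(hist.traj_q_ex)
    ql = np.asarray(hist.traj_q_lig)
    nmax = 10
    sv = np.where((qe == 0) & (ql == 0), 0,
                  np.where((qe == nmax) & (ql == nmax), 1, -1))
    sv = sv[sv >= 0]
    if sv.size == 0:
        return 0
    return int(np.sum(np.abs(np.diff(sv)) > 0))


def blocked_sem(x, n_blocks=20):
    """Standard error of the mean from contiguous block means (handles
    autocorrelation)."""
    x = np.asarray(x, dtype=float)
    edges = np.linspace(0, x.size, n_blocks + 1).astype(int)
    means = np.array([x[a:b].mean() for a, b in zip(edges, edges[1:])
                      if b > a])
    return means.std(ddof=1) / np.sqrt(len(means))
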