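"""Order parameters for probe-target capture.

The capture state of a probe/target pair is summarised by two distances:
``d_ex`` and ``d_lig``, the minimum (minimum-image) distance between the
bases of each probe arm and their designed complementary bases on the
target.  Each distance is discretized on an 11-interval table of half-open
bins into an integer order parameter ``Q`` in [0, 10].  ``(0, 0)`` is the
interaction (both arms bound) state and ``(10, 10)`` the completely
non-interacting state.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .cg_model import Interactions, SystemState

__all__ = [
    "BinTable",
    "OPState",
    "DEFAULT_EDGES",
    "default_bin_table",
    "arm_distance",
    "discretize",
    "op_state",
    "classify_state",
]

# Printed distance intervals (nm): 0-1.7, 1.7-3.4, 3.4-5.1, 5.1-8.5, 8.5-12.8,
# 12.8-17.0, 17.0-34.1, 34.1-68.1, 68.1-102.2, >102.2 enumerate only 10
# intervals while Q runs 0..10 over 11.  The default table inserts an edge at
# 85.2 nm (the 68.1-102.2 midpoint continuing the doubling pattern) so that
# all printed edges are kept and the table has 11 intervals.
DEFAULT_EDGES = (0.0, 1.7, 3.4, 5.1, 8.5, 12.8, 17.0, 34.1, 68.1, 85.2, 102.2)


@dataclass(frozen=True)
class BinTable:
    """Ascending half-open distance intervals [e_i, e_{i+1}), last unbounded."""

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self):
        e = self.edges
        if len(e) < 2:
            raise ValueError("BinTable needs at least two edges")
        if e[0] != 0.0:
            raise ValueError("first edge must be 0")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly ascending")
        object.__setattr__(self, "edges", tuple(float(x) for x in e))

    @property
    def n_intervals(self) -> int:
        return len(self.edges)

    @property
    def max_q(self) -> int:
        return len(self.edges) - 1

    def scaled(self, factor: float) -> "BinTable":
        """Uniformly scaled copy (for desk-scale systems)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return BinTable(tuple(e * factor for e in self.edges))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.edges, dtype=np.float64)

    @property
    def table_hash(self) -> str:
        return hashlib.sha1(repr(self.edges).encode()).hexdigest()[:12]


def default_bin_table() -> BinTable:
    return BinTable(DEFAULT_EDGES)


@dataclass(frozen=True)
class OPState:
    """Discretized (Qex, Qlig) pair."""

    q_ex: int
    q_lig: int

    def validate(self, bins: BinTable) -> "OPState":
        if not (0 <= self.q_ex <= bins.max_q and 0 <= self.q_lig <= bins.max_q):
            raise ValueError(f"{self} outside [0, {bins.max_q}]")
        return self


def arm_distance(state: SystemState, pairs) -> float:
    """Minimum minimum-image distance (nm) over an arm's designed pairs."""
    arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if arr.shape[0] == 0:
        raise ValueError("pair list is empty")
    return float(_k.arm_min_dist(state.pos, arr, state.box_side))


def discretize(d: float, bins: BinTable) -> int:
    """Index of the half-open interval [e_i, e_{i+1}) containing distance d."""
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    return int(np.searchsorted(bins.as_array(), d, side="right")) - 1


def op_state(state: SystemState, ext_pairs, lig_pairs, bins: BinTable) -> OPState:
    qe = discretize(arm_distance(state, ext_pairs), bins)
    ql = discretize(arm_distance(state, lig_pairs), bins)
    return OPState(qe, ql)


def op_state_system(state: SystemState, inter: Interactions, bins: BinTable) -> OPState:
    return op_state(state, inter.ext_pairs, inter.lig_pairs, bins)


def classify_state(op: OPState, bins: BinTable | None = None) -> str:
    """'interaction' at (0,0), 'non_interaction' at (max,max), else 'intermediate'."""
    max_q = (bins or default_bin_table()).max_q
    op.validate(bins or default_bin_table())
    if op.q_ex == 0 and op.q_lig == 0:
        return "interaction"
    if op.q_ex == max_q and op.q_lig == max_q:
        return "non_interaction"
    return "intermediate"
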