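"""Monte Carlo engines.

Two samplers over the same reduced energy function:

* :func:`metropolis_step` / single-bead Metropolis -- the reference sampler,
  one bead displaced uniformly per move;
* :func:`vmmc_step` -- Virtual Move Monte Carlo cluster moves (symmetrized
  Whitelam-Geissler link rule with early outright rejection), which move
  strongly coupled groups of beads -- bonded chain segments and hybridized
  duplex regions -- rigidly, and are essential for relaxing two-strand
  systems where single-bead moves of a bound duplex are almost always
  rejected.

:func:`run_sampler` drives either engine for many steps inside a compiled
kernel, optionally under a 2-D umbrella weight table: the acceptance of each
whole move is multiplied by ``w(Q_new)/w(Q_old)`` evaluated on the
(Qex, Qlig) state, so the stationary distribution is re-weighted cell-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _k
from .cg_model import EnergyParams, Interactions, SystemState
from .order_params import BinTable, OPState, default_bin_table

__all__ = ["MoveParams", "SamplerResult", "metropolis_step", "vmmc_step",
           "run_sampler"]


@dataclass(frozen=True)
class MoveParams:
    """Move-set constants.

    Defaults (0.25 nm translation, 0.2 rad rotation) target 30-50 %
    acceptance on the reference systems; ``cluster_size_cap`` of None means
    no cap (cap rejections are counted, preserving detailed balance).
    """

    max_translation: float = 0.25   # nm
    max_rotation: float = 0.2       # rad
    cluster_size_cap: int | None = None
    seed: int = 0
    # Optional large-displacement translation mixture (VMMC only): with
    # probability ``big_move_prob`` the trial translation is drawn from a
    # ball of radius ``big_translation`` instead.  Large moves recruit whole
    # chains through their bonds and act as rigid chain diffusion moves;
    # the mixture is symmetric, so detailed balance is untouched.
    big_translation: float = 0.0    # nm; 0 disables
    big_move_prob: float = 0.0
    # Fraction of VMMC trial moves that are rotations about the seed bead.
    # Rotations displace far-away beads proportionally to their distance
    # from the pivot and therefore recruit whole chains; on large systems
    # they dominate the cost, and cluster translations alone remain
    # ergodic (a translated sub-cluster deforms the chain through its
    # boundary bonds), so sweep studies turn them off.
    rotation_prob: float = 0.5

    def __post_init__(self):
        if self.max_translation <= 0 or self.max_rotation <= 0:
            raise ValueError("move step sizes must be positive")
        if self.cluster_size_cap is not None and self.cluster_size_cap < 1:
            raise ValueError("cluster_size_cap must be >= 1")
        if not (0.0 <= self.big_move_prob <= 1.0):
            raise ValueError("big_move_prob must be in [0, 1]")
        if not (0.0 <= self.rotation_prob <= 1.0):
            raise ValueError("rotation_prob must be in [0, 1]")
        if self.big_move_prob > 0.0 and self.big_translation <= 0.0:
            raise ValueError("big_translation must be positive when "
                             "big_move_prob > 0")


@dataclass
class SamplerResult:
    """OP-state trajectory plus acceptance bookkeeping for one run."""

    traj_q_ex: np.ndarray     # (n_recorded,) int16
    traj_q_lig: np.ndarray
    hist: np.ndarray          # (n_q, n_q) int64 counts over production steps
    n_steps: int              # production steps
    n_equil: int
    n_accepted: int           # over equil + production moves
    n_cap_rejected: int
    seed: int
    bins: BinTable

    @property
    def n_rejected(self) -> int:
        return self.n_steps + self.n_equil - self.n_accepted

    @property
    def acceptance_rate(self) -> float:
        tot = self.n_steps + self.n_equil
        return self.n_accepted / tot if tot else float("nan")


def _prep(state: SystemState, inter: Interactions, params: EnergyParams,
          bins: BinTable, weights):
    P = params.pack(state.box_side)
    edges = bins.as_array()
    nq = bins.n_intervals
    if weights is None:
        logw = np.zeros((nq, nq))
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (nq, nq):
            raise ValueError(f"weight table shape {w.shape} != {(nq, nq)}")
        if np.any(w <= 0):
            raise ValueError("umbrella weights must be strictly positive")
        logw = np.log(w)
    return P, edges, logw


def _single_step(state, inter, params, move, use_vmmc, weights=None, bins=None):
    bins = bins or default_bin_table()
    P, edges, logw = _prep(state, inter, params, bins, weights)
    nq = bins.n_intervals
    hist = np.zeros((nq, nq), dtype=np.int64)
    tq = np.empty(1, dtype=np.int16)
    tl = np.empty(1, dtype=np.int16)
    cap = inter.hyb_partner.shape[0] if move.cluster_size_cap is None \
        else move.cluster_size_cap
    sub_seed = int(state.rng.integers(0, 2**31 - 1))
    n_acc, n_cap, _ = _k.run_mc(
        state.pos, state.chain_id, inter.hyb_partner, P,
        inter.ext_pairs, inter.lig_pairs, edges, logw,
        use_vmmc, move.max_translation, move.max_rotation,
        move.rotation_prob, move.big_translation, move.big_move_prob, cap,
        0, 1, 1, sub_seed, hist, tq, tl, 0.0, np.zeros((nq, nq)), 0.0)
    return state, bool(n_acc)


def metropolis_step(state: SystemState, inter: Interactions,
                    params: EnergyParams, move: MoveParams):
    """One single-bead Metropolis move (in place); returns (state, accepted)."""
    return _single_step(state, inter, params, move, use_vmmc=False)


def vmmc_step(state: SystemState, inter: Interactions,
              params: EnergyParams, move: MoveParams):
    """One VMMC cluster move (in place); returns (state, accepted)."""
    return _single_step(state, inter, params, move, use_vmmc=True)


def run_sampler(state: SystemState, inter: Interactions, params: EnergyParams,
                move: MoveParams, n_steps: int, *, weights=None,
                log_weights: np.ndarray | None = None,
                bins: BinTable | None = None, n_equil: int = 0,
                stride: int = 10, seed: int | None = None,
                use_vmmc: bool = True, wl_f: float = 0.0,
                wl_sunk: np.ndarray | None = None,
                wl_temper: float = 0.0) -> SamplerResult:
    """Run ``n_equil`` discarded + ``n_steps`` recorded Monte Carlo moves.

    Mutates ``state.pos`` in place.  The OP histogram accumulates every
    production step; the trajectory is recorded every ``stride`` steps.
    Reproducible bit-for-bit for a fixed seed and inputs.

    ``log_weights`` bypasses the positive-weight validation of ``weights``
    and is mutated in place when ``wl_f > 0`` (Wang-Landau adaptation).
    """
    if n_steps < 0 or n_equil < 0:
        raise ValueError("step counts must be non-negative")
    bins = bins or default_bin_table()
    if log_weights is not None:
        P = params.pack(state.box_side)
        edges = bins.as_array()
        logw = np.ascontiguousarray(log_weights, dtype=np.float64)
        if logw.shape != (bins.n_intervals, bins.n_intervals):
            raise ValueError("log_weights has wrong shape")
    else:
        P, edges, logw = _prep(state, inter, params, bins, weights)
    nq = bins.n_intervals
    hist = np.zeros((nq, nq), dtype=np.int64)
    n_rec = 0 if stride <= 0 else (n_steps + stride - 1) // stride
    tq = np.empty(max(n_rec, 1), dtype=np.int16)
    tl = np.empty(max(n_rec, 1), dtype=np.int16)
    cap = state.n_beads if move.cluster_size_cap is None else move.cluster_size_cap
    if seed is None:
        seed = move.seed
    seed = int(seed) % (2**31 - 1)
    n_acc, n_cap, rec = _k.run_mc(
        state.pos, state.chain_id, inter.hyb_partner, P,
        inter.ext_pairs, inter.lig_pairs, edges, logw,
        use_vmmc, move.max_translation, move.max_rotation,
        move.rotation_prob, move.big_translation, move.big_move_prob, cap,
        n_equil, n_steps, max(stride, 0), seed, hist, tq, tl, wl_f,
        wl_sunk if wl_sunk is not None else np.zeros((nq, nq)), wl_temper)
    return SamplerResult(
        traj_q_ex=tq[:rec].copy(), traj_q_lig=tl[:rec].copy(), hist=hist,
        n_steps=n_steps, n_equil=n_equil, n_accepted=int(n_acc),
        n_cap_rejected=int(n_cap), seed=seed, bins=bins)
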