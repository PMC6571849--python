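"""Three-stage umbrella-sampling pipeline and free-energy estimation.

Stage 1 (:func:`adapt_weights`) builds per-state umbrella weights
``w(Qex, Qlig)`` that flatten the sampled order-parameter histogram:
starting from an analytic prior (min-image shell-volume entropy corrected
by the expected well energy), per-move Wang-Landau updates with an
annealed-then-decaying modification factor carve the residual landscape,
and the final table is rebuilt from the pooled unbiased estimates of the
small-factor tail blocks.  Stage 2 equilibrates under the (frozen,
channel-shaped) weights; stage 3 is production sampling.  The biased
histogram is then transformed to the unbiased distribution
``P propto counts / w`` and the probe-target interaction free energy, in
units of RT, is

    dG_int / RT = -ln( P(Qex=0, Qlig=0) / P(Qex=max, Qlig=max) )

i.e. the log-ratio of the bound corner to the fully dissociated corner.
Statistical errors come from a block bootstrap over the OP trajectory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .cg_model import (EnergyParams, Interactions, ProbeSpec, SystemState,
                       TargetSpec, init_configuration, interactions_from_specs)
from .order_params import BinTable, default_bin_table
from .sampler import MoveParams, SamplerResult, run_sampler

__all__ = [
    "WeightTable", "Histogram2D", "UnbiasedDistribution", "FreeEnergyResult",
    "WeightMismatchError", "UnboundedEstimateError",
    "adapt_weights", "sample_biased", "unbias", "interaction_free_energy",
    "diagonal_profile", "run_capture_pipeline",
]

logger = logging.getLogger("lassocap")


class WeightMismatchError(ValueError):
    """Histogram was not sampled under the supplied weight table."""


class UnboundedEstimateError(RuntimeError):
    """A corner state was never visited; dG_int is unbounded.

    Sample longer (or adapt weights further) so that both the interaction
    and the non-interaction corner acquire counts.
    """


def _weights_hash(w: np.ndarray) -> str:
    return hashlib.sha1(np.round(w, 10).tobytes()).hexdigest()[:16]


@dataclass
class WeightTable:
    """Positive umbrella weights per (Qex, Qlig) cell, min-normalized to 1."""

    log_weights: np.ndarray          # (n_q, n_q)
    converged: bool = True
    history: list = field(default_factory=list)

    def __post_init__(self):
        lw = np.asarray(self.log_weights, dtype=np.float64)
        if lw.ndim != 2 or lw.shape[0] != lw.shape[1]:
            raise ValueError("log_weights must be a square matrix")
        self.log_weights = lw - lw.min()   # min weight == 1

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    @property
    def table_hash(self) -> str:
        return _weights_hash(self.weights)

    @classmethod
    def uniform(cls, n_q: int) -> "WeightTable":
        return cls(np.zeros((n_q, n_q)))

    def with_channel(self, width: int = 2,
                     penalty: float = 2.0) -> "WeightTable":
        """Copy with cells outside the reaction channel suppressed by
        ``penalty`` kT per cell of excess distance from the channel.

        The channel is the diagonal band ``|Qex - Qlig| <= width`` plus the
        two bound-edge strips ``min(Qex, Qlig) = 0``: binding proceeds
        either with both arms approaching together (diagonal) or
        sequentially, one arm bound while the other roams (edges).
        Confining production sampling to this channel multiplies the
        corner-to-corner round-trip rate; the estimate stays unbiased --
        any weight table is removed exactly by :func:`unbias`."""
        lw = self.log_weights.copy()
        n = lw.shape[0]
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        excess = np.maximum(0, np.abs(ii - jj) - width)
        excess[0, :] = 0   # ext arm bound, lig arm anywhere
        excess[:, 0] = 0   # lig arm bound, ext arm anywhere
        lw -= penalty * excess
        return WeightTable(lw, converged=self.converged,
                           history=list(self.history))

    @classmethod
    def from_weights(cls, w, **kw) -> "WeightTable":
        w = np.asarray(w, dtype=np.float64)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        return cls(np.log(w), **kw)


@dataclass
class Histogram2D:
    """Biased sampling frequencies on the OP grid, with provenance."""

    counts: np.ndarray               # (n_q, n_q) int64
    n_samples: int
    weight_table_ref: str            # hash of the WeightTable sampled under
    seed: int = -1
    traj_q_ex: np.ndarray | None = None
    traj_q_lig: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if int(self.counts.sum()) != self.n_samples:
            raise ValueError("sum of counts must equal n_samples")


@dataclass
class UnbiasedDistribution:
    """P(Qex, Qlig) after removing the umbrella bias; sums to 1."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        s = self.p.sum()
        if not np.isfinite(s) or abs(s - 1.0) > 1e-9:
            raise ValueError(f"distribution must sum to 1, got {s}")

    @property
    def visited(self) -> np.ndarray:
        return self.p > 0


@dataclass
class FreeEnergyResult:
    """Interaction free energy (RT units) and the diagonal profile."""

    dg_int: float
    diagonal_profile: np.ndarray      # -ln P(q,q), 0 at the free corner; NaN gaps
    statistical_error: float | None = None
    n_samples: int = 0
    seed: int = -1


# ---------------------------------------------------------------------------
# Stage 1: adaptive flattening
# ---------------------------------------------------------------------------

def min_image_shell_volumes(bins: BinTable, box_side: float,
                            n_grid: int = 100) -> np.ndarray:
    """Fraction of relative-coordinate volume whose minimum-image distance
    falls in each bin (computed on a dense grid over the periodic cell)."""
    edges = bins.as_array()
    h = box_side / n_grid
    x = (np.arange(n_grid) + 0.5) * h - box_side / 2
    X, Y = np.meshgrid(x, x, indexing="ij")
    vols = np.zeros(bins.n_intervals)
    for z in x:
        r = np.sqrt(X * X + Y * Y + z * z)
        q = np.searchsorted(edges, r, side="right") - 1
        vols += np.bincount(q.ravel(), minlength=bins.n_intervals)
    return vols / vols.sum()


def geometric_prior_logw(bins: BinTable, box_side: float,
                         max_log_weight: float = 50.0) -> np.ndarray:
    """Initial log-weights that cancel the shell-volume entropy of the two
    arm-target distances (treated as independent).  Starting from this prior
    instead of uniform weights lets the flattening loop spend its budget on
    the energetic part of the landscape only."""
    logv = np.log(np.maximum(min_image_shell_volumes(bins, box_side), 1e-300))
    logw = -(logv[:, None] + logv[None, :])
    logw -= logw.min()
    return np.clip(logw, 0.0, max_log_weight)


def _well_energy_estimate(bins: BinTable, n_pairs: int, hyb_epsilon: float,
                          hyb_range: float, zip_fraction: float = 0.75
                          ) -> np.ndarray:
    """Expected hybridization energy gain (kT, positive) per OP bin.

    A bin whose distance interval lies inside the well range is treated as
    a (mostly) zipped arm: ``zip_fraction * n_pairs * eps``; a bin
    straddling the well edge gets the overlapping fraction.  This is a
    coarse prior, not a measurement -- adaptation corrects the residual.
    """
    est = np.zeros(bins.n_intervals)
    edges = list(bins.edges) + [np.inf]
    for q in range(bins.n_intervals):
        lo, hi = edges[q], edges[q + 1]
        if hi <= hyb_range:
            est[q] = zip_fraction * n_pairs * hyb_epsilon
        elif lo < hyb_range:
            frac = (hyb_range - lo) / (hi - lo)
            est[q] = zip_fraction * n_pairs * hyb_epsilon * frac
    return est


def analytic_prior_logw(bins: BinTable, box_side: float,
                        params: EnergyParams | None = None,
                        n_ext_pairs: int = 0, n_lig_pairs: int = 0,
                        max_log_weight: float = 80.0) -> np.ndarray:
    """Volume-entropy prior corrected by the expected well energy.

    The biased target is w = 1/P; P(cell) carries both the shell volume of
    each arm-distance bin and the Boltzmann factor of the designed wells,
    so bound bins need *less* weight than the pure-volume prior suggests,
    by roughly the zipped-arm well energy.  Starting from this analytic
    estimate leaves only few-kT residuals (loop-closure entropy, partial
    zipping, arm-arm coupling) for the adaptive stage.
    """
    logw = geometric_prior_logw(bins, box_side, max_log_weight)
    if params is not None:
        e_ext = _well_energy_estimate(bins, n_ext_pairs,
                                      params.hyb_epsilon, params.hyb_range)
        e_lig = _well_energy_estimate(bins, n_lig_pairs,
                                      params.hyb_epsilon, params.hyb_range)
        logw = logw - (e_ext[:, None] + e_lig[None, :])
    logw -= logw.min()
    return np.clip(logw, 0.0, max_log_weight)


def adapt_weights(state: SystemState, inter: Interactions, params: EnergyParams,
                  move: MoveParams, bins: BinTable | None = None, *,
                  flatness_target: float = 0.6, block_steps: int = 200_000,
                  iteration_budget: int = 20, seed: int | None = None,
                  require_corners: bool = True, use_vmmc: bool = True,
                  max_log_weight: float = 80.0,
                  initial: str = "geometric",
                  wl_f_init: float = 0.1,
                  wl_f_floor: float = 0.005) -> WeightTable:
    """Iteratively flatten the biased OP histogram.

    Starting from the analytic prior (shell-volume entropy corrected by the
    expected well energy), weights are refined by
    per-move Wang-Landau updating: every move lowers the log-weight of the
    occupied cell by a modification factor ``f``, so a walker trapped in an
    over-weighted region continuously sinks it until it escapes -- this
    self-correcting dynamics is what lets a single walker resolve the
    30+ kT dynamic range between bound-corner and free-corner cells.
    Starting from the analytic prior (shell-volume entropy corrected by
    the expected well energy), the landscape is refined by per-move
    Wang-Landau updates: every move lowers the occupied cell's log-weight
    by a modification factor ``f`` that halves each block from
    ``wl_f_init`` down to ``wl_f_floor`` and then decays as 1/t.  The
    per-move update is what makes adaptation robust here: a walker stuck
    in a cell the table over-weights continuously sinks that cell until
    it escapes.  A final block sampled under frozen weights provides the
    convergence diagnostic.

    Convergence is judged on the *diagonal* cells (Qex = Qlig), the
    reaction channel between the corner states: a frozen refinement block
    converges the table when its diagonal visited-cell counts reach
    ``flatness_target`` (min/mean) and both corner states were visited.
    Off-diagonal extremes such as (0, max) are thin, transit-only slivers
    of configuration space whose block-to-block occupancy never
    stabilises, so a global flatness criterion would never fire.  A
    non-converged table is still usable -- production re-weighting
    corrects any bias imperfection, at the price of variance.
    """
    if not (0.0 < flatness_target <= 1.0):
        raise ValueError("flatness_target must be in (0, 1]")
    if initial not in ("geometric", "uniform"):
        raise ValueError("initial must be 'geometric' or 'uniform'")
    bins = bins or default_bin_table()
    nq = bins.n_intervals
    if initial == "geometric":
        logw = analytic_prior_logw(bins, state.box_side, params,
                                   inter.ext_pairs.shape[0],
                                   inter.lig_pairs.shape[0],
                                   max_log_weight)
    else:
        logw = np.zeros((nq, nq))
    logw = np.ascontiguousarray(logw)
    history = []
    if seed is None:
        seed = move.seed
    if iteration_budget == 0:
        history.append({"iteration": -1, "flatness": 0.0,
                        "warning": "zero budget"})
        return WeightTable(logw, converged=False, history=history)

    visited_union = np.zeros((nq, nq), dtype=bool)
    frontier_margin = 2.0

    def _cap(recent):
        # Renormalizing by the minimum every block slowly inflates cells
        # the walker is not currently visiting (their weight rises by
        # however much the visited region was sunk) until they become
        # absorbing traps in production.  Clamp every cell that was NOT
        # visited in the last block to the block's visited maximum plus a
        # small frontier margin: unexplored cells keep a gentle pull
        # without ever towering over the explored landscape.
        if recent.any():
            ceil = float(logw[recent].max()) + frontier_margin
            notr = ~recent
            logw[notr] = np.minimum(logw[notr], ceil)
        logw[:] -= logw.min()
        np.clip(logw, 0.0, max_log_weight, out=logw)

    sunk = np.zeros((nq, nq))

    def _block(tag, f_val, n_steps, blk_seed, temper=0.0):
        res = run_sampler(state, inter, params, move, n_steps,
                          log_weights=logw, bins=bins, stride=0,
                          seed=blk_seed, use_vmmc=use_vmmc, wl_f=f_val,
                          wl_sunk=sunk, wl_temper=temper)
        counts = res.hist
        visited = counts > 0
        vis = counts[visited]
        flat = float(vis.min() / vis.mean()) if vis.size else 0.0
        diag = np.diagonal(counts)
        dvis = diag[diag > 0]
        dflat = float(dvis.min() / dvis.mean()) if dvis.size else 0.0
        c_ok = (not require_corners) or \
            (counts[0, 0] > 0 and counts[-1, -1] > 0)
        history.append({"iteration": len(history), "phase": tag,
                        "flatness": flat, "diag_flatness": dflat,
                        "wl_f": f_val,
                        "n_visited": int(visited.sum()),
                        "corner_00": int(counts[0, 0]),
                        "corner_max": int(counts[-1, -1]),
                        "acceptance": res.acceptance_rate})
        logger.info("adapt_weights %s %d: f=%.2e flat=%.3f diag=%.3f "
                    "visited=%d corners=(%d,%d)", tag, len(history) - 1,
                    f_val, flat, dflat, int(visited.sum()),
                    counts[0, 0], counts[-1, -1])
        visited_union[:] |= visited
        _cap(visited)
        return dflat, c_ok, counts

    # stage 1a -- anneal: halve f every block down to the floor; plain
    # Wang-Landau at a moderate starting f self-corrects sticky cells
    # (a trapped walker sinks its own trap).  If the first block reveals a
    # tiny reachable grid (an enumeration-scale toy), there is no
    # landscape to carve: Wang-Landau deposits would only churn the table
    # (each cell collects tens of thousands of visits per block), so the
    # anneal stops and the tail runs as pure frozen measurement.
    f = wl_f_init
    n_anneal = 0
    tiny_grid = False
    while f > wl_f_floor and n_anneal < iteration_budget:
        _block("anneal", f, block_steps, seed + 1000 * n_anneal)
        n_anneal += 1
        if n_anneal == 1 and visited_union.sum() <= 4:
            tiny_grid = True
            # discard the first block's deposits: the measurement tail
            # corrects any fixed table, but an extreme skew kills mixing
            logw[:, :] = analytic_prior_logw(
                bins, state.box_side, params,
                inter.ext_pairs.shape[0], inter.lig_pairs.shape[0],
                max_log_weight) if initial == "geometric" \
                else np.zeros((nq, nq))
            break
        f *= 0.5

    # stage 1b -- 1/t tail: the modification factor keeps decaying, so the
    # residual table error shrinks while the walker keeps being nudged
    # over any basin the table still misrepresents.  Each tail block also
    # contributes an unbiased estimate counts_b / w_b (the per-block bias
    # is essentially frozen at these tiny f); pooling them across blocks
    # keeps the information from every corner excursion instead of
    # trusting whatever state the deposits happen to end in.
    n_tail = max(iteration_budget - n_anneal, 1)
    log_pooled = np.full((nq, nq), -np.inf)
    tail_counts = np.zeros((nq, nq), dtype=np.int64)
    for k in range(n_tail):
        f = 0.0 if tiny_grid else wl_f_floor / (1.0 + k)
        logw_snap = logw.copy()
        _, _, counts = _block("one_over_t", f, block_steps,
                              seed + 200_000 + 1000 * k)
        tail_counts += counts
        vis = counts > 0
        contrib = np.full((nq, nq), -np.inf)
        contrib[vis] = np.log(counts[vis]) - logw_snap[vis]
        log_pooled = np.logaddexp(log_pooled, contrib)
        if tiny_grid:
            # track the running pooled estimate block by block: an
            # inaccurate prior throttles the exchange rate, and each
            # block's contribution stays unbiased through its snapshot
            pv = np.isfinite(log_pooled)
            logw[pv] = -log_pooled[pv] + log_pooled[pv].max()
            logw[:, :] -= logw.min()

    pooled_vis = np.isfinite(log_pooled)
    if pooled_vis.any():
        # cells without pooled data keep their deposit-stage estimate, but
        # that estimate lives on an arbitrary offset relative to -ln(P);
        # align the two scales by the median difference over pooled cells
        # before splicing, so no artificial cliffs appear at the seam
        offset = float(np.median(logw[pooled_vis] + log_pooled[pooled_vis]))
        new_logw = logw - offset
        new_logw[pooled_vis] = -log_pooled[pooled_vis]
        new_logw -= new_logw[pooled_vis].min()
        ceil = float(new_logw[pooled_vis].max()) + frontier_margin
        new_logw[~pooled_vis] = np.minimum(
            np.maximum(new_logw[~pooled_vis], 0.0), ceil)
        np.clip(new_logw, 0.0, max_log_weight, out=new_logw)
        logw[:, :] = new_logw

    # summary of the pooled tail: the corner coverage recorded here is the
    # meaningful "did adaptation measure the corner weights" signal (a
    # single frozen block is far shorter than a corner entry time)
    history.append({"iteration": len(history), "phase": "pooled",
                    "flatness": float("nan"), "wl_f": 0.0,
                    "n_visited": int((tail_counts > 0).sum()),
                    "corner_00": int(tail_counts[0, 0]),
                    "corner_max": int(tail_counts[-1, -1]),
                    "acceptance": float("nan")})

    # frozen diagnostic block: the convergence check
    flat, c_ok, _ = _block("frozen", 0.0, block_steps, seed + 900_000)
    converged = flat >= flatness_target and c_ok
    if not converged:
        logger.warning("adapt_weights: frozen diagnostic: diagonal flatness "
                       "%.3f (target %.2f, corners ok: %s)", flat,
                       flatness_target, c_ok)
    return WeightTable(logw, converged=converged, history=history)


# ---------------------------------------------------------------------------
# Stages 2+3: equilibration and production
# ---------------------------------------------------------------------------

def sample_biased(state: SystemState, inter: Interactions, params: EnergyParams,
                  move: MoveParams, weights: WeightTable,
                  bins: BinTable | None = None, *, n_steps: int = 1_000_000,
                  n_equilibration: int = 100_000, stride: int = 10,
                  seed: int | None = None, use_vmmc: bool = True) -> Histogram2D:
    """Equilibrate (discarded) then accumulate biased OP counts."""
    bins = bins or default_bin_table()
    if seed is None:
        seed = move.seed
    res = run_sampler(state, inter, params, move, n_steps,
                      log_weights=weights.log_weights.copy(), bins=bins,
                      n_equil=n_equilibration, stride=stride, seed=seed,
                      use_vmmc=use_vmmc)
    logger.info("sample_biased: %d steps, acc=%.2f, corners=(%d,%d)",
                n_steps, res.acceptance_rate, res.hist[0, 0], res.hist[-1, -1])
    return Histogram2D(counts=res.hist, n_samples=int(res.hist.sum()),
                       weight_table_ref=weights.table_hash, seed=res.seed,
                       traj_q_ex=res.traj_q_ex, traj_q_lig=res.traj_q_lig)


def unbias(hist: Histogram2D, weights: WeightTable) -> UnbiasedDistribution:
    """Remove the umbrella bias: P(cell) propto counts(cell) / w(cell)."""
    if hist.weight_table_ref != weights.table_hash:
        raise WeightMismatchError(
            f"histogram was sampled under table {hist.weight_table_ref}, "
            f"got table {weights.table_hash}")
    if hist.counts.sum() <= 0:
        raise ValueError("empty histogram cannot be unbiased")
    return UnbiasedDistribution(
        _unbias_counts(hist.counts, weights.log_weights))


def _unbias_counts(counts: np.ndarray, logw: np.ndarray) -> np.ndarray:
    # log-space for numerical safety at large weight ranges
    logp = np.full(counts.shape, -np.inf)
    vis = counts > 0
    logp[vis] = np.log(counts[vis]) - logw[vis]
    logp -= logp[vis].max()
    raw = np.exp(logp)
    return raw / raw.sum()


def interaction_free_energy(p: UnbiasedDistribution,
                            hist: Histogram2D | None = None,
                            weights: WeightTable | None = None, *,
                            n_boot: int = 200, n_blocks: int = 20,
                            seed: int = 0) -> FreeEnergyResult:
    """dG_int/RT = -ln(P(0,0)/P(max,max)), with block-bootstrap error.

    The error is computed when the production trajectory (``hist`` with
    recorded OP states) and its weight table are supplied.
    """
    p00 = p.p[0, 0]
    pmm = p.p[-1, -1]
    if p00 <= 0 or pmm <= 0:
        raise UnboundedEstimateError(
            "corner state never visited (P(0,0)=%g, P(max,max)=%g); "
            "sample longer or adapt weights further" % (p00, pmm))
    dg = -np.log(p00 / pmm)
    err = None
    n_samples = 0
    if hist is not None and hist.traj_q_ex is not None and weights is not None:
        if hist.weight_table_ref != weights.table_hash:
            raise WeightMismatchError("trajectory/weight table mismatch")
        err = _bootstrap_error(hist, weights, n_boot, n_blocks, seed)
        n_samples = hist.n_samples
    return FreeEnergyResult(dg_int=float(dg), diagonal_profile=diagonal_profile(p),
                            statistical_error=err, n_samples=n_samples,
                            seed=hist.seed if hist is not None else -1)


def _bootstrap_error(hist: Histogram2D, weights: WeightTable,
                     n_boot: int, n_blocks: int, seed: int) -> float | None:
    qe = np.asarray(hist.traj_q_ex, dtype=np.int64)
    ql = np.asarray(hist.traj_q_lig, dtype=np.int64)
    m = qe.shape[0]
    if m < n_blocks * 2:
        return None
    nq = hist.counts.shape[0]
    flat = qe * nq + ql
    edges_idx = np.linspace(0, m, n_blocks + 1).astype(int)
    block_hists = np.zeros((n_blocks, nq * nq), dtype=np.int64)
    for b in range(n_blocks):
        seg = flat[edges_idx[b]:edges_idx[b + 1]]
        block_hists[b] = np.bincount(seg, minlength=nq * nq)
    rng = np.random.default_rng(seed)
    w = weights.log_weights
    vals = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        counts = block_hists[pick].sum(axis=0).reshape(nq, nq)
        if counts[0, 0] == 0 or counts[-1, -1] == 0:
            continue
        pb = _unbias_counts(counts, w)
        vals.append(-np.log(pb[0, 0] / pb[-1, -1]))
    if len(vals) < max(10, n_boot // 4):
        return None
    return float(np.std(vals, ddof=1))


def diagonal_profile(p: UnbiasedDistribution) -> np.ndarray:
    """Free energy -ln P(q,q) along the diagonal, zeroed at the free corner.

    Cells with zero probability are reported as NaN gaps.
    """
    diag = np.diagonal(p.p).astype(float)
    prof = np.full_like(diag, np.nan)
    ok = diag > 0
    prof[ok] = -np.log(diag[ok])
    if diag[-1] > 0:
        prof -= prof[-1]
    return prof


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_capture_pipeline(probe: ProbeSpec, target: TargetSpec, config,
                         out_dir=None) -> FreeEnergyResult:
    """Three-stage umbrella run for one probe/target pair.

    ``config`` is a :class:`lassocap.io.RunConfig` (or any object with the
    same attributes).  All intermediates (weights, histogram, unbiased
    distribution, result, resolved config) are persisted when ``out_dir``
    is given.
    """
    t0 = time.time()
    params: EnergyParams = config.energy
    move: MoveParams = config.move
    bins: BinTable = config.bins
    seed = int(config.seed)
    box = config.box_side
    if box is None:
        contour = params.bond_r0 * (max(probe.length, len(target.sequence)) - 1)
        box = 1.2 * contour
    state = init_configuration(probe, target, box, seed, params)
    inter = interactions_from_specs(probe, target)
    use_vmmc = config.sampler == "vmmc"

    logger.info("pipeline: %d probe + %d target beads, box=%.1f nm, seed=%d",
                probe.length, len(target.sequence), box, seed)
    # Weight adaptation occasionally lands in a table with an absorbing
    # artifact (the frozen diagnostic block then misses a corner state);
    # retry with fresh adaptation seeds -- a deterministic schedule, so the
    # pipeline remains reproducible for a given config seed.
    max_attempts = 4
    fe = None
    for attempt in range(max_attempts):
        if attempt > 0:
            # fresh initial configuration too: a pathological state (for
            # example a conformation wedged behind an unweighted barrier)
            # would otherwise be inherited by every retry
            state = init_configuration(probe, target, box,
                                       seed + 17 * attempt, params)
        wt = adapt_weights(state, inter, params, move, bins,
                           flatness_target=config.flatness_target,
                           block_steps=config.adapt_block_steps,
                           iteration_budget=config.adapt_iterations,
                           seed=seed + 1 + 40 * attempt, use_vmmc=use_vmmc)
        pooled = next((h for h in reversed(wt.history)
                       if h.get("phase") == "pooled"), {})
        corners_seen = pooled.get("corner_00", 0) > 0 and \
            pooled.get("corner_max", 0) > 0
        if not corners_seen and attempt < max_attempts - 1:
            logger.warning("pipeline: adaptation attempt %d missed a corner "
                           "state in its diagnostic block; retrying", attempt)
            continue
        if getattr(config, "channel_penalty", 0.0) > 0:
            wt = wt.with_channel(config.channel_width,
                                 config.channel_penalty)
        t1 = time.time()
        hist = sample_biased(state, inter, params, move, wt, bins,
                             n_steps=config.production_steps,
                             n_equilibration=config.equil_steps,
                             stride=config.stride,
                             seed=seed + 2 + 40 * attempt,
                             use_vmmc=use_vmmc)
        t2 = time.time()
        p = unbias(hist, wt)
        try:
            fe = interaction_free_energy(p, hist, wt, seed=seed + 3)
            break
        except UnboundedEstimateError:
            if attempt == max_attempts - 1:
                raise
            logger.warning("pipeline: production attempt %d missed a corner "
                           "state; re-adapting", attempt)
    assert fe is not None
    t3 = time.time()
    logger.info("pipeline done: dG_int=%.3f RT (err=%s); stages %.1f/%.1f/%.1f s",
                fe.dg_int, fe.statistical_error, t1 - t0, t2 - t1, t3 - t2)
    if out_dir is not None:
        from . import io as _io
        _io.persist_pipeline(out_dir, config, wt, hist, p, fe,
                             stage_seconds=(t1 - t0, t2 - t1, t3 - t2))
    return fe
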