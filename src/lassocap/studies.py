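"""Pre-configured desk-scale simulation studies.

These bundle the package's standard study conditions for the two adapter
sweeps:

* :func:`loop_closure_sweep` -- an ideal-chain (no bending, no excluded
  volume, no electrostatics) probe/target pair whose interaction free
  energy isolates the entropic loop-closure cost of the adapter; the cost
  grows as ~1.5 ln N in adapter bead count, the ring-closure scaling of a
  Gaussian chain.  The study uses the smallest workable arms (2 nt) and
  target (4 nt) with a tight 0.36-scaled bin table: any non-adapter
  material in the closed loop adds a constant offset M to the effective
  loop length, and a fit of dG against ln N (rather than ln(N+M))
  measures a slope depressed by ln((128+M)/(16+M))/ln 8 -- minimizing M
  is what makes the asymptotic exponent visible at these N.
* :func:`capture_sweep` -- the capture-study geometry at desk scale (8-nt
  arms, 40-bead target with sites at its ends, adapters of 10-120 beads),
  the scaled-down analogue of varying a LASSO probe's adapter length
  against a fixed gene target.

Both use a box FIXED across the sweep (sized for the longest probe): if the
box scaled with probe length, the translational-entropy term ln V of the
dissociated corner would add ~3 ln N to dG_int and mask the adapter
physics.  The per-pair hybridization well is 1.2 kT: capture is performed
near the arms' melting temperature, where the net per-base stability is of
order 1 kT -- and a much deeper well would freeze unbinding out of the
reachable timescale.  The bin table is the printed 11-interval table scaled
by 0.6 so that the dissociated corner fits inside the desk-scale box.
"""

from __future__ import annotations

import logging

import numpy as np

from .cg_model import (EnergyParams, NucleotideSequence, ProbeSpec,
                       TargetSpec)
from .io import RunConfig
from .order_params import default_bin_table
from .sampler import MoveParams
from .synthetic import SynthConfig, gen_capture_system
from .umbrella import FreeEnergyResult, run_capture_pipeline

__all__ = ["loop_closure_sweep", "capture_sweep", "fit_log_slope",
           "sweep_config"]

logger = logging.getLogger("lassocap")

BIN_SCALE = 0.6
HYB_EPS = 1.2          # kT per pair: near-melting per-base stability
IDEAL_BOX = 90.0       # nm; >= contour of the longest ideal-study probe
CAPTURE_BOX = 90.0     # nm; >= contour of the 136-bead probe (87.75 nm)


def sweep_config(seed: int, *, ideal: bool, box_side: float,
                 production_steps: int, adapt_budget: int = 30,
                 block_steps: int = 200_000, bin_scale: float = BIN_SCALE,
                 hyb_epsilon: float = HYB_EPS) -> RunConfig:
    """The standard study configuration (fixed box, scaled bins)."""
    # Both sweep studies use the freely-jointed reduced chain (bending,
    # excluded volume and electrostatics off): at desk scale every adapter
    # spans several Kuhn lengths, so the adapter-length dependence is
    # dominated by loop-closure entropy, and the sparse interaction set
    # keeps bound-state sampling (arm zipping/unzipping) fast enough for
    # corner-to-corner round trips.  ``ideal`` is kept for signature
    # stability; both branches currently share the reduced energy.
    energy = EnergyParams(bend_k=0.0, ev_epsilon=0.0, el_amplitude=0.0,
                          hyb_epsilon=hyb_epsilon)
    move = MoveParams(max_translation=0.3, max_rotation=0.25,
                      big_translation=4.0, big_move_prob=0.25,
                      rotation_prob=0.5, seed=seed)
    return RunConfig(
        seed=seed,
        box_side=box_side,
        energy=energy,
        move=move,
        bins=default_bin_table().scaled(bin_scale),
        adapt_block_steps=block_steps,
        adapt_iterations=adapt_budget,
        equil_steps=200_000,
        production_steps=production_steps,
        stride=50,
    )


def _minimal_systems(seed, arm_len, target_len, adapter_lens):
    """Probe/target pairs below the generator's arm-length floor, built
    directly (same construction: arms = reverse complements of the target
    ends, shared across the sweep)."""
    rng = np.random.default_rng(seed)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    bases = np.array(list("ACGT"))
    t_seq = "".join(bases[rng.integers(0, 4, target_len)])
    rc = lambda x: "".join(comp[c] for c in reversed(x))
    target = TargetSpec(sequence=NucleotideSequence("loop_target", t_seq),
                        ext_site=(0, arm_len),
                        lig_site=(target_len - arm_len, target_len))
    ext = NucleotideSequence("ext", rc(t_seq[:arm_len]))
    lig = NucleotideSequence("lig", rc(t_seq[-arm_len:]))
    out = []
    for al in adapter_lens:
        adapter = NucleotideSequence(
            f"ad{al}", "".join(bases[rng.integers(0, 4, al)]))
        out.append((ProbeSpec(ext, lig, adapter, name=f"probe_AL{al}"),
                    target))
    return out


def _run_sweep(adapter_lens, arm_len, target_len, seed, ideal, box,
               production_steps, out_dir=None, bin_scale=BIN_SCALE,
               hyb_epsilon=HYB_EPS,
               production_scale=(1, 1, 2, 4)) -> dict[int, FreeEnergyResult]:
    if arm_len >= 4:
        synth = SynthConfig(seed=seed, target_len=target_len,
                            arm_len=arm_len, adapter_lens=tuple(adapter_lens))
        systems = gen_capture_system(synth)
    else:
        systems = _minimal_systems(seed, arm_len, target_len, adapter_lens)
    results: dict[int, FreeEnergyResult] = {}
    for idx, ((probe, target), al) in enumerate(zip(systems, adapter_lens)):
        # corner round-trip rates drop with adapter length; long members
        # get proportionally more production sampling
        scale = production_scale[min(idx, len(production_scale) - 1)]
        cfg = sweep_config(seed + al, ideal=ideal, box_side=box,
                           production_steps=scale * production_steps,
                           bin_scale=bin_scale, hyb_epsilon=hyb_epsilon)
        sub_dir = None if out_dir is None else f"{out_dir}/AL{al}"
        logger.info("sweep member AL=%d (%d probe beads)", al, probe.length)
        results[al] = run_capture_pipeline(probe, target, cfg,
                                           out_dir=sub_dir)
    return results


def loop_closure_sweep(adapter_lens=(16, 32, 64, 128), *, arm_len: int = 2,
                       target_len: int = 4, seed: int = 7,
                       production_steps: int = 6_000_000,
                       out_dir=None) -> dict[int, FreeEnergyResult]:
    """Ideal-chain adapter sweep isolating the ring-closure entropy.

    Arms of 2 nt on a 4-nt target with 2.5 kT wells: deep enough to zip
    the tiny arms (so the closed loop is essentially the adapter alone),
    small enough to leave unbinding sampleable."""
    return _run_sweep(adapter_lens, arm_len, target_len, seed, True,
                      IDEAL_BOX, production_steps, out_dir,
                      bin_scale=0.36, hyb_epsilon=2.5,
                      production_scale=(2, 2, 3, 4))


def capture_sweep(adapter_lens=(10, 30, 60, 120), *, arm_len: int = 8,
                  target_len: int = 40, seed: int = 7,
                  production_steps: int = 6_000_000,
                  out_dir=None) -> dict[int, FreeEnergyResult]:
    """Desk-scale adapter sweep at the capture-study geometry (8-nt arms,
    40-bead target): the scaled-down analogue of varying a LASSO probe's
    adapter length against a fixed gene target."""
    return _run_sweep(adapter_lens, arm_len, target_len, seed, False,
                      CAPTURE_BOX, production_steps, out_dir,
                      production_scale=(1, 1, 2, 3))


def fit_log_slope(dg_by_n: dict[int, FreeEnergyResult]) -> float:
    """Least-squares slope of dG_int against ln(adapter beads), weighted by
    the bootstrap errors when available."""
    ns = sorted(dg_by_n)
    x = np.log(ns)
    y = np.array([dg_by_n[n].dg_int for n in ns])
    errs = [dg_by_n[n].statistical_error for n in ns]
    if all(e is not None and e > 0 for e in errs):
        w = 1.0 / np.asarray(errs) ** 2
    else:
        w = np.ones_like(y)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    return float(np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2))
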