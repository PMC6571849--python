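"""Synthetic inputs with controlled ground truth.

Desk-scale stand-ins for the experimental study design: probe/target pairs
whose arms are exact reverse complements of the target ends (an adapter
sweep sharing identical arms, mirroring the real 54/242/442/788-nt adapter
series at reduced length), overdispersed read-count tables with a known
target-vs-off-target enrichment, and reference polymer ensembles (freely
jointed and discrete worm-like chains) with closed-form statistics for
validating the sampler and force-field calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .cg_model import NucleotideSequence, ProbeSpec, SpecError, TargetSpec

__all__ = [
    "SynthConfig", "gen_capture_system", "gen_read_table", "gen_ideal_chain",
    "gen_wlc_chain", "fjc_mean_square_r", "wlc_mean_cos", "wlc_mean_square_r",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the desk-scale study conditions."""

    seed: int = 0
    target_len: int = 40             # nt
    arm_len: int = 8                 # nt
    adapter_lens: tuple[int, ...] = (10, 30, 60, 120)
    n_targets: int = 40
    n_offtargets: int = 40
    true_enrichment: float = 10.0
    dispersion: float = 0.3          # NB: var = mu + dispersion * mu^2
    mean_depth: float = 100.0        # reads per kilobase of sequence
    length_range: tuple[int, int] = (400, 1500)   # nt, off/target lengths
    probe_propensities: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.target_len <= 0 or self.arm_len <= 0:
            raise ValueError("lengths must be positive")
        if self.true_enrichment <= 0 or self.dispersion <= 0:
            raise ValueError("true_enrichment and dispersion must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def gen_capture_system(cfg: SynthConfig):
    """One (ProbeSpec, TargetSpec) per adapter length, sharing identical arms.

    The target is random; the extension arm is the reverse complement of the
    target's first ``arm_len`` bases and the ligation arm of its last
    ``arm_len`` bases, so every generated pair passes the complementarity
    validators by construction.
    """
    if cfg.arm_len < 4:
        raise SpecError("arm_len must be >= 4")
    if cfg.target_len < 2 * cfg.arm_len:
        raise SpecError("target_len must be at least twice arm_len")
    rng = np.random.default_rng(cfg.seed)
    t_seq = _random_seq(rng, cfg.target_len)
    a = cfg.arm_len
    target = TargetSpec(
        sequence=NucleotideSequence("synthetic_target", t_seq),
        ext_site=(0, a),
        lig_site=(cfg.target_len - a, cfg.target_len),
    )
    ext = NucleotideSequence("ext_arm", _revcomp(t_seq[:a]))
    lig = NucleotideSequence("lig_arm", _revcomp(t_seq[-a:]))
    systems = []
    for al in cfg.adapter_lens:
        adapter = None if al == 0 else NucleotideSequence(
            f"adapter_{al}", _random_seq(rng, al))
        probe = ProbeSpec(extension_arm=ext, ligation_arm=lig,
                          adapter=adapter, name=f"probe_AL{al}")
        systems.append((probe, target))
    return systems


def _nb_draw(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + dispersion*mu^2
    (gamma-Poisson mixture); dispersion -> 0 recovers Poisson."""
    if dispersion < 1e-8:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def gen_read_table(cfg: SynthConfig, poisson: bool = False) -> pd.DataFrame:
    """Read-count table with known target enrichment.

    Row means are ``mean_depth * enrichment_factor * length/1000`` with
    ``enrichment_factor = true_enrichment`` for targets (optionally scaled by
    a per-probe capture propensity) and 1 for off-targets; counts are
    negative-binomial (``poisson=True`` drops the overdispersion).  Sequence
    lengths are uniform over ``length_range``.
    """
    rng = np.random.default_rng(cfg.seed)
    probes = [f"probe_AL{al}" for al in cfg.adapter_lens]
    props = cfg.probe_propensities
    if props is not None and len(props) != len(probes):
        raise ValueError("probe_propensities must match adapter_lens")
    rows = []
    lo, hi = cfg.length_range
    for kind, n, base_factor in (("target", cfg.n_targets, cfg.true_enrichment),
                                 ("offtarget", cfg.n_offtargets, 1.0)):
        lengths = rng.integers(lo, hi + 1, n)
        for i in range(n):
            pid = probes[i % len(probes)]
            factor = base_factor
            if kind == "target" and props is not None:
                factor = base_factor * props[i % len(probes)]
            mu = cfg.mean_depth * factor * lengths[i] / 1000.0
            reads = int(_nb_draw(rng, np.array([mu]),
                                 0.0 if poisson else cfg.dispersion)[0])
            rows.append((f"{kind}_{i}", int(lengths[i]), reads,
                         kind == "target", pid))
    return pd.DataFrame(rows, columns=["sequence_id", "length_nt", "reads",
                                       "is_target", "probe_id"])


# ---------------------------------------------------------------------------
# Reference polymers
# ---------------------------------------------------------------------------

def gen_ideal_chain(n_beads: int, bond_r0: float, seed: int,
                    n_samples: int = 1) -> np.ndarray:
    """Freely jointed chains with fixed bond length.

    Returns (n_samples, n_beads, 3); exact mean-squared end-to-end distance
    is ``(n_beads - 1) * bond_r0**2``.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_samples, n_beads - 1, 3))
    steps *= bond_r0 / np.linalg.norm(steps, axis=2, keepdims=True)
    pos = np.zeros((n_samples, n_beads, 3))
    pos[:, 1:] = np.cumsum(steps, axis=1)
    return pos


def fjc_mean_square_r(n_beads: int, bond_r0: float) -> float:
    return (n_beads - 1) * bond_r0 ** 2


def _bond_length_moments(bond_k: float, bond_r0: float):
    """<b> and <b^2> under p(b) propto b^2 exp(-k/2 (b-r0)^2)."""
    sig = 1.0 / math.sqrt(bond_k)
    lo, hi = max(1e-9, bond_r0 - 8 * sig), bond_r0 + 8 * sig
    z, _ = quad(lambda b: b**2 * math.exp(-0.5 * bond_k * (b - bond_r0)**2), lo, hi)
    m1, _ = quad(lambda b: b**3 * math.exp(-0.5 * bond_k * (b - bond_r0)**2), lo, hi)
    m2, _ = quad(lambda b: b**4 * math.exp(-0.5 * bond_k * (b - bond_r0)**2), lo, hi)
    return m1 / z, m2 / z


def wlc_mean_cos(bend_k: float) -> float:
    """<cos theta> = coth(k) - 1/k for the Kratky-Porod bending energy."""
    if bend_k == 0:
        return 0.0
    return 1.0 / math.tanh(bend_k) - 1.0 / bend_k


def wlc_mean_square_r(n_beads: int, bond_k: float, bond_r0: float,
                      bend_k: float) -> float:
    """Exact <R^2> of the discrete worm-like chain with fluctuating bonds.

    Bond directions are a Markov chain with correlation c = <cos theta> per
    step, independent of the (harmonically distributed) bond lengths:
    ``<R^2> = n <b^2> + 2 <b>^2 sum_{i<j} c^(j-i)``.
    """
    n = n_beads - 1
    b1, b2 = _bond_length_moments(bond_k, bond_r0)
    c = wlc_mean_cos(bend_k)
    if abs(c) < 1e-15:
        cross = 0.0
    else:
        # sum_{i<j<=n} c^(j-i) = sum_{k=1}^{n-1} (n-k) c^k
        cross = sum((n - k) * c**k for k in range(1, n))
    return n * b2 + 2.0 * b1**2 * cross


def gen_wlc_chain(n_beads: int, bond_k: float, bond_r0: float, bend_k: float,
                  seed: int, n_samples: int = 1) -> np.ndarray:
    """Direct equilibrium draws of the bonded (bond + Kratky-Porod) model.

    Bond lengths are sampled from their 1-D Boltzmann density by rejection;
    each successive direction from p(cos t) propto exp(bend_k cos t) by
    inverse CDF, azimuth uniform.  Exact Gibbs samples, independent of the
    Monte Carlo engine.
    """
    rng = np.random.default_rng(seed)
    nb = n_beads - 1
    sig = 1.0 / math.sqrt(bond_k)

    # bond lengths: rejection against the Gaussian envelope
    lens = np.empty((n_samples, nb))
    need = n_samples * nb
    got = 0
    flat = lens.reshape(-1)
    bmax = bond_r0 + 8 * sig
    while got < need:
        cand = rng.normal(bond_r0, sig, size=2 * (need - got))
        cand = cand[(cand > 0) & (cand < bmax)]
        accept = rng.random(cand.size) < (cand / bmax) ** 2
        take = cand[accept][: need - got]
        flat[got:got + take.size] = take
        got += take.size

    # directions
    dirs = np.empty((n_samples, nb, 3))
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    dirs[:, 0] = v
    for i in range(1, nb):
        if bend_k == 0:
            u = rng.normal(size=(n_samples, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            dirs[:, i] = u
            continue
        r = rng.random(n_samples)
        ct = np.log(np.exp(-bend_k) + r * (np.exp(bend_k) - np.exp(-bend_k))) / bend_k
        st = np.sqrt(np.maximum(0.0, 1.0 - ct**2))
        phi = rng.uniform(0, 2 * np.pi, n_samples)
        prev = dirs[:, i - 1]
        # orthonormal frame around prev
        a = np.where(np.abs(prev[:, :1]) < 0.9,
                     np.tile([1.0, 0.0, 0.0], (n_samples, 1)),
                     np.tile([0.0, 1.0, 0.0], (n_samples, 1)))
        e1 = np.cross(prev, a)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(prev, e1)
        dirs[:, i] = (ct[:, None] * prev
                      + st[:, None] * (np.cos(phi)[:, None] * e1
                                       + np.sin(phi)[:, None] * e2))
    steps = dirs * lens[:, :, None]
    pos = np.zeros((n_samples, n_beads, 3))
    pos[:, 1:] = np.cumsum(steps, axis=1)
    return pos
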