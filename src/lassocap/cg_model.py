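"""Coarse-grained probe/target model.

One bead per nucleotide.  A LASSO (long-adapter single-stranded
oligonucleotide) probe is ``extension_arm + adapter + ligation_arm``; the two
arms are exact reverse complements of two disjoint sites on the target
strand.  The reduced energy function has five terms:

* harmonic bonds between consecutive beads of a chain,
* Kratky--Porod bending ``k_bend * (1 - cos theta)`` (harmonic in the bend
  angle for small angles); ``k_bend`` sets the persistence length,
* purely repulsive truncated-and-shifted Lennard-Jones (WCA) excluded
  volume between all non-bonded bead pairs,
* screened electrostatic (Yukawa) repulsion with the Debye length implied
  by the Na+ concentration, truncated and shifted at twice the Debye length,
* a Go-like finite-range square well of depth ``hyb_epsilon`` between each
  designed arm base and its complementary target base (hybridization).

Energies are expressed in units of kT at the configured temperature;
distances in nm.  All pair distances use the minimum-image convention in a
periodic cubic box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq
from scipy.optimize import brentq

from . import _kernels as _k

__all__ = [
    "NucleotideSequence",
    "ProbeSpec",
    "TargetSpec",
    "EnergyParams",
    "SystemState",
    "Interactions",
    "SpecError",
    "MismatchError",
    "ConfigurationError",
    "build_probe",
    "find_arm_complements",
    "total_energy",
    "init_configuration",
    "debye_length_nm",
    "persistence_length",
    "bend_k_for_persistence",
]

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SpecError(ValueError):
    """Invalid probe/target specification."""


class MismatchError(SpecError):
    """Arm and target site are not complementary; carries offending positions."""

    def __init__(self, arm_name: str, positions: list[int]):
        self.arm_name = arm_name
        self.positions = positions
        super().__init__(
            f"{arm_name} arm is not the reverse complement of its target site; "
            f"mismatches at arm positions {positions}"
        )


class ConfigurationError(ValueError):
    """Invalid geometric/thermodynamic configuration (e.g. box too small)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the strict ACGT alphabet."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise SpecError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise SpecError(
                f"sequence {self.id!r} contains non-ACGT characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> str:
        return str(Seq(self.seq).reverse_complement())


@dataclass(frozen=True)
class ProbeSpec:
    """extension arm (5') + adapter + ligation arm (3')."""

    extension_arm: NucleotideSequence
    ligation_arm: NucleotideSequence
    adapter: NucleotideSequence | None
    name: str = "probe"

    def __post_init__(self):
        if len(self.extension_arm) == 0 or len(self.ligation_arm) == 0:
            raise SpecError("probe arms must be non-empty")

    @property
    def adapter_length(self) -> int:
        return 0 if self.adapter is None else len(self.adapter)

    @property
    def length(self) -> int:
        return len(self.extension_arm) + self.adapter_length + len(self.ligation_arm)

    @property
    def sequence(self) -> str:
        mid = "" if self.adapter is None else self.adapter.seq
        return self.extension_arm.seq + mid + self.ligation_arm.seq


@dataclass(frozen=True)
class TargetSpec:
    """Target strand with the two arm-complementary sites (0-based, half-open)."""

    sequence: NucleotideSequence
    ext_site: tuple[int, int]
    lig_site: tuple[int, int]

    def __post_init__(self):
        n = len(self.sequence)
        for name, (lo, hi) in (("ext_site", self.ext_site), ("lig_site", self.lig_site)):
            if not (0 <= lo < hi <= n):
                raise SpecError(f"{name}=({lo},{hi}) out of bounds for target length {n}")
        a, b = sorted([self.ext_site, self.lig_site])
        if a[1] > b[0]:
            raise SpecError("ext_site and lig_site overlap")


def debye_length_nm(salt_Na_mM: float) -> float:
    """Debye screening length 0.304/sqrt(I[M]) nm for monovalent salt."""
    if salt_Na_mM <= 0:
        raise ValueError("salt concentration must be positive")
    return 0.304 / math.sqrt(salt_Na_mM / 1000.0)


@dataclass(frozen=True)
class EnergyParams:
    """Force-field parameters; energies in kT, lengths in nm.

    ``debye_length`` is derived from ``salt_Na_mM`` when left as None and is
    checked for consistency with the screening formula otherwise.
    """

    bond_k: float = 100.0        # kT/nm^2
    bond_r0: float = 0.65        # nm, ssDNA rise per base
    bend_k: float = 2.8          # kT; persistence length ~1.5 nm at 300 mM Na+
    ev_sigma: float = 0.55       # nm
    ev_epsilon: float = 1.0      # kT
    hyb_epsilon: float = 3.0     # kT per designed complementary pair
    hyb_range: float = 0.85      # nm
    el_amplitude: float = 0.5    # kT*nm, Yukawa prefactor
    temperature: float = 338.15  # K (65 C capture temperature)
    salt_Na_mM: float = 300.0
    debye_length: float | None = None
    cap_energy: float = 100.0    # kT, finite cap on pair repulsion

    def __post_init__(self):
        for name in ("bond_k", "bond_r0", "ev_sigma", "hyb_range",
                     "temperature", "salt_Na_mM", "cap_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("bend_k", "ev_epsilon", "hyb_epsilon", "el_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lam = debye_length_nm(self.salt_Na_mM)
        if self.debye_length is None:
            object.__setattr__(self, "debye_length", lam)
        elif not math.isclose(self.debye_length, lam, rel_tol=1e-6):
            raise ValueError(
                f"debye_length={self.debye_length} inconsistent with "
                f"salt_Na_mM={self.salt_Na_mM} (expected {lam:.6f} nm)"
            )

    def with_(self, **kw) -> "EnergyParams":
        if "salt_Na_mM" in kw and "debye_length" not in kw:
            kw["debye_length"] = None
        return replace(self, **kw)

    def pack(self, box_side: float) -> np.ndarray:
        """Flatten to the parameter vector the numba kernels consume."""
        return np.array(
            [self.bond_k, self.bond_r0, self.bend_k, self.ev_sigma,
             self.ev_epsilon, self.hyb_epsilon, self.hyb_range,
             self.el_amplitude, self.debye_length, 2.0 * self.debye_length,
             self.cap_energy, box_side],
            dtype=np.float64,
        )


def persistence_length(params: EnergyParams) -> float:
    """Persistence length (nm) implied by the Kratky-Porod bending constant."""
    k = params.bend_k
    if k <= 0:
        return 0.0
    c = 1.0 / math.tanh(k) - 1.0 / k  # <cos theta>
    return -params.bond_r0 / math.log(c)


def bend_k_for_persistence(lp_nm: float, bond_r0: float = 0.65) -> float:
    """Bending constant (kT) giving persistence length ``lp_nm``."""
    c_target = math.exp(-bond_r0 / lp_nm)

    def f(k):
        return (1.0 / math.tanh(k) - 1.0 / k) - c_target

    return brentq(f, 1e-6, 1e4)


@dataclass
class SystemState:
    """Bead coordinates of every chain in a periodic cube.

    Chains are stored concatenated: beads ``[0, n_probe)`` belong to the
    probe, the rest to the target (toy systems may declare more chains via
    ``chain_id`` directly).  Coordinates are kept wrapped into
    ``[0, box_side)^3``; all energies/distances are minimum-image, so
    wrapping never changes observables.
    """

    pos: np.ndarray          # (N, 3) float64, wrapped
    chain_id: np.ndarray     # (N,) int64
    box_side: float
    rng: np.random.Generator

    def __post_init__(self):
        self.pos = np.ascontiguousarray(np.asarray(self.pos, dtype=np.float64))
        self.chain_id = np.ascontiguousarray(np.asarray(self.chain_id, dtype=np.int64))
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ConfigurationError("pos must have shape (N, 3)")
        if self.chain_id.shape[0] != self.pos.shape[0]:
            raise ConfigurationError("chain_id length must match bead count")
        if self.box_side <= 0:
            raise ConfigurationError("box_side must be positive")
        self.wrap()

    def wrap(self) -> None:
        np.mod(self.pos, self.box_side, out=self.pos)

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    @property
    def n_probe(self) -> int:
        return int(np.searchsorted(self.chain_id, 1))

    @property
    def probe_positions(self) -> np.ndarray:
        return self.pos[: self.n_probe]

    @property
    def target_positions(self) -> np.ndarray:
        return self.pos[self.n_probe:]

    def copy(self) -> "SystemState":
        g = np.random.default_rng()
        g.bit_generator.state = self.rng.bit_generator.state
        return SystemState(self.pos.copy(), self.chain_id.copy(), self.box_side, g)


@dataclass(frozen=True)
class Interactions:
    """Interaction topology: hybridization partners and per-arm pair lists.

    ``hyb_partner[i]`` is the global bead index Go-paired with bead ``i`` or
    -1; ``ext_pairs``/``lig_pairs`` are ``(m, 2)`` arrays of (probe bead,
    target bead) global indices used for the order-parameter distances.
    """

    hyb_partner: np.ndarray
    ext_pairs: np.ndarray
    lig_pairs: np.ndarray

    @staticmethod
    def from_pairs(n_beads: int, ext_pairs, lig_pairs) -> "Interactions":
        ext = np.asarray(ext_pairs, dtype=np.int64).reshape(-1, 2)
        lig = np.asarray(lig_pairs, dtype=np.int64).reshape(-1, 2)
        partner = np.full(n_beads, -1, dtype=np.int64)
        for a, b in np.vstack([ext, lig]):
            partner[a] = b
            partner[b] = a
        return Interactions(partner, ext, lig)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_probe(spec: ProbeSpec) -> NucleotideSequence:
    """Concatenate extension arm + adapter + ligation arm into one strand."""
    return NucleotideSequence(id=spec.name, seq=spec.sequence)


def _site_pairs(arm: NucleotideSequence, site: tuple[int, int],
                target: NucleotideSequence, arm_offset: int, arm_name: str):
    lo, hi = site
    if hi - lo != len(arm):
        raise SpecError(
            f"{arm_name} arm length {len(arm)} does not match site width {hi - lo}"
        )
    pairs = []
    mismatches = []
    for k, base in enumerate(arm.seq):
        t_idx = hi - 1 - k  # antiparallel: arm 5'->3' maps site 3'->5'
        if _COMPLEMENT[base] != target.seq[t_idx]:
            mismatches.append(k)
        pairs.append((arm_offset + k, t_idx))
    if mismatches:
        raise MismatchError(arm_name, mismatches)
    return pairs


def find_arm_complements(probe: ProbeSpec, target: TargetSpec):
    """Designed base pairs per arm as (probe index, target index) lists.

    Pairing is antiparallel: arm position k (5'->3') pairs with target
    position ``site_hi - 1 - k``.  Raises :class:`MismatchError` if a site is
    not the exact reverse complement of its arm.
    """
    ext_pairs = _site_pairs(probe.extension_arm, target.ext_site,
                            target.sequence, 0, "extension")
    lig_offset = len(probe.extension_arm) + probe.adapter_length
    lig_pairs = _site_pairs(probe.ligation_arm, target.lig_site,
                            target.sequence, lig_offset, "ligation")
    return ext_pairs, lig_pairs


def interactions_from_specs(probe: ProbeSpec, target: TargetSpec) -> Interactions:
    ext_pairs, lig_pairs = find_arm_complements(probe, target)
    n = probe.length + len(target.sequence)
    off = probe.length
    ext = [(p, off + t) for p, t in ext_pairs]
    lig = [(p, off + t) for p, t in lig_pairs]
    return Interactions.from_pairs(n, ext, lig)


def total_energy(state: SystemState, probe: ProbeSpec, target: TargetSpec,
                 params: EnergyParams) -> float:
    """Total reduced energy (kT) of the two-strand system."""
    inter = interactions_from_specs(probe, target)
    return total_energy_system(state, inter, params)


def total_energy_system(state: SystemState, inter: Interactions,
                        params: EnergyParams) -> float:
    """Total energy for an arbitrary (possibly multi-chain) bead system."""
    P = params.pack(state.box_side)
    return float(_k.total_energy_arr(state.pos, state.chain_id,
                                     inter.hyb_partner, P))


def _grow_chain(rng, n, r0, box, start, existing, min_sep, max_tries=200):
    """Self-avoiding random-walk growth; returns (n,3) unwrapped coordinates."""
    pos = np.empty((n, 3))
    pos[0] = start
    for i in range(1, n):
        for attempt in range(max_tries):
            v = rng.normal(size=3)
            v *= r0 / np.linalg.norm(v)
            cand = pos[i - 1] + v
            prev = np.vstack([pos[:i], existing]) if len(existing) else pos[:i]
            d = prev - cand
            d -= box * np.round(d / box)
            if i == 1 or np.min(np.einsum("ij,ij->i", d[:-1], d[:-1])) > min_sep**2:
                pos[i] = cand
                break
        else:
            raise ConfigurationError("self-avoiding growth failed; box too crowded")
    return pos


def init_configuration(probe: ProbeSpec, target: TargetSpec, box_side: float,
                       seed: int, params: EnergyParams | None = None) -> SystemState:
    """Random self-avoiding initial placement of both strands in the box.

    Requires ``box_side`` at least the longer chain's contour length, so the
    box can geometrically contain either chain fully extended.
    """
    params = params or EnergyParams()
    n_p, n_t = probe.length, len(target.sequence)
    contour = params.bond_r0 * (max(n_p, n_t) - 1)
    if box_side < contour:
        raise ConfigurationError(
            f"box_side={box_side} nm smaller than max contour length {contour:.1f} nm"
        )
    rng = np.random.default_rng(seed)
    min_sep = 0.9 * params.ev_sigma if params.ev_epsilon > 0 else 0.3
    for _restart in range(50):
        try:
            p_pos = _grow_chain(rng, n_p, params.bond_r0, box_side,
                                rng.uniform(0, box_side, 3), np.empty((0, 3)), min_sep)
            t_pos = _grow_chain(rng, n_t, params.bond_r0, box_side,
                                rng.uniform(0, box_side, 3), p_pos, min_sep)
            break
        except ConfigurationError:
            continue
    else:  # pragma: no cover - essentially unreachable at the enforced box size
        raise ConfigurationError("could not place chains after 50 restarts")
    pos = np.vstack([p_pos, t_pos])
    chain_id = np.concatenate([np.zeros(n_p, dtype=np.int64),
                               np.ones(n_t, dtype=np.int64)])
    return SystemState(pos=pos, chain_id=chain_id, box_side=box_side, rng=rng)
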