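"""Sequencing-side enrichment statistics.

Capture efficiency of a probe library is quantified from read counts:

* RPKM (reads per kilobase per million mapped reads) per sequence,
* enrichment ratio = median target RPKM / median off-target RPKM,
* free-energy differences between probes from RPKM ratios,
  ``dG(A-B)/RT = -ln(RPKM_A / RPKM_B)``, with the zero reference placed at
  the probe with the largest RPKM (the most favourable adapter length),
* Pearson correlation between experimental and simulated dG series.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "READ_TABLE_COLUMNS", "validate_read_table",
    "rpkm", "rpkm_per_row", "enrichment_ratio", "dg_from_rpkm",
    "relative_dg", "pearson_r", "enrichment_summary",
]

READ_TABLE_COLUMNS = ("sequence_id", "length_nt", "reads", "is_target", "probe_id")


def validate_read_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a read-count table."""
    missing = [c for c in READ_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("read table is empty")
    if (table["length_nt"] <= 0).any():
        raise ValueError("length_nt must be positive")
    if (table["reads"] < 0).any():
        raise ValueError("reads must be non-negative")
    return table


def rpkm(reads_target: float, reads_lib: float, length_nt: float) -> float:
    """Reads per kilobase per million mapped reads.

    ``reads_target * 1e9 / (reads_lib * length_nt)``: the read count for one
    sequence normalized by library size (per million) and sequence length
    (per kilobase).  Every downstream quantity (ratios, log-ratios) is
    invariant to the constant.
    """
    if reads_lib <= 0:
        raise ValueError("library size must be positive")
    if length_nt <= 0:
        raise ValueError("sequence length must be positive")
    return reads_target * 1e9 / (reads_lib * length_nt)


def rpkm_per_row(table: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """RPKM for every row, with the whole table as the library."""
    validate_read_table(table)
    lib = float(table["reads"].sum()) + pseudocount * len(table)
    if lib <= 0:
        raise ValueError("library has zero total reads")
    return (table["reads"] + pseudocount) * 1e9 / (lib * table["length_nt"])


def enrichment_ratio(table: pd.DataFrame, pseudocount: float = 0.0) -> float:
    """median(target RPKM) / median(off-target RPKM).

    Median of an even-length stratum is the mean of the central pair (the
    numpy convention).  A zero off-target median raises with a hint to use
    the pseudocount option.
    """
    validate_read_table(table)
    vals = rpkm_per_row(table, pseudocount=pseudocount)
    is_t = table["is_target"].astype(bool)
    if not is_t.any() or is_t.all():
        raise ValueError("need at least one target and one off-target row")
    med_t = float(np.median(vals[is_t]))
    med_o = float(np.median(vals[~is_t]))
    if med_o <= 0:
        raise ValueError(
            "off-target median RPKM is zero; consider pseudocount=0.5")
    return med_t / med_o


def dg_from_rpkm(rpkm_a: float, rpkm_b: float) -> float:
    """Free-energy difference (RT units) between probes A and B:
    ``-ln(RPKM_A / RPKM_B)``; antisymmetric under swap."""
    if rpkm_a <= 0 or rpkm_b <= 0:
        raise ValueError("RPKM values must be positive (enable a pseudocount "
                         "upstream for zero counts)")
    # log difference rather than log of the ratio: antisymmetry is then
    # exact in floating point
    return math.log(rpkm_b) - math.log(rpkm_a)


def relative_dg(rpkms_per_probe: dict[str, float]) -> dict[str, float]:
    """Per-probe free energy relative to the best probe.

    The probe with the largest RPKM defines the zero of free energy (ties
    all map to exactly 0); every other probe gets ``-ln(RPKM_p / max)``,
    which is >= 0 by construction.
    """
    if len(rpkms_per_probe) < 2:
        raise ValueError("need at least two probes")
    if any(v <= 0 for v in rpkms_per_probe.values()):
        raise ValueError("all RPKM values must be positive")
    best = max(rpkms_per_probe.values())
    out = {}
    for pid, v in rpkms_per_probe.items():
        out[pid] = 0.0 if v == best else -math.log(v / best)
    return out


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length series (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def enrichment_summary(table: pd.DataFrame, sim_dg: dict[str, float] | None = None,
                       pseudocount: float = 0.0) -> dict:
    """Tidy summary: per-probe median target RPKM, relative dG, enrichment
    ratio, and (when simulated dG per probe is supplied) the Pearson r
    between experimental and simulated relative free energies."""
    validate_read_table(table)
    vals = rpkm_per_row(table, pseudocount=pseudocount)
    tab = table.assign(rpkm=vals)
    targets = tab[tab["is_target"].astype(bool)]
    per_probe = targets.groupby("probe_id")["rpkm"].median().to_dict()
    summary = {
        "enrichment_ratio": enrichment_ratio(table, pseudocount=pseudocount),
        "median_target_rpkm_per_probe": per_probe,
    }
    if len(per_probe) >= 2:
        summary["dg_rel_per_probe"] = relative_dg(per_probe)
    if sim_dg is not None and len(per_probe) >= 3:
        common = sorted(set(per_probe) & set(sim_dg))
        if len(common) >= 3:
            exp_dg = relative_dg({p: per_probe[p] for p in common})
            summary["pearson_r"] = pearson_r(
                [exp_dg[p] for p in common], [sim_dg[p] for p in common])
            summary["probes_compared"] = common
    return summary
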