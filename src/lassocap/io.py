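"""File formats and run configuration.

FASTA for sequences; CSV for weight/histogram/distribution matrices (rows =
Qex) and read-count tables; JSON for results; YAML for the run config; and
the classic two-file oxDNA topology/configuration dialect for exporting
coordinates to standard viewers (visualization-grade: identity orientations,
zero velocities).  Every artifact written by a run embeds the config hash
and seed in its header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cg_model import EnergyParams, NucleotideSequence, SystemState
from .order_params import BinTable, default_bin_table
from .sampler import MoveParams

__all__ = [
    "FastaParseError", "ConfigError", "RunConfig",
    "read_fasta", "write_fasta",
    "write_matrix_csv", "read_matrix_csv",
    "read_read_table", "write_read_table",
    "write_oxdna_files", "read_oxdna_configuration",
    "persist_pipeline",
]

OXDNA_LENGTH_NM = 0.8518  # nm per oxDNA simulation length unit

_ALPHABET = frozenset("ACGT")


class FastaParseError(ValueError):
    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def read_fasta(path) -> list[NucleotideSequence]:
    """Parse FASTA records; IDs up to first whitespace, sequences uppercased.

    Rejects empty files, records without sequence, and any non-ACGT
    character (including U and ambiguity codes), reporting the line number.
    """
    records = []
    cur_id = None
    cur_seq: list[str] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            n_lines = lineno
            line = raw.strip()
            if not line or line.startswith(";"):  # ';' = comment line
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    records.append(_finish_record(cur_id, cur_seq, lineno))
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise FastaParseError("empty record id", lineno)
                cur_seq = []
            else:
                if cur_id is None:
                    raise FastaParseError("sequence data before any '>' header",
                                          lineno)
                seq = line.upper()
                bad = set(seq) - _ALPHABET
                if bad:
                    raise FastaParseError(
                        f"non-ACGT characters {sorted(bad)}", lineno)
                cur_seq.append(seq)
    if cur_id is not None:
        records.append(_finish_record(cur_id, cur_seq, n_lines))
    if not records:
        raise FastaParseError("no FASTA records found", max(n_lines, 1))
    return records


def _finish_record(rid, chunks, lineno) -> NucleotideSequence:
    seq = "".join(chunks)
    if not seq:
        raise FastaParseError(f"record {rid!r} has no sequence", lineno)
    return NucleotideSequence(rid, seq)


def write_fasta(path, records, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f";{header_comment}\n")
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Matrix / table CSV
# ---------------------------------------------------------------------------

def write_matrix_csv(path, matrix: np.ndarray, kind: str, **meta) -> None:
    """CSV matrix with row = Qex; metadata in '#' header lines."""
    lines = [f"kind={kind}"] + [f"{k}={v}" for k, v in sorted(meta.items())]
    np.savetxt(path, np.asarray(matrix), delimiter=",",
               header="\n".join(lines))


def read_matrix_csv(path):
    """Returns (matrix, metadata dict)."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if "=" in text:
                k, v = text.split("=", 1)
                meta[k.strip()] = v.strip()
    mat = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return mat, meta


def write_read_table(path, table: pd.DataFrame, **meta) -> None:
    with open(path, "w") as fh:
        for k, v in sorted(meta.items()):
            fh.write(f"# {k}={v}\n")
        table.to_csv(fh, index=False)


def read_read_table(path) -> pd.DataFrame:
    from .enrichment import validate_read_table
    table = pd.read_csv(path, comment="#")
    return validate_read_table(table)


# ---------------------------------------------------------------------------
# oxDNA export
# ---------------------------------------------------------------------------

def write_oxdna_files(state: SystemState, topology_path, configuration_path,
                      bases: str | None = None) -> None:
    """Write oxDNA-dialect topology + configuration for external viewers.

    Topology: ``N_nucleotides N_strands`` then one ``strand base 3'-neighbor
    5'-neighbor`` line per nucleotide.  Configuration: ``t``/``b``/``E``
    header lines then 15 columns per nucleotide (position in oxDNA length
    units, identity orientation vectors, zero velocities).  Positions only;
    orientations are placeholders.
    """
    n = state.n_beads
    chain = state.chain_id
    n_strands = len(np.unique(chain))
    if bases is None:
        bases = "A" * n
    if len(bases) != n:
        raise ValueError("bases string must have one character per bead")
    try:
        with open(topology_path, "w") as fh:
            fh.write(f"{n} {n_strands}\n")
            for i in range(n):
                prev3 = i - 1 if i > 0 and chain[i - 1] == chain[i] else -1
                next5 = i + 1 if i < n - 1 and chain[i + 1] == chain[i] else -1
                fh.write(f"{chain[i] + 1} {bases[i]} {prev3} {next5}\n")
        box_lu = state.box_side / OXDNA_LENGTH_NM
        with open(configuration_path, "w") as fh:
            fh.write("t = 0\n")
            fh.write(f"b = {box_lu:.8f} {box_lu:.8f} {box_lu:.8f}\n")
            fh.write("E = 0 0 0\n")
            for i in range(n):
                x, y, z = state.pos[i] / OXDNA_LENGTH_NM
                fh.write(f"{x:.8f} {y:.8f} {z:.8f} "
                         "1 0 0 0 0 1 0 0 0 0 0 0\n")
    except OSError as exc:
        raise OSError(f"failed writing oxDNA files "
                      f"({topology_path}, {configuration_path}): {exc}") from exc


def read_oxdna_configuration(configuration_path):
    """Read back our own configuration export; returns (positions_nm, box_nm)."""
    with open(configuration_path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    box = float(lines[1].split("=")[1].split()[0]) * OXDNA_LENGTH_NM
    rows = [list(map(float, ln.split()[:3])) for ln in lines[3:]]
    return np.asarray(rows) * OXDNA_LENGTH_NM, box


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one capture-pipeline run.

    Schema-validated: unknown keys are rejected, nested sections map onto
    :class:`EnergyParams`, :class:`MoveParams` and :class:`BinTable`.
    ``box_side=None`` means 1.2x the longer strand's contour length.
    """

    seed: int = 0
    box_side: float | None = None
    sampler: str = "vmmc"
    energy: EnergyParams = field(default_factory=EnergyParams)
    move: MoveParams = field(default_factory=MoveParams)
    bins: BinTable = field(default_factory=default_bin_table)
    adapt_block_steps: int = 200_000
    adapt_iterations: int = 20
    flatness_target: float = 0.6
    equil_steps: int = 100_000
    production_steps: int = 1_000_000
    stride: int = 10
    # production sampling is confined to the diagonal reaction channel
    # |Qex - Qlig| <= channel_width by an extra weight penalty; 0 disables
    channel_width: int = 2
    channel_penalty: float = 2.0
    probe_fasta: str | None = None
    target_fasta: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.sampler not in ("vmmc", "metropolis"):
            raise ConfigError(f"unknown sampler {self.sampler!r}")
        for key in ("adapt_block_steps", "adapt_iterations", "equil_steps",
                    "production_steps", "stride"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        if not (0 < self.flatness_target <= 1):
            raise ConfigError("flatness_target must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            if "energy" in d and isinstance(d["energy"], dict):
                d["energy"] = EnergyParams(**d["energy"])
            if "move" in d and isinstance(d["move"], dict):
                d["move"] = MoveParams(**d["move"])
            if "bins" in d and isinstance(d["bins"], (list, tuple)):
                d["bins"] = BinTable(tuple(d["bins"]))
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["energy"] = dataclasses.asdict(self.energy)
        d["move"] = dataclasses.asdict(self.move)
        d["bins"] = list(self.bins.edges)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def persist_pipeline(out_dir, config: RunConfig, weight_table, hist, p, fe,
                     stage_seconds=(0.0, 0.0, 0.0)) -> None:
    """Write every pipeline intermediate with config hash + seed provenance."""
    os.makedirs(out_dir, exist_ok=True)
    meta = {"config_hash": config.config_hash, "seed": config.seed,
            "bin_table_hash": config.bins.table_hash}
    write_matrix_csv(os.path.join(out_dir, "weights.csv"),
                     weight_table.weights, "weight_table",
                     converged=weight_table.converged, **meta)
    write_matrix_csv(os.path.join(out_dir, "histogram.csv"),
                     hist.counts, "histogram2d", n_samples=hist.n_samples,
                     weights_hash=hist.weight_table_ref, **meta)
    write_matrix_csv(os.path.join(out_dir, "distribution.csv"),
                     p.p, "unbiased_distribution", **meta)
    if hist.traj_q_ex is not None:
        traj = pd.DataFrame({"q_ex": hist.traj_q_ex, "q_lig": hist.traj_q_lig})
        with open(os.path.join(out_dir, "op_trajectory.csv"), "w") as fh:
            for k, v in sorted(meta.items()):
                fh.write(f"# {k}={v}\n")
            traj.to_csv(fh, index=False)
    result = {
        "dg_int_RT": fe.dg_int,
        "statistical_error_RT": fe.statistical_error,
        "diagonal_profile_RT": [None if np.isnan(v) else float(v)
                                for v in fe.diagonal_profile],
        "n_samples": fe.n_samples,
        "stage_seconds": list(stage_seconds),
        **meta,
    }
    with open(os.path.join(out_dir, "result.json"), "w") as fh:
        json.dump(result, fh, indent=2)
    config.to_yaml(os.path.join(out_dir, "config.yaml"))
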