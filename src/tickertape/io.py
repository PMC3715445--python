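"""File formats, configuration, and seed management.

Interchange formats are deliberately plain text:

* misincorporation counts — TSV with columns ``pos``, ``n_templates``,
  ``n_misinc`` and ``#``-prefixed comment headers carrying provenance
  (config hash, seed).  This table is the hand-off point from real
  sequencing pipelines: upstream alignment against the known template is
  expected to emit it, and this package neither aligns nor assembles.
* concentration traces — TSV with columns ``t_start_ms``, ``concentration``.
* templates — FASTA (first record fixes the template length).

Configuration is YAML/JSON with explicit units in key names (``tau_e_ms``)
and no hidden defaults for the link function: ``e0`` and ``m`` must always
be stated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .kinetics import PolymeraseKinetics, StartTimeModel, TimeGrid
from .link import ConcentrationTrace, LinearCMLF
from .simulate import MisincorporationTable

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_trace_tsv",
    "write_trace_tsv",
    "read_fasta_length",
    "RunConfig",
    "config_hash",
    "spawn_rngs",
]


def read_counts_tsv(path) -> tuple[MisincorporationTable, dict]:
    """Read a counts table; returns the table and any ``# key: value`` metadata."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"pos", "n_templates", "n_misinc"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts TSV needs columns {sorted(required)}")
    df = df.sort_values("pos")
    pos = df["pos"].to_numpy()
    if pos[0] != 1 or np.any(np.diff(pos) != 1):
        raise ValueError("positions must be 1-based and contiguous")
    if np.any(df["n_misinc"].to_numpy() > df["n_templates"].to_numpy()):
        raise ValueError("n_misinc exceeds n_templates")
    table = MisincorporationTable(
        df["n_templates"].to_numpy(np.int64), df["n_misinc"].to_numpy(np.int64)
    )
    return table, meta


def write_counts_tsv(table: MisincorporationTable, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("pos\tn_templates\tn_misinc\n")
        for p, n, x in zip(table.positions, table.n_templates, table.n_misinc):
            fh.write(f"{p}\t{n}\t{x}\n")


def read_trace_tsv(path) -> ConcentrationTrace:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"t_start_ms", "concentration"}.issubset(df.columns):
        raise ValueError("trace TSV needs columns t_start_ms, concentration")
    t = df["t_start_ms"].to_numpy(float)
    dts = np.diff(t)
    if t.size < 1 or (t.size > 1 and (np.ptp(dts) > 1e-6 * dts[0])):
        raise ValueError("trace requires a uniform time grid")
    dt = float(dts[0]) if t.size > 1 else float(t[0]) or 1.0
    grid = TimeGrid(dt, dt * t.size)
    return ConcentrationTrace(grid, df["concentration"].to_numpy(float))


def write_trace_tsv(trace: ConcentrationTrace, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("t_start_ms\tconcentration\n")
        for t0, v in zip(trace.grid.edges[:-1], trace.values):
            fh.write(f"{t0:.6f}\t{v:.12g}\n")


def read_fasta_length(path) -> int:
    """Template length from the first FASTA record (warns on multi-record)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        import warnings

        warnings.warn(f"{path} has {len(records)} records; using the first")
    return len(records[0].seq)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration shared by the CLI subcommands."""

    kinetics: PolymeraseKinetics
    cmlf: LinearCMLF
    start: StartTimeModel | None
    seed: int
    raw: dict

    @staticmethod
    def from_file(path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        kin_d = raw.get("kinetics", {})
        kin = PolymeraseKinetics(
            tau_e=float(kin_d["tau_e_ms"]),
            tau_p=float(kin_d["tau_p_ms"]),
            pause_prob=float(kin_d["pause_prob"]),
            dissoc_prob=float(kin_d.get("dissoc_prob", 0.0)),
            tau_reassoc=(
                float(kin_d["tau_reassoc_ms"]) if "tau_reassoc_ms" in kin_d else None
            ),
        )
        cm = raw.get("cmlf", {})
        if "e0" not in cm or "m" not in cm:
            raise ValueError("config must state cmlf e0 and m explicitly (no defaults)")
        f = LinearCMLF(e0=float(cm["e0"]), m=float(cm["m"]))
        start = None
        if "start" in raw and float(raw["start"].get("mean_ms", 0)) > 0:
            start = StartTimeModel(
                mean_delay=float(raw["start"]["mean_ms"]),
                shape=float(raw["start"].get("shape", 8.0)),
            )
        return RunConfig(
            kinetics=kin, cmlf=f, start=start, seed=int(raw.get("seed", 0)), raw=raw
        )

    @property
    def hash(self) -> str:
        return config_hash(self.raw)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-replicate generators via SeedSequence spawning, so
    replicate k is reproducible in isolation."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
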