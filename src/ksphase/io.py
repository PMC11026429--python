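"""Shared file IO, configuration and seed management.

FASTA goes through Biopython (60-column wrapping); TSV reading is strict
about ragged rows so malformed tables fail loudly with a row number.  One
global seed deterministically derives per-stage seeds by hashing the stage
name, giving stage-level reproducibility without seed bookkeeping.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import io as _io
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """FASTA file → ordered {id: sequence}; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    """Write {id: sequence} as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_tsv(path) -> pd.DataFrame:
    """Read a header-rowed TSV, rejecting ragged rows with a row number."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        return pd.DataFrame()
    header = rows[0]
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: row {i} has {len(row)} fields, expected {len(header)}"
            )
    df = pd.DataFrame(rows[1:], columns=header)
    # restore numeric dtypes where the whole column parses
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any():
            df[col] = converted
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed < 2**31 from the global seed."""
    digest = hashlib.blake2s(
        f"{global_seed}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run parameters (synthetic scenario + analysis knobs)."""

    seed: int = 0
    n_chromosomes: int = 15
    genes_per_chromosome: int = 50
    codons_per_gene: int = 300
    ks_ortholog_A: float = 0.05
    ks_ortholog_B: float = 0.09
    ks_paralog: float = 0.102
    min_genes: int = 10
    mu: float = 6.51648e-09
    peak_method: str = "median"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        buf = _io.StringIO()
        yaml.safe_dump(self.to_dict(), buf, sort_keys=True)
        return buf.getvalue()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
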