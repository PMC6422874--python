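"""File I/O: FASTQ/FASTA via Biopython, TSV via pandas, flat YAML configs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .simulate import SimulationConfig


def write_fastq(reads: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(reads, str(path), "fastq")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_config(config: SimulationConfig, path: str | Path) -> None:
    data = asdict(config)
    data["genes"] = list(data["genes"])
    data["gene_lengths"] = dict(data["gene_lengths"])
    if data["expressed_genera"] is not None:
        data["expressed_genera"] = list(data["expressed_genera"])
    if data["abundance_profile"] is not None:
        data["abundance_profile"] = dict(data["abundance_profile"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "genes" in data:
        data["genes"] = tuple(data["genes"])
    if data.get("expressed_genera") is not None:
        data["expressed_genera"] = tuple(data["expressed_genera"])
    return SimulationConfig(**data)
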