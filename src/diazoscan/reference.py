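"""Taxon-annotated nitrogenase reference catalogs.

A catalog is an ordered collection of nitrogenase structural-gene records
(nifH, nifD, nifK) plus optional non-nif decoy records, each carrying
machine-readable taxonomy in a pipe-delimited FASTA header::

    >record_id|genus|strain|gene

Catalogs can be enriched with additional records (e.g. keyword-collected
sequences or genes lifted from best-hit genomes), with exact-duplicate
nucleotide sequences collapsed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NIF_GENES = ("nifH", "nifD", "nifK")
#: valid values for :attr:`NifGeneRecord.gene`
GENE_LABELS = NIF_GENES + ("decoy",)
#: valid values for :attr:`NifGeneRecord.source`
SOURCES = ("base_db", "keyword_enrichment", "besthit_genome", "synthetic")

TRANSLATION_TABLE = 11  # bacterial code


class CatalogError(ValueError):
    """Malformed catalog content (headers, duplicate ids, label conflicts)."""


@dataclass(frozen=True)
class NifGeneRecord:
    """One reference nitrogenase gene (or decoy) with taxonomy.

    ``protein_seq`` must equal the frame +1 translation of
    ``nucleotide_seq`` for non-decoy records (checked by ``validate``).
    """

    record_id: str
    genus: str
    strain: str
    gene: str
    nucleotide_seq: str
    protein_seq: str
    source: str = "base_db"

    def __post_init__(self) -> None:
        object.__setattr__(self, "nucleotide_seq", self.nucleotide_seq.upper())
        object.__setattr__(self, "protein_seq", self.protein_seq.upper())
        if not self.gene:
            raise CatalogError(f"record {self.record_id!r}: empty gene label")
        if self.gene not in GENE_LABELS:
            raise CatalogError(
                f"record {self.record_id!r}: unknown gene label {self.gene!r}"
            )
        bad = set(self.nucleotide_seq) - set("ACGTN")
        if bad:
            raise CatalogError(
                f"record {self.record_id!r}: non-ACGTN nucleotides {sorted(bad)}"
            )

    @property
    def is_nif(self) -> bool:
        return self.gene in NIF_GENES

    def header(self) -> str:
        return f"{self.record_id}|{self.genus}|{self.strain}|{self.gene}"


def translate(nucleotide_seq: str) -> str:
    """Frame +1 translation under the bacterial genetic code; N-containing
    ambiguous codons give X."""
    usable = len(nucleotide_seq) - len(nucleotide_seq) % 3
    return str(Seq(nucleotide_seq[:usable]).translate(table=TRANSLATION_TABLE))


@dataclass
class Catalog:
    """Ordered collection of :class:`NifGeneRecord` with provenance counts."""

    records: list[NifGeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        dupes = [k for k, v in Counter(ids).items() if v > 1]
        if dupes:
            raise CatalogError(f"duplicate record ids: {dupes}")

    @property
    def provenance_counts(self) -> dict[str, int]:
        return dict(Counter(r.source for r in self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NifGeneRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Catalog) and self.records == other.records

    def get(self, record_id: str) -> NifGeneRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    @property
    def genera(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if r.is_nif:
                seen.setdefault(r.genus)
        return list(seen)

    def nif_records(self) -> list[NifGeneRecord]:
        return [r for r in self.records if r.is_nif]

    def decoy_records(self) -> list[NifGeneRecord]:
        return [r for r in self.records if not r.is_nif]

    def validate(self) -> None:
        """Check the translation invariant for every non-decoy record."""
        for r in self.records:
            if r.is_nif and translate(r.nucleotide_seq) != r.protein_seq:
                raise CatalogError(
                    f"record {r.record_id!r}: protein_seq does not match the "
                    "frame +1 translation of nucleotide_seq"
                )


def _parse_header(header: str) -> tuple[str, str, str, str]:
    parts = header.split("|")
    if len(parts) != 4:
        raise CatalogError(
            f"malformed header {header!r}: expected 'id|genus|strain|gene'"
        )
    return tuple(parts)  # type: ignore[return-value]


def load_catalog(fasta_path: str | Path, source: str = "base_db") -> Catalog:
    """Load a catalog from FASTA with ``id|genus|strain|gene`` headers.

    Sequences are upper-cased; protein sequences are derived by frame +1
    translation (decoy records included, so decoy proteins are available for
    peptide simulation).
    """
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        record_id, genus, strain, gene = _parse_header(rec.description)
        nt = str(rec.seq).upper()
        records.append(
            NifGeneRecord(
                record_id=record_id,
                genus=genus,
                strain=strain,
                gene=gene,
                nucleotide_seq=nt,
                protein_seq=translate(nt),
                source=source,
            )
        )
    return Catalog(records)


def write_catalog(catalog: Catalog, fasta_path: str | Path, width: int = 60) -> None:
    """Write a catalog as FASTA (60-column wrapped by default)."""
    with open(fasta_path, "w") as fh:
        for r in catalog:
            fh.write(f">{r.header()}\n")
            seq = r.nucleotide_seq
            for i in range(0, max(len(seq), 1), width):
                fh.write(seq[i : i + width] + "\n")


def enrich_catalog(base: Catalog, additions: Catalog | Iterable[NifGeneRecord]) -> Catalog:
    """Union of base and addition records with exact-duplicate collapse.

    Two records are duplicates iff they share both gene label and nucleotide
    sequence; the base-catalog copy is kept.  The same nucleotide sequence
    under two different gene labels is a conflict and raises.
    """
    merged: list[NifGeneRecord] = list(base.records)
    by_seq: dict[str, str] = {r.nucleotide_seq: r.gene for r in merged}
    seen_keys = {(r.gene, r.nucleotide_seq) for r in merged}
    ids = {r.record_id for r in merged}
    add_records = additions.records if isinstance(additions, Catalog) else list(additions)
    for r in add_records:
        if r.nucleotide_seq in by_seq and by_seq[r.nucleotide_seq] != r.gene:
            raise CatalogError(
                f"gene-label conflict for identical sequence: record "
                f"{r.record_id!r} labelled {r.gene!r} vs existing "
                f"{by_seq[r.nucleotide_seq]!r}"
            )
        if (r.gene, r.nucleotide_seq) in seen_keys:
            continue  # exact duplicate; keep base copy
        if r.record_id in ids:
            raise CatalogError(f"duplicate record id on enrichment: {r.record_id!r}")
        merged.append(r)
        seen_keys.add((r.gene, r.nucleotide_seq))
        by_seq[r.nucleotide_seq] = r.gene
        ids.add(r.record_id)
    return Catalog(merged)
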