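"""Build the taxon-annotated NifHDK protein database and digest it.

Retained reads are translated in the reading frame implied by their
screening alignment (falling back to the best stop-free frame when
sequencing errors disrupt that frame), tagged with the best hit's
taxonomy, and optionally complemented with the full-length proteins of the
best-hit reference records.  Tryptic digestion cleaves C-terminal to K/R
except before P.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .align import AlignmentResult, reverse_complement
from .reference import Catalog, NifGeneRecord, translate

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX*")

READ_ENTRY_PREFIX = "r_"
REFERENCE_ENTRY_PREFIX = "p_"


@dataclass(frozen=True)
class TranslatedEntry:
    """One protein entry of the custom NifHDK database."""

    entry_id: str
    origin: str  # "read" | "reference_protein"
    gene: str
    genus: str
    strain: str
    protein_fragment: str
    source_read: str = ""
    frame: int = 1

    def __post_init__(self) -> None:
        if not self.protein_fragment:
            raise ValueError(f"entry {self.entry_id!r}: empty protein fragment")
        if "*" in self.protein_fragment:
            raise ValueError(f"entry {self.entry_id!r}: internal stop codon")
        if self.origin == "read" and not self.source_read:
            raise ValueError(f"entry {self.entry_id!r}: read origin without source read")

    def header(self) -> str:
        return f"{self.entry_id}|{self.genus}|{self.strain}|{self.gene}"


@dataclass(frozen=True)
class TrypticPeptide:
    sequence: str
    parent_entry: str
    start: int  # 1-based position in the parent protein


@dataclass
class DigestResult:
    """Kept and length-dropped peptides of one protein digestion."""

    peptides: list[TrypticPeptide]
    dropped: list[TrypticPeptide] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def all_peptides(self) -> list[TrypticPeptide]:
        """All cleavage fragments in order; their concatenation is the parent."""
        return sorted(self.peptides + self.dropped, key=lambda p: p.start)


def digest_protein(
    protein: str,
    min_peptide_length: int = 6,
    missed_cleavages: int = 0,
    parent_entry: str = "",
) -> DigestResult:
    """In-silico tryptic digestion: cleave after K or R unless followed by P.

    Fragments shorter than ``min_peptide_length`` go to the dropped tally.
    With ``missed_cleavages`` > 0, merges of up to that many adjacent
    fragments are additionally reported (kept list only).
    """
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - VALID_AA
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    if "*" in protein:
        raise ValueError("protein contains a stop codon")

    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))

    base = [
        TrypticPeptide(protein[a:b], parent_entry, a + 1)
        for a, b in zip(cuts[:-1], cuts[1:])
    ]
    kept = [p for p in base if len(p.sequence) >= min_peptide_length]
    dropped = [p for p in base if len(p.sequence) < min_peptide_length]

    for mc in range(1, missed_cleavages + 1):
        for i in range(len(base) - mc):
            seq = "".join(p.sequence for p in base[i : i + mc + 1])
            if len(seq) >= min_peptide_length:
                kept.append(TrypticPeptide(seq, parent_entry, base[i].start))
    return DigestResult(kept, dropped)


def _kmer_overlap(a: str, b: str, k: int = 4) -> int:
    if len(a) < k or len(b) < k:
        return 0
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return sum(1 for i in range(len(a) - k + 1) if a[i : i + k] in kb)


def _frame_translations(read_seq: str) -> dict[int, str]:
    """Translations of all six frames, keyed by frame in {±1, ±2, ±3}."""
    out = {}
    rc = reverse_complement(read_seq)
    for off in range(3):
        out[off + 1] = translate(read_seq[off:])
        out[-(off + 1)] = translate(rc[off:])
    return out


def select_frame_and_translate(
    read_id: str,
    read_seq: str,
    best_hit: NifGeneRecord,
    alignment: AlignmentResult,
) -> TranslatedEntry | None:
    """Translate a retained read in the frame implied by its alignment.

    The alignment gives the strand and the subject offset of the read; the
    reading frame follows from the subject's frame +1 ORF (subject position
    0 starts a codon).  If that frame contains an internal stop (sequencing
    error), the best-scoring stop-free frame among all six is used instead,
    scored by exact 4-mer overlap with the best hit's protein.  Returns
    None when every frame contains a stop.
    """
    oriented = read_seq if alignment.strand == "+" else reverse_complement(read_seq)
    q0 = alignment.aligned_query_span[0] - 1
    s0 = alignment.aligned_subject_span[0] - 1
    offset = (q0 - s0) % 3
    implied_frame = offset + 1 if alignment.strand == "+" else -(offset + 1)

    frag = translate(oriented[offset:]).rstrip("*")
    chosen = implied_frame
    if "*" in frag or not frag:
        candidates = {
            f: t.rstrip("*") for f, t in _frame_translations(read_seq).items()
        }
        stop_free = {f: t for f, t in candidates.items() if t and "*" not in t}
        if not stop_free:
            return None
        chosen, frag = max(
            stop_free.items(),
            key=lambda ft: (_kmer_overlap(ft[1], best_hit.protein_seq), -abs(ft[0])),
        )
    return TranslatedEntry(
        entry_id=f"{READ_ENTRY_PREFIX}{read_id}",
        origin="read",
        gene=best_hit.gene,
        genus=best_hit.genus,
        strain=best_hit.strain,
        protein_fragment=frag,
        source_read=read_id,
        frame=chosen,
    )


def reference_entry(record: NifGeneRecord) -> TranslatedEntry:
    return TranslatedEntry(
        entry_id=f"{REFERENCE_ENTRY_PREFIX}{record.record_id}",
        origin="reference_protein",
        gene=record.gene,
        genus=record.genus,
        strain=record.strain,
        protein_fragment=record.protein_seq.rstrip("*"),
        frame=1,
    )


def build_peptide_database(
    entries: list[TranslatedEntry],
    catalog: Catalog | None = None,
    include_besthit_proteins: bool = False,
    best_hit_ids: set[str] | None = None,
) -> list[TranslatedEntry]:
    """Assemble the protein database: read fragments plus (optionally) the
    full-length proteins of every distinct best-hit reference record."""
    db = list(entries)
    if include_besthit_proteins:
        if catalog is None:
            raise ValueError("include_besthit_proteins requires a catalog")
        if best_hit_ids is None:
            raise ValueError("include_besthit_proteins requires best_hit_ids")
        for rid in sorted(set(best_hit_ids)):
            db.append(reference_entry(catalog.get(rid)))
    return db


def write_peptide_database(db: list[TranslatedEntry], fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for e in db:
            fh.write(f">{e.header()}\n{e.protein_fragment}\n")


def load_peptide_database(fasta_path: str | Path) -> list[TranslatedEntry]:
    """Reload a protein database written by :func:`write_peptide_database`.

    Origin is recovered from the entry-id prefix; the frame of read entries
    is not serialized and reloads as +1.
    """
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 4:
            raise ValueError(f"malformed database header: {rec.description!r}")
        entry_id, genus, strain, gene = parts
        origin = "read" if entry_id.startswith(READ_ENTRY_PREFIX) else "reference_protein"
        out.append(
            TranslatedEntry(
                entry_id=entry_id,
                origin=origin,
                gene=gene,
                genus=genus,
                strain=strain,
                protein_fragment=str(rec.seq).upper(),
                source_read=entry_id[len(READ_ENTRY_PREFIX):] if origin == "read" else "",
                frame=1,
            )
        )
    return out
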