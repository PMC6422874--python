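"""Read quality trimming and two-stage nitrogenase read screening.

Stage 1 assigns each metagenomic read to its best-scoring nitrogenase
reference by local alignment and keeps it as a candidate when the percent
identity clears the gene-specific threshold (nifH 90%, nifD/nifK 80%) and
at least half the read is aligned.  Stage 2 re-searches candidates against
a background database (nif references plus non-nif decoys, standing in for
NR) and retains a candidate only when its best background hit is a nif
record of the same gene at E <= 1e-10 — a deterministic automation of
"remove false hits by inspection".  Retained reads are taxonomically
assigned by best hit and summarized as genus x gene counts and relative
abundances.

An edit-distance prescreen (edlib, semi-global) shortlists references per
read before exact Smith-Waterman scoring; references within a configurable
edit margin of the best are scored exactly, so best-hit choice and ties are
decided by alignment score, not by the prescreen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import edlib
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .align import (
    AlignmentResult,
    DEFAULT_SCORING,
    Scoring,
    encode,
    evalue,
    reverse_complement,
    sw_align,
    sw_score,
)
from .reference import Catalog, NifGeneRecord


@dataclass(frozen=True)
class TrimSettings:
    """Quality-trimming settings (prinseq-lite conventions)."""

    trim_left: int = 20
    trim_right: int = 5
    trim_qual_right: int = 30
    min_qual_mean: float = 20.0
    min_len: int = 70


@dataclass(frozen=True)
class ScreenConfig:
    identity_threshold_nifH: float = 90.0
    identity_threshold_nifDK: float = 80.0
    evalue_threshold: float = 1e-10
    min_read_coverage: float = 0.5
    scoring: Scoring = DEFAULT_SCORING
    karlin_lambda: float = 0.625
    karlin_K: float = 0.41
    prescreen_margin: int = 8  # extra edits beyond the best prescreen hit

    def __post_init__(self) -> None:
        for t in (self.identity_threshold_nifH, self.identity_threshold_nifDK):
            if not 0 < t <= 100:
                raise ValueError("identity thresholds must be in (0, 100]")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")

    def identity_threshold(self, gene: str) -> float:
        return (
            self.identity_threshold_nifH
            if gene == "nifH"
            else self.identity_threshold_nifDK
        )


@dataclass
class ReadAssignment:
    """Per-read screening outcome."""

    read_id: str
    gene: str
    best_record: str
    identity: float
    evalue: float
    taxon: str
    status: str  # candidate | retained | removed_stage2 | unassigned
    alignment: AlignmentResult | None = None
    read_seq: str = ""

    def to_row(self) -> dict:
        return {
            "read_id": self.read_id,
            "gene": self.gene,
            "best_record": self.best_record,
            "identity": round(self.identity, 3),
            "evalue": self.evalue,
            "taxon": self.taxon,
            "status": self.status,
        }


# ---------------------------------------------------------------------------
# trimming


def trim_reads(
    reads: list[SeqRecord], settings: TrimSettings = TrimSettings()
) -> list[SeqRecord]:
    """Quality-trim reads and drop those failing the length/quality filters.

    Order of operations: fixed 5'/3' trims, then repeated removal of 3'
    bases below ``trim_qual_right``, then discard of reads with mean
    quality < ``min_qual_mean`` or length < ``min_len``.
    """
    kept = []
    for r in reads:
        qual = r.letter_annotations.get("phred_quality")
        if qual is None or len(qual) != len(r.seq):
            raise ValueError(f"read {r.id!r}: missing or mismatched quality string")
        end = len(r) - settings.trim_right
        if end <= settings.trim_left:
            continue
        t = r[settings.trim_left : end]
        q = t.letter_annotations["phred_quality"]
        cut = len(q)
        while cut > 0 and q[cut - 1] < settings.trim_qual_right:
            cut -= 1
        t = t[:cut]
        q = t.letter_annotations["phred_quality"]
        if len(t) < settings.min_len:
            continue
        if sum(q) / len(q) < settings.min_qual_mean:
            continue
        kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# stage 1


class _CatalogIndex:
    """Pre-encoded reference sequences for repeated alignment."""

    def __init__(self, records: list[NifGeneRecord]):
        self.records = records
        self.encoded = [encode(r.nucleotide_seq) for r in records]
        self.total_length = sum(len(r.nucleotide_seq) for r in records)


def _best_hits(
    read_seq: str,
    index: _CatalogIndex,
    scoring: Scoring,
    margin: int,
) -> tuple[list[tuple[int, str]], int]:
    """Exact-best (record index, strand) pairs and the best SW score.

    edlib semi-global edit distances shortlist (record, strand) pairs within
    ``margin`` edits of the prescreen best; exact affine Smith-Waterman then
    ranks the shortlist.
    """
    rc = reverse_complement(read_seq)
    dists = []
    for i, rec in enumerate(index.records):
        for strand, q in (("+", read_seq), ("-", rc)):
            d = edlib.align(q, rec.nucleotide_seq, mode="HW", task="distance")[
                "editDistance"
            ]
            dists.append((d, i, strand))
    dmin = min(d for d, _, _ in dists)
    shortlist = [(i, strand) for d, i, strand in dists if d <= dmin + margin]

    enc_f = encode(read_seq)
    enc_r = encode(rc)
    best_score = -1
    best_pairs: list[tuple[int, str]] = []
    for i, strand in shortlist:
        q = enc_f if strand == "+" else enc_r
        s = sw_score(q, index.encoded[i], scoring)
        if s > best_score:
            best_score = s
            best_pairs = [(i, strand)]
        elif s == best_score:
            best_pairs.append((i, strand))
    return best_pairs, best_score


def screen_reads(
    reads: list[SeqRecord],
    nif_catalog: Catalog,
    config: ScreenConfig = ScreenConfig(),
) -> list[ReadAssignment]:
    """Stage-1 screening of trimmed reads against the nif catalog."""
    nif_records = nif_catalog.nif_records()
    if not nif_records:
        raise ValueError("nif catalog contains no nif records")
    index = _CatalogIndex(nif_records)
    out = []
    for r in reads:
        seq = str(r.seq).upper()
        pairs, _score = _best_hits(seq, index, config.scoring, config.prescreen_margin)
        i0, strand0 = pairs[0]
        best = index.records[i0]
        aln = sw_align(
            seq if strand0 == "+" else reverse_complement(seq),
            best.nucleotide_seq,
            config.scoring,
            strand=strand0,
        )
        genera = {index.records[i].genus for i, _ in pairs}
        taxon = best.genus if len(genera) == 1 else "ambiguous"
        passing = (
            aln.identity >= config.identity_threshold(best.gene)
            and aln.query_span_length >= config.min_read_coverage * len(seq)
        )
        out.append(
            ReadAssignment(
                read_id=r.id,
                gene=best.gene,
                best_record=best.record_id,
                identity=aln.identity,
                evalue=math.nan,
                taxon=taxon,
                status="candidate" if passing else "unassigned",
                alignment=aln,
                read_seq=seq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# stage 2


def validate_candidates(
    assignments: list[ReadAssignment],
    background_db: Catalog,
    config: ScreenConfig = ScreenConfig(),
) -> list[ReadAssignment]:
    """Stage-2 validation against the background (NR stand-in) database.

    A candidate is retained iff its best background hit is significant
    (E <= threshold) and is a nif record of the candidate's gene; if any
    equal-best background hit is a decoy the candidate is removed.
    Non-candidate assignments pass through unchanged.
    """
    if len(background_db) == 0:
        raise ValueError("background database is empty")
    index = _CatalogIndex(list(background_db.records))
    out = []
    for a in assignments:
        if a.status != "candidate":
            out.append(a)
            continue
        pairs, score = _best_hits(
            a.read_seq, index, config.scoring, config.prescreen_margin
        )
        e = evalue(
            score,
            len(a.read_seq),
            index.total_length,
            config.karlin_lambda,
            config.karlin_K,
        )
        hits = [index.records[i] for i, _ in pairs]
        ok = (
            e <= config.evalue_threshold
            and all(h.is_nif for h in hits)
            and any(h.gene == a.gene for h in hits)
        )
        out.append(
            replace(a, evalue=e, status="retained" if ok else "removed_stage2")
        )
    return out


# ---------------------------------------------------------------------------
# summaries


def assign_and_summarize(assignments: list[ReadAssignment]) -> pd.DataFrame:
    """Genus x gene counts and per-gene relative abundances of retained reads.

    Reads tied across genera at equal best score are counted under the
    taxon "ambiguous".  Fractions sum to 1 within each gene.
    """
    retained = [a for a in assignments if a.status == "retained"]
    rows = [(a.gene, a.taxon) for a in retained]
    df = pd.DataFrame(rows, columns=["gene", "genus"])
    if df.empty:
        return pd.DataFrame(columns=["gene", "genus", "count", "fraction"])
    counts = df.value_counts(["gene", "genus"]).rename("count").reset_index()
    counts["fraction"] = counts["count"] / counts.groupby("gene")["count"].transform(
        "sum"
    )
    return counts.sort_values(["gene", "count"], ascending=[True, False]).reset_index(
        drop=True
    )


def assignments_to_frame(assignments: list[ReadAssignment]) -> pd.DataFrame:
    return pd.DataFrame([a.to_row() for a in assignments])
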