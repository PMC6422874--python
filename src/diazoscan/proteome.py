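"""Assignment of identified peptides to the NifHDK database at 100% identity.

A peptide matches a database entry iff it is an exact contiguous substring
of the entry's protein sequence (case-insensitive; optional I/L-equivalence
mode for mass-spectrometric indistinguishability, off by default).  Each
observed peptide gets exactly one verdict: a genus (all matched entries
from one genus), multi-assigned (entries from two or more genera) or
unmatched.  Summaries count genus-verdict peptides per genus per Nif
protein per sample and flag, per genus, detection in all replicates and
simultaneous NifH+NifD+NifK detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptides import TranslatedEntry

_SEPARATOR = "#"
AA20 = set("ACDEFGHIKLMNPQRSTVWY")


class PeptideDatabase:
    """Searchable index over the protein entries of the custom database.

    Entries are concatenated with a separator and peptides located with
    string search over the concatenation, then mapped back to entries; X
    positions (ambiguous translations) never match.
    """

    def __init__(self, entries: list[TranslatedEntry], il_equivalence: bool = False):
        self.entries = list(entries)
        self.il_equivalence = il_equivalence
        seqs = [e.protein_fragment.upper() for e in self.entries]
        if il_equivalence:
            seqs = [s.replace("I", "L") for s in seqs]
        self._concat = _SEPARATOR + _SEPARATOR.join(seqs) + _SEPARATOR
        starts = [1]
        for s in seqs[:-1]:
            starts.append(starts[-1] + len(s) + 1)
        self._starts = np.array(starts if seqs else [], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.entries)

    def match(self, peptide: str) -> set[str]:
        """Complete set of entry ids containing the peptide as an exact
        substring."""
        if not peptide:
            raise ValueError("empty peptide")
        pep = peptide.upper()
        bad = set(pep) - AA20
        if bad:
            raise ValueError(f"non-amino-acid characters in peptide: {sorted(bad)}")
        if self.il_equivalence:
            pep = pep.replace("I", "L")
        hits: set[str] = set()
        pos = self._concat.find(pep)
        while pos != -1:
            idx = int(np.searchsorted(self._starts, pos, side="right") - 1)
            hits.add(self.entries[idx].entry_id)
            pos = self._concat.find(pep, pos + 1)
        return hits


def match_peptide(peptide: str, database: PeptideDatabase) -> set[str]:
    return database.match(peptide)


@dataclass
class PeptideCall:
    """An observed peptide with its matches and taxonomic verdict."""

    peptide: str
    sample: str
    replicate: int
    matched_entries: set[str] = field(default_factory=set)
    genera: set[str] = field(default_factory=set)
    gene_set: set[str] = field(default_factory=set)
    verdict: str = "unmatched"  # "genus:<name>" | "multi_assigned" | "unmatched"


def assign_verdict(call: PeptideCall) -> str:
    """Resolve the verdict from the call's matched genera."""
    if not call.matched_entries:
        return "unmatched"
    if len(call.genera) == 1:
        return f"genus:{next(iter(call.genera))}"
    return "multi_assigned"


def call_peptides(
    peptides: pd.DataFrame, database: PeptideDatabase
) -> list[PeptideCall]:
    """Match and taxonomically resolve an identified-peptide table.

    ``peptides`` columns: sample, replicate, peptide.  Duplicate
    (sample, replicate, peptide) rows collapse to one call — counts are of
    peptides, not spectra.
    """
    by_id = {e.entry_id: e for e in database.entries}
    match_cache: dict[str, set[str]] = {}
    calls = []
    seen = set()
    for row in peptides.itertuples(index=False):
        key = (row.sample, int(row.replicate), row.peptide)
        if key in seen:
            continue
        seen.add(key)
        pep = row.peptide
        if pep not in match_cache:
            match_cache[pep] = database.match(pep)
        hits = match_cache[pep]
        call = PeptideCall(
            peptide=pep,
            sample=row.sample,
            replicate=int(row.replicate),
            matched_entries=hits,
            genera={by_id[h].genus for h in hits},
            gene_set={by_id[h].gene for h in hits},
        )
        call.verdict = assign_verdict(call)
        calls.append(call)
    return calls


@dataclass
class NifSummary:
    """Genus-level peptide count summary with consistency flags."""

    counts: pd.DataFrame  # sample, genus, gene, count (genus-verdict peptides)
    multi_assigned: pd.DataFrame  # sample, gene_set, count
    unmatched: pd.DataFrame  # sample, count
    consistency: pd.DataFrame  # sample, genus, detected_all_replicates, nifHDK_simultaneous
    total_calls: int

    def table(self, min_total: int = 0) -> pd.DataFrame:
        """Genus-by-(sample x Nif protein) pivot; genera whose total count
        falls below ``min_total`` are pooled into an "Others" row."""
        df = self.counts.copy()
        totals = df.groupby("genus")["count"].sum()
        small = totals[totals < min_total].index
        df.loc[df["genus"].isin(small), "genus"] = "Others"
        pivot = df.pivot_table(
            index="genus", columns=["sample", "gene"], values="count",
            aggfunc="sum", fill_value=0,
        )
        return pivot.sort_index()


def summarize(
    calls: list[PeptideCall],
    replicates: list[int] | None = None,
) -> NifSummary:
    """Aggregate peptide calls into a genus x Nif-protein count table.

    ``replicates`` declares the expected replicate labels (defaults to the
    labels observed); a call with a replicate label outside the declared
    structure raises.  ``detected_all_replicates`` is true for a genus with
    at least one genus-verdict peptide in every declared replicate of the
    sample; ``nifHDK_simultaneous`` requires at least one genus-verdict
    peptide for each of NifH, NifD and NifK in the sample.
    """
    observed = sorted({c.replicate for c in calls})
    if replicates is None:
        replicates = observed
    unknown = set(observed) - set(replicates)
    if unknown:
        raise ValueError(f"unknown replicate labels: {sorted(unknown)}")

    rows = []
    for c in calls:
        genus = c.verdict.removeprefix("genus:") if c.verdict.startswith("genus:") else None
        rows.append(
            {
                "sample": c.sample,
                "replicate": c.replicate,
                "verdict": c.verdict,
                "genus": genus,
                # a peptide almost always matches entries of a single gene;
                # the rare multi-gene match is labelled with the joined set so
                # counts stay an exact partition of the calls
                "gene": "+".join(sorted(c.gene_set)),
                "genes": frozenset(c.gene_set),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        empty = pd.DataFrame()
        return NifSummary(empty, empty, empty, empty, 0)

    genus_df = df[df["genus"].notna()]
    counts = (
        genus_df.groupby(["sample", "genus", "gene"]).size().rename("count").reset_index()
    )
    multi = (
        df[df["verdict"] == "multi_assigned"]
        .groupby(["sample", "gene"])
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"gene": "gene_set"})
    )
    unmatched = (
        df[df["verdict"] == "unmatched"].groupby("sample").size().rename("count").reset_index()
    )

    cons_rows = []
    for (sample, genus), sub in genus_df.groupby(["sample", "genus"]):
        reps_with = set(sub["replicate"])
        genes_with: set[str] = set().union(*sub["genes"])
        cons_rows.append(
            {
                "sample": sample,
                "genus": genus,
                "detected_all_replicates": set(replicates) <= reps_with,
                "nifHDK_simultaneous": {"nifH", "nifD", "nifK"} <= genes_with,
            }
        )
    consistency = pd.DataFrame(cons_rows)
    return NifSummary(counts, multi, unmatched, consistency, len(calls))
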