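"""End-to-end orchestration: simulate -> trim -> screen -> translate ->
match -> summarize, returning every intermediate for inspection."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.SeqRecord import SeqRecord

from .peptides import TranslatedEntry, build_peptide_database, select_frame_and_translate
from .proteome import NifSummary, PeptideCall, PeptideDatabase, call_peptides, summarize
from .reference import Catalog
from .screen import (
    ReadAssignment,
    ScreenConfig,
    TrimSettings,
    assign_and_summarize,
    screen_reads,
    trim_reads,
    validate_candidates,
)
from .simulate import (
    SimulationConfig,
    generate_reference_catalog,
    simulate_expressed_peptides,
    simulate_reads,
)


@dataclass
class PipelineResult:
    catalog: Catalog
    reads: list[SeqRecord]
    read_truth: pd.DataFrame
    trimmed: list[SeqRecord]
    assignments: list[ReadAssignment]
    read_summary: pd.DataFrame
    entries: list[TranslatedEntry]
    peptide_database: list[TranslatedEntry]
    peptides: pd.DataFrame
    peptide_truth: pd.DataFrame
    calls: list[PeptideCall] = field(default_factory=list)
    nif_summary: NifSummary | None = None

    @property
    def retained(self) -> list[ReadAssignment]:
        return [a for a in self.assignments if a.status == "retained"]


def translate_retained(
    assignments: list[ReadAssignment], catalog: Catalog
) -> list[TranslatedEntry]:
    """Frame-select and translate every retained read (drops the rare read
    whose six frames all contain stops)."""
    entries = []
    for a in assignments:
        if a.status != "retained" or a.alignment is None:
            continue
        entry = select_frame_and_translate(
            a.read_id, a.read_seq, catalog.get(a.best_record), a.alignment
        )
        if entry is not None:
            entries.append(entry)
    return entries


def run_pipeline(
    config: SimulationConfig,
    screen_config: ScreenConfig = ScreenConfig(),
    trim_settings: TrimSettings | None = TrimSettings(),
    include_besthit_proteins: bool = True,
) -> PipelineResult:
    """Run the whole analysis on a synthetic community."""
    catalog = generate_reference_catalog(config)
    reads, read_truth = simulate_reads(catalog, config)
    trimmed = trim_reads(reads, trim_settings) if trim_settings else list(reads)

    nif_catalog = Catalog(catalog.nif_records())
    stage1 = screen_reads(trimmed, nif_catalog, screen_config)
    stage2 = validate_candidates(stage1, catalog, screen_config)
    read_summary = assign_and_summarize(stage2)

    entries = translate_retained(stage2, catalog)
    best_hits = {a.best_record for a in stage2 if a.status == "retained"}
    database = build_peptide_database(
        entries,
        catalog,
        include_besthit_proteins=include_besthit_proteins,
        best_hit_ids=best_hits,
    )

    peptides, peptide_truth = simulate_expressed_peptides(catalog, config)
    calls = call_peptides(peptides, PeptideDatabase(database))
    nif_summary = summarize(calls, replicates=list(range(1, config.n_replicates + 1)))

    return PipelineResult(
        catalog=catalog,
        reads=reads,
        read_truth=read_truth,
        trimmed=trimmed,
        assignments=stage2,
        read_summary=read_summary,
        entries=entries,
        peptide_database=database,
        peptides=peptides,
        peptide_truth=peptide_truth,
        calls=calls,
        nif_summary=nif_summary,
    )
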