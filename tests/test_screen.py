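"""Quality trimming and two-stage nif read screening."""

import math

import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from diazoscan import (
    Catalog,
    NifGeneRecord,
    ScreenConfig,
    SimulationConfig,
    assign_and_summarize,
    evalue,
    low_quality_tail_read,
    reverse_complement,
    screen_reads,
    simulate_reads,
    translate,
    trim_reads,
    validate_candidates,
)


def _read(seq, qual=35, rid="r1"):
    sr = SeqRecord(Seq(seq), id=rid, description="")
    q = [qual] * len(seq) if isinstance(qual, int) else list(qual)
    sr.letter_annotations["phred_quality"] = q
    return sr


def _mutate_every(seq, step, offset=0):
    """Deterministically substitute every ``step``-th base."""
    out = list(seq)
    for i in range(offset, len(out), step):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestTrim:
    def test_uniform_high_quality_read_trimmed_to_75(self):
        kept = trim_reads([_read("A" * 100)])
        assert len(kept) == 1 and len(kept[0]) == 75

    def test_short_read_discarded_by_min_len(self):
        assert trim_reads([_read("A" * 90)]) == []  # 90-25=65 < 70

    def test_low_mean_quality_discarded(self):
        assert trim_reads([_read("A" * 120, qual=15)]) == []

    def test_low_quality_tail_removed(self):
        r = low_quality_tail_read("G" * 120, tail_length=10, tail_quality=10)
        (kept,) = trim_reads(r and [r])
        # 120 - 20 left - 5 right = 95, then 5 remaining low-Q tail bases cut
        assert len(kept) == 90

    def test_malformed_records_rejected(self):
        # length/quality mismatch is rejected at record construction
        with pytest.raises((TypeError, ValueError)):
            _read("ACGT" * 30, qual=[30] * 10)
        # a record without qualities cannot be quality-trimmed
        r = SeqRecord(Seq("ACGT" * 30), id="noq", description="")
        with pytest.raises(ValueError, match="quality"):
            trim_reads([r])


@pytest.fixture(scope="module")
def screen_setup(small_catalog):
    nif = Catalog(small_catalog.nif_records())
    cfg = ScreenConfig()
    return small_catalog, nif, cfg


class TestStage1:
    def test_error_free_read_is_candidate_at_100(self, screen_setup):
        catalog, nif, cfg = screen_setup
        rec = nif.get("Bradyrhizobium_nifH")
        read = _read(rec.nucleotide_seq[30:130], rid="exact")
        (a,) = screen_reads([read], nif, cfg)
        assert a.status == "candidate"
        assert a.identity == 100.0
        assert a.best_record == rec.record_id
        assert a.taxon == "Bradyrhizobium"

    def test_gene_specific_thresholds(self, screen_setup):
        """~85% identity fails the nifH 90% threshold but passes nifDK 80%."""
        catalog, nif, cfg = screen_setup
        h = nif.get("Bradyrhizobium_nifH").nucleotide_seq[:100]
        d = nif.get("Bradyrhizobium_nifD").nucleotide_seq[:100]
        read_h = _read(_mutate_every(h, 7), rid="h85")  # 15 substitutions
        read_d = _read(_mutate_every(d, 7), rid="d85")
        a_h, a_d = screen_reads([read_h, read_d], nif, cfg)
        assert a_h.gene == "nifH" and a_h.status == "unassigned"
        assert a_d.gene == "nifD" and a_d.status == "candidate"

    def test_reverse_strand_read_recovered(self, screen_setup):
        catalog, nif, cfg = screen_setup
        rec = nif.get("Kosakonia_nifK")
        read = _read(reverse_complement(rec.nucleotide_seq[50:150]), rid="rc")
        (a,) = screen_reads([read], nif, cfg)
        assert a.status == "candidate"
        assert a.alignment.strand == "-"
        assert a.taxon == "Kosakonia"

    def test_short_perfect_match_fails_coverage(self, screen_setup):
        """A perfect 25-nt match inside a 100-nt read is not a candidate."""
        catalog, nif, cfg = screen_setup
        rec = nif.get("Bradyrhizobium_nifH")
        junk = "AC" * 19 + rec.nucleotide_seq[:25] + "GT" * 19
        (a,) = screen_reads([_read(junk, rid="cov")], nif, cfg)
        assert a.status == "unassigned"

    def test_tie_between_genera_is_ambiguous(self):
        nt = "ATG" + "GCTCAA" * 30
        recs = [
            NifGeneRecord(f"{g}_nifH", g, "s", "nifH", nt, translate(nt), "synthetic")
            for g in ("GenusA", "GenusB")
        ]
        nif = Catalog(recs)
        (a,) = screen_reads([_read(nt[:100], rid="tie")], nif)
        assert a.taxon == "ambiguous"


class TestStage2:
    def test_genuine_nif_read_retained(self, screen_setup):
        catalog, nif, cfg = screen_setup
        rec = nif.get("Bradyrhizobium_nifD")
        read = _read(rec.nucleotide_seq[100:200], rid="good")
        out = validate_candidates(screen_reads([read], nif, cfg), catalog, cfg)
        assert out[0].status == "retained"
        assert out[0].evalue <= cfg.evalue_threshold

    def test_decoy_resembling_nif_removed(self, screen_setup):
        """A read from a nif-like decoy passes stage 1 but is removed when the
        background search finds the decoy as its best hit."""
        catalog, nif, cfg = screen_setup
        src = nif.get("Bradyrhizobium_nifD").nucleotide_seq
        decoy_nt = _mutate_every(src, 10)  # 90% identical to nifD
        decoy = NifGeneRecord(
            "decoy_like", "decoy_org_x", "s", "decoy", decoy_nt,
            translate(decoy_nt), "synthetic",
        )
        background = Catalog(list(catalog.records) + [decoy])
        read = _read(decoy_nt[200:300], rid="trap")
        stage1 = screen_reads([read], nif, cfg)
        assert stage1[0].status == "candidate"  # fools the identity threshold
        out = validate_candidates(stage1, background, cfg)
        assert out[0].status == "removed_stage2"

    def test_weak_background_hit_removed_by_evalue(self, screen_setup):
        """With the background shrunk to one unrelated decoy, the best hit's
        E-value (recomputed with the closed form) exceeds 1e-10."""
        catalog, nif, cfg = screen_setup
        rec = nif.get("Bradyrhizobium_nifD")
        read = _read(rec.nucleotide_seq[:100], rid="orphan")
        background = Catalog([catalog.decoy_records()[0]])
        stage1 = screen_reads([read], nif, cfg)
        out = validate_candidates(stage1, background, cfg)
        assert out[0].status == "removed_stage2"
        # independent E-value check: score implied by reported E
        e = out[0].evalue
        n = len(background.records[0].nucleotide_seq)
        score = -math.log(e / (0.41 * 100 * n)) / 0.625
        assert evalue(score, 100, n) == pytest.approx(e, rel=1e-9)
        assert e > cfg.evalue_threshold

    def test_stage2_never_promotes(self, small_catalog):
        cfg = ScreenConfig()
        config = SimulationConfig(
            n_genera=3, gene_lengths={"nifH": 450, "nifD": 600, "nifK": 660},
            n_reads=120, read_length=100, seed=5,
        )
        reads, _ = simulate_reads(small_catalog, config)
        nif = Catalog(small_catalog.nif_records())
        stage1 = screen_reads(reads, nif, cfg)
        stage2 = validate_candidates(stage1, small_catalog, cfg)
        cand = {a.read_id for a in stage1 if a.status == "candidate"}
        ret = {a.read_id for a in stage2 if a.status == "retained"}
        assert ret <= cand

    def test_empty_background_rejected(self, screen_setup):
        catalog, nif, cfg = screen_setup
        with pytest.raises(ValueError, match="background"):
            validate_candidates([], Catalog([]), cfg)


class TestSummary:
    def test_counts_and_fractions(self, screen_setup):
        catalog, nif, cfg = screen_setup
        reads = []
        for i in range(8):
            reads.append(_read(nif.get("Bradyrhizobium_nifH").nucleotide_seq[i * 10 : i * 10 + 100], rid=f"a{i}"))
        for i in range(2):
            reads.append(_read(nif.get("Kosakonia_nifH").nucleotide_seq[i * 17 : i * 17 + 100], rid=f"b{i}"))
        out = validate_candidates(screen_reads(reads, nif, cfg), catalog, cfg)
        summary = assign_and_summarize(out)
        nifh = summary[summary.gene == "nifH"].set_index("genus")
        assert nifh.loc["Bradyrhizobium", "fraction"] == pytest.approx(0.8)
        assert nifh.loc["Kosakonia", "fraction"] == pytest.approx(0.2)

    def test_fractions_sum_to_one_per_gene(self, small_catalog):
        cfg = ScreenConfig()
        config = SimulationConfig(
            n_genera=3, gene_lengths={"nifH": 450, "nifD": 600, "nifK": 660},
            n_reads=150, read_length=100, seed=6,
        )
        reads, _ = simulate_reads(small_catalog, config)
        nif = Catalog(small_catalog.nif_records())
        out = validate_candidates(screen_reads(reads, nif, cfg), small_catalog, cfg)
        summary = assign_and_summarize(out)
        sums = summary.groupby("gene")["fraction"].sum()
        assert (abs(sums - 1.0) < 1e-9).all()

    def test_threshold_monotonicity(self, small_catalog):
        """Raising the identity thresholds never increases retained counts."""
        config = SimulationConfig(
            n_genera=3, gene_lengths={"nifH": 450, "nifD": 600, "nifK": 660},
            n_reads=150, read_length=100, error_rate=0.05, seed=7,
        )
        reads, _ = simulate_reads(small_catalog, config)
        nif = Catalog(small_catalog.nif_records())
        counts = []
        for th in (70.0, 85.0, 95.0):
            cfg = ScreenConfig(
                identity_threshold_nifH=th, identity_threshold_nifDK=th
            )
            out = validate_candidates(screen_reads(reads, nif, cfg), small_catalog, cfg)
            counts.append(sum(a.status == "retained" for a in out))
        assert counts[0] >= counts[1] >= counts[2]
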