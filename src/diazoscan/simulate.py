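"""Synthetic data generators for the whole pipeline.

These emulate the statistical structure of a root-microbiome study of
N2-fixing bacteria: a multi-genus nitrogenase gene catalog with controlled
inter-genus divergence, shotgun reads drawn from a genus-abundance profile
with substitution errors plus non-nif decoy reads, per-replicate tryptic
peptide lists from the expressed genera's NifHDK proteins, and noisy
per-plant assay measurement tables.  Every generator is deterministic for
a fixed seed and returns a truth table alongside its output.

Ancestral gene sequences are codon-aware (built from the 61 sense codons)
and substitutions never create an internal stop, so frame +1 translations
are always clean — the translated-database stage requires valid ORFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peptides import digest_protein
from .rates import atom_percent_to_delta, delta_to_atom_percent
from .reference import Catalog, NifGeneRecord, translate

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

#: default genus names, dominant first (a Bradyrhizobium-dominated community,
#: as is typical for root-associated diazotroph profiles)
DEFAULT_GENERA = (
    "Bradyrhizobium",
    "Kosakonia",
    "Azorhizobium",
    "Klebsiella",
    "Rhodospirillum",
    "Desulfovibrio",
    "Anabaena",
    "Methylobacterium",
    "Rhizobium",
    "Hartmannibacter",
)

#: gene lengths near the real nifH/nifD/nifK gene sizes, rounded to full
#: codons; keeps NifH vs NifD/NifK protein sizes in distinct ranges
DEFAULT_GENE_LENGTHS = {"nifH": 879, "nifD": 1449, "nifK": 1560}


def _default_profile(genera: Sequence[str]) -> dict[str, float]:
    """One dominant genus at 70% of nif reads, remainder split geometrically."""
    if len(genera) == 1:
        return {genera[0]: 1.0}
    rest = np.array([0.5**i for i in range(len(genera) - 1)])
    rest = 0.30 * rest / rest.sum()
    out = {genera[0]: 0.70}
    out.update({g: float(w) for g, w in zip(genera[1:], rest)})
    return out


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic community and its measurements."""

    n_genera: int = 5
    genes: tuple[str, ...] = ("nifH", "nifD", "nifK")
    gene_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS)
    )
    inter_genus_divergence: float = 0.10
    abundance_profile: Mapping[str, float] | None = None
    n_reads: int = 10_000
    read_length: int = 150
    error_rate: float = 0.01
    indel_rate: float = 0.0
    decoy_fraction: float = 0.10
    n_decoy_genes: int = 4
    decoy_gene_length: int = 1200
    expressed_genera: tuple[str, ...] | None = None
    peptide_detection_prob: float = 0.8
    decoy_peptides_per_replicate: int = 10
    n_replicates: int = 3
    sample_name: str = "sample1"
    quality: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        if not 0 <= self.inter_genus_divergence <= 1:
            raise ValueError("inter_genus_divergence must be in [0, 1]")
        for frac in (self.error_rate, self.indel_rate, self.decoy_fraction,
                     self.peptide_detection_prob):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for gene in self.genes:
            length = self.gene_lengths[gene]
            if length % 3 != 0:
                raise ValueError(f"gene length for {gene} must be a multiple of 3")
        if self.decoy_gene_length % 3 != 0:
            raise ValueError("decoy_gene_length must be a multiple of 3")
        if self.abundance_profile is not None:
            vals = np.array(list(self.abundance_profile.values()), float)
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError("abundance_profile must sum to 1")
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError("abundance fractions must be in [0, 1]")

    @property
    def genera(self) -> tuple[str, ...]:
        if self.abundance_profile is not None:
            return tuple(self.abundance_profile)
        if self.n_genera <= len(DEFAULT_GENERA):
            return DEFAULT_GENERA[: self.n_genera]
        extra = tuple(
            f"Genus{i:02d}" for i in range(len(DEFAULT_GENERA) + 1, self.n_genera + 1)
        )
        return DEFAULT_GENERA + extra

    @property
    def profile(self) -> dict[str, float]:
        if self.abundance_profile is not None:
            return dict(self.abundance_profile)
        return _default_profile(self.genera)

    @property
    def expressed(self) -> tuple[str, ...]:
        if self.expressed_genera is not None:
            return tuple(self.expressed_genera)
        return (self.genera[0],)


# ---------------------------------------------------------------------------
# reference catalog


def _random_orf(rng: np.random.Generator, length: int) -> str:
    codons = rng.integers(0, len(_SENSE_CODONS), length // 3)
    return "".join(_SENSE_CODONS[i] for i in codons)


def _mutate_no_stop(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site with probability ``rate``; the substituted base is
    drawn uniformly from the alternatives that do not create a stop codon, so
    the per-site Hamming distribution stays exactly binomial."""
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for pos in hits:
        c0 = pos - pos % 3
        codon = arr[c0 : c0 + 3]
        within = pos % 3
        choices = []
        for b in _BASES:
            if b == arr[pos]:
                continue
            codon[within] = b
            if "".join(codon) not in _STOPS:
                choices.append(b)
        codon[within] = arr[pos]
        arr[pos] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def generate_reference_catalog(config: SimulationConfig) -> Catalog:
    """Multi-genus nifHDK catalog plus non-nif decoy records.

    One ancestral sequence per gene; each genus's copy differs from the
    ancestor by binomially sampled substitutions at the configured
    divergence.  Decoys are random-composition (stop-free) genes labelled
    ``decoy``.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for gene in config.genes:
        ancestor = _random_orf(rng, config.gene_lengths[gene])
        for gi, genus in enumerate(config.genera):
            nt = _mutate_no_stop(rng, ancestor, config.inter_genus_divergence)
            records.append(
                NifGeneRecord(
                    record_id=f"{genus}_{gene}",
                    genus=genus,
                    strain=f"sim{gi + 1:02d}",
                    gene=gene,
                    nucleotide_seq=nt,
                    protein_seq=translate(nt),
                    source="synthetic",
                )
            )
    for d in range(config.n_decoy_genes):
        nt = _random_orf(rng, config.decoy_gene_length)
        records.append(
            NifGeneRecord(
                record_id=f"decoy_{d + 1:02d}",
                genus=f"decoy_org_{d + 1:02d}",
                strain="sim",
                gene="decoy",
                nucleotide_seq=nt,
                protein_seq=translate(nt),
                source="synthetic",
            )
        )
    return Catalog(records)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    catalog: Catalog, config: SimulationConfig
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Shotgun reads from the catalog under the genus-abundance profile.

    Reads are drawn genus-proportionally (decoy reads with probability
    ``decoy_fraction``), from a uniformly random offset and strand, with
    i.i.d. substitution errors at ``error_rate``; quality strings are
    constant at ``config.quality``.  Returns the reads and a truth table
    with one row per read.
    """
    rng = np.random.default_rng(config.seed + 1)
    nif = catalog.nif_records()
    decoys = catalog.decoy_records()
    if not nif:
        raise ValueError("catalog contains no nif records")
    if config.decoy_fraction > 0 and not decoys:
        raise ValueError("decoy_fraction > 0 but catalog has no decoy records")
    shortest = min(len(r.nucleotide_seq) for r in catalog)
    if config.read_length > shortest:
        raise ValueError(
            f"read_length {config.read_length} exceeds shortest source "
            f"sequence ({shortest} nt)"
        )

    profile = config.profile
    by_genus: dict[str, list[NifGeneRecord]] = {}
    for r in nif:
        by_genus.setdefault(r.genus, []).append(r)
    missing = [g for g in profile if g not in by_genus]
    if missing:
        raise ValueError(f"profile genera missing from catalog: {missing}")

    # flat source pool: decoy pool + per-genus pools, length-weighted within
    sources: list[NifGeneRecord] = []
    weights: list[float] = []
    for genus, frac in profile.items():
        recs = by_genus[genus]
        lens = np.array([len(r.nucleotide_seq) for r in recs], float)
        for r, w in zip(recs, lens / lens.sum()):
            sources.append(r)
            weights.append((1.0 - config.decoy_fraction) * frac * w)
    if config.decoy_fraction > 0:
        lens = np.array([len(r.nucleotide_seq) for r in decoys], float)
        for r, w in zip(decoys, lens / lens.sum()):
            sources.append(r)
            weights.append(config.decoy_fraction * w)
    w = np.array(weights)
    w = w / w.sum()

    picks = rng.choice(len(sources), size=config.n_reads, p=w)
    reads = []
    truth_rows = []
    L = config.read_length
    qual = [config.quality] * L
    for k, pick in enumerate(picks):
        rec = sources[pick]
        seq = rec.nucleotide_seq
        offset = int(rng.integers(0, len(seq) - L + 1))
        fragment = seq[offset : offset + L]
        frag, n_errors = _apply_errors(rng, fragment, config.error_rate,
                                       config.indel_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = str(Seq(frag).reverse_complement())
        read_id = f"read_{k + 1:06d}"
        sr = SeqRecord(Seq(frag), id=read_id, description="")
        sr.letter_annotations["phred_quality"] = (
            qual if len(frag) == L else [config.quality] * len(frag)
        )
        reads.append(sr)
        truth_rows.append(
            {
                "read_id": read_id,
                "genus": rec.genus,
                "gene": rec.gene,
                "record_id": rec.record_id,
                "strand": strand,
                "offset": offset,
                "n_errors": n_errors,
                "is_decoy": rec.gene == "decoy",
            }
        )
    return reads, pd.DataFrame(truth_rows)


def _apply_errors(
    rng: np.random.Generator, fragment: str, error_rate: float, indel_rate: float
) -> tuple[str, int]:
    arr = list(fragment)
    n_errors = 0
    if error_rate > 0:
        hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
        for pos in hits:
            alts = [b for b in _BASES if b != arr[pos]]
            arr[pos] = alts[rng.integers(0, 3)]
        n_errors = len(hits)
    if indel_rate > 0:
        out = []
        for b in arr:
            u = rng.random()
            if u < indel_rate / 2:
                n_errors += 1
                continue  # deletion
            out.append(b)
            if u > 1 - indel_rate / 2:
                out.append(_BASES[rng.integers(0, 4)])
                n_errors += 1
        arr = out
    return "".join(arr), n_errors


def low_quality_tail_read(
    seq: str, read_id: str = "tail_read", head_quality: int = 35,
    tail_length: int = 0, tail_quality: int = 10,
) -> SeqRecord:
    """A read whose last ``tail_length`` bases have low quality (for
    exercising 3' quality trimming)."""
    if tail_length > len(seq):
        raise ValueError("tail longer than read")
    sr = SeqRecord(Seq(seq), id=read_id, description="")
    sr.letter_annotations["phred_quality"] = [head_quality] * (
        len(seq) - tail_length
    ) + [tail_quality] * tail_length
    return sr


# ---------------------------------------------------------------------------
# expressed peptides


def simulate_expressed_peptides(
    catalog: Catalog, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate identified-peptide lists from expressed NifHDK proteins.

    Each tryptic peptide (length >= 6) of every expressed genus's NifHDK
    protein is detected with probability ``peptide_detection_prob`` in each
    replicate, independently; decoy peptides are drawn from the decoy
    proteins' digests.  Returns (peptide table, truth table).
    """
    rng = np.random.default_rng(config.seed + 2)
    expressed = config.expressed
    unknown = set(expressed) - set(catalog.genera)
    if unknown:
        raise ValueError(f"expressed genera not in catalog: {sorted(unknown)}")
    if not expressed and config.peptide_detection_prob > 0:
        warnings.warn("empty expressed set: only decoy peptides will be produced")

    true_peptides = []  # (peptide, genus, gene)
    for rec in catalog.nif_records():
        if rec.genus not in expressed:
            continue
        for pep in digest_protein(rec.protein_seq.rstrip("*")).peptides:
            true_peptides.append((pep.sequence, rec.genus, rec.gene))
    decoy_pool = []
    for rec in catalog.decoy_records():
        prot = rec.protein_seq.rstrip("*")
        if "*" in prot:
            continue  # decoy references may be arbitrary; only clean ORFs digest
        for pep in digest_protein(prot).peptides:
            decoy_pool.append(pep.sequence)

    rows = []
    truth_rows = []
    for rep in range(1, config.n_replicates + 1):
        for pep, genus, gene in true_peptides:
            if rng.random() < config.peptide_detection_prob:
                rows.append((config.sample_name, rep, pep))
                truth_rows.append(
                    (config.sample_name, rep, pep, genus, gene, False)
                )
        if decoy_pool and config.decoy_peptides_per_replicate > 0:
            n = min(config.decoy_peptides_per_replicate, len(decoy_pool))
            for i in rng.choice(len(decoy_pool), size=n, replace=False):
                rows.append((config.sample_name, rep, decoy_pool[i]))
                truth_rows.append(
                    (config.sample_name, rep, decoy_pool[i], "decoy", "decoy", True)
                )
    peptides = pd.DataFrame(rows, columns=["sample", "replicate", "peptide"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "replicate", "peptide", "genus", "gene", "is_decoy"],
    )
    return peptides, truth


# ---------------------------------------------------------------------------
# assay measurements


@dataclass(frozen=True)
class TrueRates:
    """Ground-truth fixation activities for one plant line."""

    ara_c2h4_nmol_per_plant_h: float
    n2_ug_per_plant_day: float

    def __post_init__(self) -> None:
        if self.ara_c2h4_nmol_per_plant_h < 0 or self.n2_ug_per_plant_day < 0:
            raise ValueError("true rates must be non-negative")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)


def simulate_assay_measurements(
    true_rates: Mapping[str, TrueRates],
    noise_cv: float = 0.2,
    seed: int = 0,
    n_replicates: int = 3,
    root_dry_weight_g: float = 50.0,
    n_content_percent: float = 0.6,
    ara_incubation_hours: float = 24.0,
    isotope_incubation_hours: float = 23.0,
    control_delta15n_permil: float = 2.0,
    baseline_ethylene_nmol: float = 2.0,
    r_standard: float = 0.0036765,
) -> pd.DataFrame:
    """Per-plant raw assay measurements whose derived rates recover the true
    rates in expectation (exactly, when ``noise_cv`` is 0)."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    atom_ctrl = delta_to_atom_percent(control_delta15n_permil, r_standard)
    rows = []
    for line, tr in true_rates.items():
        signal = tr.ara_c2h4_nmol_per_plant_h * ara_incubation_hours
        # atom% excess that yields the true isotope rate at the base biomass
        a_true = (
            tr.n2_ug_per_plant_day
            * 100.0
            / (
                root_dry_weight_g
                * (n_content_percent / 100.0)
                * 1e6
                * (24.0 / isotope_incubation_hours)
            )
        )
        f = _lognormal_factor(rng, noise_cv, 6 * n_replicates).reshape(n_replicates, 6)
        for rep in range(1, n_replicates + 1):
            base, sig, bio, nc, aexc, _spare = f[rep - 1]
            delta = atom_percent_to_delta(atom_ctrl + a_true * aexc, r_standard)
            rows.append(
                {
                    "line": line,
                    "replicate": rep,
                    "ethylene_with_nmol": baseline_ethylene_nmol * base + signal * sig,
                    "ethylene_without_nmol": baseline_ethylene_nmol * base,
                    "ara_incubation_hours": ara_incubation_hours,
                    "plants": 1,
                    "delta15n_permil": delta,
                    "control_delta15n_permil": control_delta15n_permil,
                    "root_dry_weight_g": root_dry_weight_g * bio,
                    "n_content_percent": n_content_percent * nc,
                    "isotope_incubation_hours": isotope_incubation_hours,
                }
            )
    return pd.DataFrame(rows)
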