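# Methods

## Scope and model

`diazoscan` treats "which microbiome members fix N₂?" as three linked
sub-problems: detecting nitrogenase structural genes (*nifH*, *nifD*,
*nifK*) in shotgun reads, confirming their expression through peptide
evidence, and quantifying whole-plant fixation. The package implements
the computational stages only; gas-chromatography, mass-spectrometry
identification and wet-lab steps are consumed as their tabular outputs
(ethylene amounts, δ¹⁵N values, identified peptide sequences).

## Read trimming

Trimming follows prinseq-lite conventions with defaults
`trim_left=20, trim_right=5, trim_qual_right=30, min_qual_mean=20,
min_len=70`: fixed end trims first, then repeated removal of 3′ bases
below Q30, then discard on mean quality and length. A read whose
quality tail erodes it below 70 nt is discarded on the length filter.

## Two-stage nif screening

Stage 1 aligns each read (both strands) against every nif reference with
an exact affine-gap Smith–Waterman under a BLASTN-like scheme
(match +2, mismatch −3; a gap of length L costs 5 + 2L). Percent
identity is matched columns / alignment columns, gaps counted as
columns and N never counting as a match — the common BLAST-report
convention; the alternative (ungapped denominator) would shift
identities by well under a percent at the error rates modelled here. A
read becomes a candidate when identity meets the gene threshold (nifH
90%, nifD/nifK 80%, nucleotide space) and at least `min_read_coverage`
(default 0.5) of the read is inside the alignment; the coverage floor
exists because a 20-nt perfect match would otherwise clear any identity
threshold. Ties at equal best score across genera are reported as
taxon `ambiguous` rather than an arbitrary winner.

Stage 2 re-searches candidates against a background database containing
the nif references plus non-nif decoys (a stand-in for a comprehensive
protein/nucleotide collection). A candidate is retained only when its
best background hit is a nif record of the same gene with
E = K·m·n·e^(−λS) ≤ 10⁻¹⁰ (Karlin–Altschul defaults λ=0.625, K=0.41 for
the +2/−3 scheme; both are configuration since they are
calibration-sensitive). This is a deterministic automation of
"remove false hits by manual inspection": anything whose closest
relative is not the expected gene is dropped, and stage 2 can only
demote, never promote.

Performance: an edlib semi-global edit-distance prescreen shortlists
(reference, strand) pairs within 8 edits of the per-read best before
exact Smith–Waterman scoring. Because substitution-dominated reads rank
nearly identically under unit edit costs and the affine scheme, the
margin is generous; best-hit choice and ties are always decided by the
exact alignment score on the shortlist. With 10,000 150-nt reads and a
15-gene catalog a full two-stage screen runs in about a minute on one
CPU; the margin (`prescreen_margin`) can be raised if references ever
sit closer than a few edits apart.

## Translated peptide database

Each retained read is translated in the frame implied by its alignment
(subject position 0 starts a codon; the in-read offset is the alignment
start difference mod 3), reverse-strand reads via their reverse
complement. If a sequencing error introduces a stop in the implied
frame, the best stop-free frame among all six is chosen by exact 4-mer
overlap with the best hit's protein; a read with stops in all six frames
is dropped with a logged reason. Entries carry the best hit's
genus/strain/gene; with `include_besthit_proteins` the full-length
protein of every distinct best-hit record is appended (exposed as a
flag because gene-level practice differs on whether reference proteins
accompany translated reads). Translation uses the bacterial genetic
code; N-containing codons give X, and X never matches in peptide search.

## Peptide assignment and summaries

A peptide matches an entry iff it is an exact contiguous substring
(case-insensitive). I/L equivalence is off by default — 100% identity is
taken literally — but switchable, since mass spectrometry cannot
distinguish the isobaric pair. Peptides are deduplicated per
(sample, replicate, peptide): counts are of peptides, not spectra.
Verdicts partition calls into genus-resolved, multi-assigned (≥2
genera) and unmatched; summaries count genus-verdict peptides per genus
× Nif protein × sample, with an optional "Others" pooling threshold,
and flag per genus `detected_all_replicates` (≥1 peptide in every
declared replicate) and `nifHDK_simultaneous` (≥1 peptide for each of
NifH, NifD, NifK in the sample). The conjunction of both flags is the
package's operational definition of a functional diazotroph.

## Fixation rates

ARA is (ethylene with acetylene − without) / h / plant and may be
negative (reported, not clamped). The ARA→N conversion uses 4 mol C₂H₄
per mol N₂ and 28 g mol⁻¹ N₂ — the theoretical electron-pair
stoichiometry, consistent to printed rounding with the published
conversion columns (585.8 × 24/4 = 3515; × 0.028 = 98.4); the ratio is
configurable because 3 is a common empirically calibrated alternative.
δ¹⁵N converts to atom% against the air-N₂ standard R = 0.0036765. The
¹⁵N₂ rate is b·(c/100)·(a/100)·10⁶·(24/t) µg N plant⁻¹ day⁻¹; no
correction is applied by default for a partially labelled gas phase
(the published tables are consistent with the uncorrected formula), but
`gas_atom_percent` applies the standard excess-fraction correction when
wanted. Rates are computed per replicate and averaged afterwards;
means of derived ratios differ from ratios of column means, which is
why summary tables built from the replicate level cannot be reproduced
exactly from printed column means alone.

## Synthetic data: what it emulates, and what not

The generators plant known structure so recovery is measurable:

- **Catalog** — one ancestral sequence per gene built from the 61 sense
  codons; each genus's copy mutates each site independently at
  `inter_genus_divergence` (default 0.10, giving ≈81–83% cross-genus
  nucleotide identity — distinct genera that still exercise both
  thresholds). Substituted bases are drawn among alternatives that do
  not create a stop, keeping per-site Hamming distances exactly binomial
  while guaranteeing clean ORFs. Default gene lengths 879/1449/1560 nt
  sit near the real *nifH*/*nifD*/*nifK* sizes and keep NifH vs NifDK
  protein masses in distinct ranges.
- **Reads** — genus chosen by the abundance profile (default: one
  dominant genus at 70%, remainder geometric — a dominant-diazotroph
  community), gene by length weight within genus, offset and strand
  uniform, substitutions i.i.d. at `error_rate` (default 0.01); decoy
  reads (default 10%) come from random-composition non-nif genes.
  Qualities are constant Q30; `low_quality_tail_read` builds explicit
  low-quality tails for trimming tests. Defaults use 10,000 reads of
  150 nt, three replicates.
- **Peptides** — tryptic peptides (≥6 aa) of the expressed genera's
  NifHDK proteins, each detected with probability 0.8 per replicate,
  plus a fixed number of decoy-protein peptides.
- **Assays** — raw per-plant tables built by inverting the rate
  formulas from planted true rates, with independent mean-one lognormal
  factors (given CV) on the ethylene signal, biomass, N content and
  atom% excess, so derived rates are unbiased and exact at CV 0.

Not modelled: quality-dependent miscall profiles, paired-end inserts,
indel-rich platforms (an optional indel rate exists, default 0),
amplification bias, MS spectra and identification error. Passing tests
therefore demonstrate correctness of the screening/assignment logic
under substitution-type divergence and detection dropout — not
robustness to every artefact of real MiSeq or Mascot output.

## Numerical and design choices

- Alignment scoring, thresholds and Karlin–Altschul constants are all
  explicit configuration with the defaults above; raising an identity
  threshold can only shrink the retained set (tested property).
- Coordinates are 0-based half-open internally, 1-based inclusive in
  reports; strand ties resolve to '+'.
- Catalog enrichment collapses exact (gene, nucleotide) duplicates
  only, keeping the base copy; no clustering. The same sequence under
  two gene labels is an error, not a silent choice.
- Tryptic cleavage is after K/R not before P, zero missed cleavages by
  default (configurable); sub-6-residue fragments are dropped from the
  search set but kept in a tally so digestion conserves the parent.
- Degenerate inputs fail loudly: empty sequences, empty background
  databases, non-codon gene lengths, profiles not summing to 1, zero
  incubation times and sub-(−1000)‰ deltas all raise.

## Problem sizes

Default end-to-end checks run 10,000 reads against a 5-genus, 19-record
catalog and ~400 expressed peptides per replicate — small enough for a
laptop core in minutes, large enough that binomial checks on planted
fractions have power. Unit tests use 3-genus catalogs with 450–660-nt
genes.

## Known limitations

- Stage-1 identity is nucleotide-space; a translated-space variant
  would be more sensitive at high divergence but is out of scope.
- The automated stage-2 rule is a stand-in for expert curation; reads
  whose best background hit is missing from the background database are
  removed, which is conservative.
- Genus assignment is best-hit with tie→ambiguous; no lowest-common-
  ancestor walk over near-ties.
- Alternative nitrogenases (*vnfH*, *anfH*, archaeal) pass through as
  labels only; no dedicated handling.
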