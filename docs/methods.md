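# Methods

## Scope and model

`venomkit` implements the computational core of an integrated venom-gland
proteo-transcriptomic analysis: given assembled contigs with read counts, a
homology-annotation table, signal-peptide annotations and peptide-spectrum
evidence, it quantifies transcript abundance, mines toxin transcripts by
keyword, parses toxin precursors and infers their C-terminal processing
state from mass, classifies cysteine scaffolds, assigns rational toxin
names, and maps the proteome back onto the transcriptome. Heavy upstream
steps (read assembly, homology search, signal-peptide prediction, spectral
scoring) are deliberately consumed as tables, never re-implemented: the
package starts where those tools stop.

## Transcript abundance

TPM is computed directly from its definition,
`tpm_i = 1e6 (c_i/l_i) / Σ_j (c_j/l_j)`, with effective length defaulting
to contig length. An optional mean-fragment-length correction
(`l_eff = l − μ_frag + 1`, floored at 1) is available because assembled
transcripts shorter than the library fragment length otherwise overstate
their sampling probability; it is off by default since the upstream
quantifier's fragment-length settings are usually unknown. Toxin tables
apply an inclusive TPM ≥ 1 floor; the top-expressed report ranks by
descending TPM with contig-id tie-break so output order is total.

## Precursor processing and masses

A toxin precursor is partitioned signal / propeptide / mature at externally
annotated cleavage positions (1-based segment ends). Propeptide ends are
only meaningful when proteomic evidence or explicit annotation supplies
them, so absent annotations simply collapse segments to empty.

Peptide masses are residue sums plus one water, in both monoisotopic and
average conventions (via pyteomics residue tables). The monoisotopic value
is the verification surface for printed toxin masses. C-terminal
amidation-signal processing is modelled by the grammar *glycine followed by
0–2 basic residues* (G, GK, GR, GKK, GRR): candidates are the intact
peptide, stepwise des-basic variants, the des-G variant, and its amidated
form at −0.98402 Da (OH→NH₂). Matching an observed mass picks the candidate
with minimal absolute error; ties prefer the less-processed state, because
claiming additional processing requires positive evidence. The default
acceptance window is 0.5 Da, a MALDI-TOF-scale tolerance for ~3 kDa
peptides; it is configurable for higher-resolution instruments.

## Alignment statistics

Pairwise comparison uses a deterministic Needleman–Wunsch global alignment:
match +1, same conservative class 0, other mismatch −1, gap −2, traceback
ties broken diagonal > up > left. The conservative classes default to
{AVLIM, FWY, ST, KR, DE, NQ, H, C, G, P}; grouping Ala with the aliphatic
residues is required for an A↔V exchange to count as conservative, which is
how venom-peptide isoform similarity is conventionally reported. Percent
identity and similarity are counted over all alignment columns (gaps and X
columns count in the denominator, never the numerator). The published
isoform percentages this package reproduces come from gapless alignments,
so they are insensitive to the gap penalty choice.

## Cysteine scaffolds and frameworks

Scaffold strings encode inter-cysteine spacings (`x_n`) and adjacent
cysteines (`CC`); parsing recovers `(length, n_cys)` and the formatter is
the parser's exact inverse. Toxin-like peptides are those with an even
cysteine count ≥ 4 — the inclusive reading, which is what the published
four-cysteine framework-I tables require. Classification is pattern-level
only: framework I is exactly 4 cysteines as CC-C-C, ICK (frameworks VI/VII)
exactly 6 as C-C-CC-C-C, any other even count ≥ 4 is `other_even`
(putatively novel scaffolds, including published 8- and 10-cysteine cases).
Disulfide prediction is the count `n_cys/2` plus a canonical connectivity
label (I: 1-3/2-4; VI/VII: 1-4/2-5/3-6); knottedness is never structurally
verified, and an odd cysteine count is an error (a free cysteine cannot be
fully paired).

## Nomenclature

The peptide grammar is `<prefix>-<stem>-<Gs><family><isoform>[_<variant>]`
(Greek activity prefix or `U<n>` for unknown activity, genus-derived stem,
two-letter species code); the protein grammar is
`<Generic-Name>-<family><isoform>[_<variant>]-<G>-<species>`. The stem
("paraponeritoxin") is configuration, not derived — there is no reliable
morphological rule. Parsing accepts published typography (Unicode
subscripts, underscore-subscript artefacts, verbatim misspellings); the
builder always emits the canonical form, and a spelling-normalisation table
is available but never applied implicitly.

Batch assignment must be a pure function of `(sequences, TPMs)`: family
numbers, isoform letters and nucleotide-variant numerals are all ranked by
descending peak TPM with lexicographic tie-breaks. Abundance ranking was
chosen over input order because the published variant numbering follows
descending expression and because input-order "discovery" would make names
depend on file ordering. Isoform letters extend past `z` as `aa, ab, …`.

## Proteome mapping

In-silico tryptic digestion cleaves after K/R except before P; full mode
bounds internal missed cleavages (default ≤ 3), semi mode adds every
truncation of a fully-tryptic peptide with one ragged terminus; peptides
shorter than 5 residues are dropped. PSM filtering is conjunctive: a
confidence floor (95%) and a target-decoy FDR threshold — the lowest score
cut at which decoys/targets among accepted records stays under 2% (a
`2·decoy/total` estimator is selectable). Peptides are located by exact
substring in ORF translations with Ile/Leu distinct (sequence-database
matching, not spectral). Identical protein sequences collapse into one
group whose contigs share counts and coverage; uniqueness is per group.
Proteins need ≥ 2 matched peptides and best −10lgP ≥ 15; matches without a
predicted signal peptide are partitioned out of the secreted-toxin list
with an explicit reason rather than silently dropped, so the filter
conserves records. The 50 ppm / 0.1 Da mass tolerances exist as validity
predicates on evidence records (`evidence_mass_ok`), not as spectrum
matching.

## Synthetic dataset generator

The generator emulates the data shape the pipeline consumes: toxin
precursors with signal (24-residue, Met + hydrophobic core) + optional
propeptide + mature segments, about half carrying a GK amidation tail;
framework peptides realising published scaffold templates exactly;
housekeeping contigs; annotations whose descriptions carry family keywords
(toxins, e-values 1e-20..1e-6) or junk descriptions straddling the e-value
cutoff; and target/decoy evidence from tryptic digestion of a subset of
secreted precursors. Defaults: 300 contigs, 20 toxin precursors (2 without
signal peptide), 15 framework peptides, 5% identical-protein variant
groups, log-normal expression (σ = 2) with one toxin forced to a 30% read
share, 100k multinomial reads, target scores ~N(40,10) vs decoy ~N(15,5)
truncated at zero so the 2% FDR cut lands mid-distribution, decoy:target
0.5, 60% of secreted toxins detectable. CDSs are reverse-translated with
uniform synonymous codon choice (codon bias is irrelevant to the stages
under test) and flanked by in-frame stops inside random UTR, so the planted
ORF is recovered exactly.

What the generator does **not** emulate: sequencing error, mis-assembly,
chimeric contigs, spectral noise or score/confidence correlation
structure, PTMs other than the amidation signal, and homology between
planted families. Passing end-to-end tests therefore demonstrates the
pipeline's logic and determinism, not robustness to real-data artefacts.

## Numerical and degenerate-input choices

All randomness flows through one `numpy` Generator seeded by the caller;
regeneration is byte-identical. Serialised TPMs are rounded to 2 dp (full
precision internally), masses to 4 dp internally and 1 dp where published
values are compared. Zero-count TPM input is an error (undefined
normalisation), as are empty sequences, out-of-order cleavage positions,
odd cysteine counts in disulfide prediction, and evidence with no target
records. Ambiguous codons translate to X; X columns never count as
identical or similar. The e-value filter is strict (`<` cutoff), the TPM
floor inclusive (`>=`), per their published phrasings.

## Problem sizes

Default test and acceptance runs use the 300-contig generator dataset
(~1200 ORFs, ~90 evidence records); property tests use 1000 random
sequences for translation, 10,000 for framework classification, and
exhaustive enumeration oracles for alignment (length ≤ 6) and FDR
thresholds. These sizes keep every oracle brute-forceable while exercising
all code paths.

## Known limitations

Signal peptides and spectral scores are consumed, never predicted, so the
pipeline is only as good as its upstream annotations; the amidation grammar
covers G + ≤2 basics only; multiple sequence alignment is out of scope
(pairwise only); coverage counts all occurrences of a peptide including
incidental repeats; and the keyword map, while user-configurable, cannot
resolve descriptions that carry no informative keyword.
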