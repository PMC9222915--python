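# Methods

This note records how each stage of `csd-typer` works, the parameter choices
and their rationale, and the limitations we know about.

## Target region and inputs

The hypervariable region (HVR) of *csd* lies in exon 7; we use the interval
`NC_037640.1:11771976-11772119` (1-based, inclusive, 144 bp on the Amel_HAv3.1
assembly) as the extraction target. `extract_region_reads` keeps primary
alignments overlapping the interval by at least `min_overlap_bp` (default 1)
reference base; secondary, supplementary and unmapped records are skipped.
The rest of the pipeline is alignment-free, so it accepts FASTQ/FASTA input
directly when no alignments exist.

## Assembly

`assembler.assemble` is a greedy overlap–layout–consensus assembler written
for this one job: separating two divergent haplotypes in a small read pile.

* **Overlap model.** Gap-free (substitutions only) dovetail overlaps on a
  single alignment diagonal, both orientations. An overlap qualifies if its
  length ≥ `min_overlap` (default 40) and identity ≥ `min_identity`
  (default 0.90). Overlaps are scored `matches − 2 × mismatches`
  (`mismatch_penalty` configurable).
* **Greedy merging.** The best-scoring qualifying overlap between any two
  units (reads or partial contigs) is merged first; ties break
  deterministically by longer combined length, forward orientation, then
  lexicographic labels. Merging repeats until no qualifying overlap remains.
* **Candidate search.** Exhaustively enumerating diagonals is quadratic in
  sequence length per pair, so candidate diagonals are seeded with exact
  8-mers. This is lossless for qualifying overlaps: an overlap of length
  L ≥ 40 with at most ⌊0.1·L⌋ mismatches always contains an exact match of
  length ≥ 8: by pigeonhole, the mismatches cut the L columns into at most
  ⌊0.1·L⌋ + 1 exact runs, the longest of which has length
  ≥ ⌈(L − ⌊0.1·L⌋) / (⌊0.1·L⌋ + 1)⌉ ≥ 8 for all L ≥ 40. `assemble(..., exhaustive=True)`
  disables seeding; the test suite checks both modes agree.
* **Consensus.** Per-column majority over the layout; ties break first by
  summed base quality, then alphabetically. `N` never outvotes a concrete
  base.

Why not reuse an existing assembler? Analyses of this kind have typically
used CAP3 with `-o 40 -p 90`; CAP3 is unmaintained, binary-distributed and
awkward to pin in a reproducible Python package, and the job here (tens to
hundreds of reads, two expected haplotypes) does not need its full
generality. We reimplemented
the relevant semantics — overlap length/identity thresholds, greedy
best-overlap-first merging, majority consensus — and validate the merging
logic against an exhaustive-enumeration oracle in the tests.

## Translation and peptide selection

Contigs are translated in all six frames (Biopython, standard code; codons
containing `N` render as `X`). Within each frame we take the span from the
first `SSLS` to the last `IEQI`. A span is a valid HVR peptide if it contains
no stop (`*`) or ambiguity (`X`) character and its length is within
[20, 80] aa — generous bounds around the observed 27–50 aa range, so the
filter rejects garbage without clipping genuine novel alleles. Rejections are
typed: `no_motif`, `internal_stop`, `length_out_of_range`, and
`ambiguous_multi_frame` when more than one frame yields a valid span.

## Genotyping and the reporting funnel

A sample passes the assembly filter iff it produced **exactly two contigs and
at most one singleton read**. This is a conservative proxy for "both
haplotypes assembled cleanly": more contigs or leftovers indicate
under-merging, contamination or a collapsed assembly. A passing sample is
genotyped when both contigs yield valid peptides; otherwise it is rejected as
`one_allele_truncated` or `both_invalid`. Two identical peptides are kept but
flagged `homozygous_warning`, since diploid *csd* homozygotes should not
survive to sampling and such a call usually means the assembler collapsed two
similar alleles.

`funnel_report` summarizes a cohort: samples in → passing the filter →
contigs translated → valid peptides → samples with both alleles → final
sequences (always exactly 2 × resolved samples).

## Allele catalogue

Alleles are clustered by **exact amino-acid identity** (case-insensitive).
Allele ids are assigned by descending copy count, ties by order of first
observation. Frequencies are reported per subspecies (copies / subspecies
total) and against the whole cohort, as percentages rounded half-up to two
decimals. Sharing classes partition alleles by the number of subspecies they
occur in: private (1), shared2 (exactly 2), shared3plus (≥ 3). The diversity
ratio is distinct alleles / total sequenced copies; `format_diversity_ratio`
defaults to truncation at two decimals (88/138 = 0.6376… prints `0.63`),
with `mode="half_up"` available.

`match_known` compares a peptide against the packaged database of known HVR
peptides (GenBank accessions) by exact identity. No similarity threshold is
involved: a single substitution makes an allele novel, which mirrors how the
reference catalogue distinguishes known from novel alleles.

### Packaged reference catalogue

`csd_typer/data/` ships a fixture of 88 distinct HVR alleles observed across
138 sequenced copies from seven subspecies/breeds (ligustica 68, buckfast 42,
carnica 10, sicula 8, hybrid_carnica 4, mellifera 4, cecropia 2), with
per-subspecies copy counts and known-accession matches (68 alleles known, 20
novel). All summary statistics in the README are recomputed from this fixture
at run time, never hard-coded.

## Phylogenetics

`phylo_lite` is intentionally minimal. Pairwise distance between peptides is
the unit-cost global (Needleman–Wunsch) edit distance divided by the number of
alignment columns, giving a p-distance-like value in [0, 1]; the pair is
canonicalized by lexicographic order before alignment because co-optimal
alignments can differ in column count between argument orders. Trees are
built with a hand-written canonical Saitou–Nei neighbor-joining
implementation (deterministic tie-breaking by label order; negative branch
lengths clamped to zero and counted on `tree.negative_lengths_clamped`),
cross-checked in the tests against dendropy's NJ on additive matrices.
Rooting on an outgroup inserts the root at the midpoint of the outgroup's
pendant edge. NJ on normalized edit distances supports a qualitative look at
allele relatedness only; no model-based inference is claimed.

## Synthetic data generator

`synthetic_data.generate_cohort` emulates the sequencing experiment the
pipeline targets:

* Each sample is a diploid with two alleles drawn from a pool (default: the
  88 packaged peptides) under subspecies weights proportional to a plausible
  cohort composition; pairs are redrawn until they differ by ≥ 5 aa
  (`min_pair_aa_diff`), matching the assembler's design envelope of clearly
  heterozygous samples.
* Each haplotype is the back-translated allele (uniform choice among
  synonymous codons, seeded) embedded in 200 nt random flanks drawn
  **independently per haplotype**.
* Reads: length 150, count `round(depth × haplotype_length / read_length)`
  per haplotype (default depth 20×), uniform start positions and strands,
  i.i.d. substitution errors at `error_rate` (default 0.001).

**What it does not emulate.** Real haplotypes share most of their flanking
sequence outside the HVR; there, phasing is driven by paired-end information
and the divergent region itself. Independent flanks sidestep this, so the
generator validates the assembler/translator/genotyper chain, not read-pair
phasing. It also ignores indel sequencing errors, quality-score variation,
coverage bias and mapping artifacts. Published funnel attrition (e.g. samples
lost to truncated or unresolvable assemblies in real cohorts) is therefore
not reproduced by synthetic data; the pipeline's filters are exercised by
dedicated unit tests instead.

## Determinism

Every stage is deterministic given its inputs and configuration: tie-breaks
are total orders, the generator uses a single seeded RNG, and report tables
are written in a canonical order. The test suite checks byte-identical
re-runs for both the generator and the pipeline tables.

## Validation summary

`tests/test_acceptance.py` holds the headline checks: exact reproduction of
the reference-catalogue structure (88 alleles; lengths 27–50; sharing classes
70/16/2; 68 known / 20 novel), exact inversion of the printed frequency
arithmetic, ≥ 95% exact genotype recovery on a 50-sample synthetic cohort at
20× / 0.1% error, assembler conservation and junction-validity properties,
translator strand-invariance and back-translate→select identity across all
alleles and 10 seeds, and NJ correctness on closed-form and additive
matrices. The wider suite (~140 tests) validates each module against
independent oracles (hand codon tables, brute-force overlap search, dendropy
NJ, cigar-walking SAM extraction).
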