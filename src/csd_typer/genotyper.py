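"""Per-sample acceptance filtering and diploid genotype calling.

A sample passes assembly filtering only when its reads assembled into
exactly two contigs with at most one leftover singleton — the signature of
a clean diploid reconstruction (one contig per allele). Both contigs must
then translate to valid HVR peptides for the genotype to be called; samples
with one truncated allele are dropped so the final sequence set always
contains both alleles of every surviving sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from csd_typer.assembler import Assembly
from csd_typer.translator import HvrPeptide, Rejection, select_hvr_peptide


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str = ""  # contig_count | singleton_count

    def __bool__(self) -> bool:
        return self.passed


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of HVR alleles for one diploid sample.

    The pair is canonicalized lexicographically by peptide sequence.
    Identical peptides (a homozygous call) are biologically anomalous for a
    viable worker bee and carry a ``homozygous_warning`` flag but are kept.
    """

    sample_id: str
    subspecies: str
    alleles: tuple[HvrPeptide, HvrPeptide]
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a.aa_seq > b.aa_seq:
            object.__setattr__(self, "alleles", (b, a))


@dataclass
class FunnelReport:
    """Counts surviving each pipeline stage.

    Sample-level counts are monotone non-increasing; the final sequence
    count is exactly twice the number of fully resolved samples.
    """

    n_samples_in: int = 0
    n_pass_assembly_filter: int = 0
    n_contigs_translated: int = 0
    n_peptides_valid: int = 0
    n_samples_both_alleles: int = 0
    n_sequences_final: int = 0

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("samples_in", self.n_samples_in),
            ("samples_pass_assembly_filter", self.n_pass_assembly_filter),
            ("contigs_translated", self.n_contigs_translated),
            ("peptides_valid", self.n_peptides_valid),
            ("samples_both_alleles", self.n_samples_both_alleles),
            ("sequences_final", self.n_sequences_final),
        ]


def filter_sample(assembly: Assembly, max_singletons: int = 1) -> FilterResult:
    """Pass iff exactly 2 contigs and at most ``max_singletons`` singletons."""
    if len(assembly.contigs) != 2:
        return FilterResult(False, "contig_count")
    if len(assembly.singletons) > max_singletons:
        return FilterResult(False, "singleton_count")
    return FilterResult(True)


def call_genotype(
    sample_id: str,
    subspecies: str,
    assembly: Assembly,
    **select_kwargs,
) -> Genotype | Rejection:
    """Call the diploid genotype from a filter-passing two-contig assembly."""
    if not filter_sample(assembly):
        raise ValueError(
            f"sample {sample_id!r}: call_genotype requires a filter-passing assembly"
        )
    results = [select_hvr_peptide(c, **select_kwargs) for c in assembly.contigs]
    peptides = [r for r in results if isinstance(r, HvrPeptide)]
    if len(peptides) == 0:
        return Rejection("both_invalid", "; ".join(r.reason for r in results))
    if len(peptides) == 1:
        bad = next(r for r in results if isinstance(r, Rejection))
        return Rejection("one_allele_truncated", bad.reason)
    flags = set()
    if peptides[0].aa_seq == peptides[1].aa_seq:
        flags.add("homozygous_warning")
    return Genotype(sample_id, subspecies, (peptides[0], peptides[1]), frozenset(flags))


def funnel_report(outcomes) -> FunnelReport:
    """Tally the per-sample funnel.

    ``outcomes`` is an iterable of (assembly, genotype_or_rejection_or_None)
    pairs, one per input sample; the second element is None for samples that
    failed assembly filtering.
    """
    rep = FunnelReport()
    for assembly, call in outcomes:
        rep.n_samples_in += 1
        if call is None:
            continue
        rep.n_pass_assembly_filter += 1
        rep.n_contigs_translated += len(assembly.contigs)
        if isinstance(call, Genotype):
            rep.n_peptides_valid += 2
            rep.n_samples_both_alleles += 1
        elif call.reason == "one_allele_truncated":
            rep.n_peptides_valid += 1
    rep.n_sequences_final = 2 * rep.n_samples_both_alleles
    return rep
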