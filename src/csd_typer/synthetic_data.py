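"""Synthetic diploid cohorts for end-to-end testing of the HVR pipeline.

Emulates the data regime the pipeline targets: 150 bp Illumina-style reads
drawn from the two haplotypes of a diploid sample, each haplotype being a
back-translated HVR allele embedded in flanking sequence, with i.i.d.
substitution errors. The two alleles of a sample are constrained to differ
by at least 5 amino acids, the separation known to reliably trigger female
development at the csd locus. Every cohort comes with a truth table so any
downstream result can be scored exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from csd_typer.io_formats import Read, SampleSheet, SUBSPECIES, write_fastq
from csd_typer.phylo_lite import pairwise_distance

_CODONS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default subspecies mix, proportional to the seven-subspecies cohort the
#: packaged reference catalogue was built from (125 colonies).
DEFAULT_SUBSPECIES_WEIGHTS = {
    "ligustica": 61 / 125,
    "buckfast": 43 / 125,
    "carnica": 8 / 125,
    "sicula": 6 / 125,
    "mellifera": 4 / 125,
    "hybrid_carnica": 2 / 125,
    "cecropia": 1 / 125,
}


@dataclass
class SimConfig:
    """Knobs of the cohort simulator.

    ``depth`` is mean per-haplotype coverage (default 20x, the regime of a
    modest whole-genome resequencing run restricted to a short locus);
    ``error_rate`` is the per-base substitution probability (default 0.001,
    Illumina-like); ``flank_len`` nucleotides of random fixed-seed DNA
    stand in for exon context on each side of the allele.
    """

    n_samples: int = 50
    subspecies_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSPECIES_WEIGHTS)
    )
    allele_pool: Optional[list[str]] = None  # default: packaged 88-allele catalogue
    depth: float = 20.0
    read_len: int = 150
    error_rate: float = 0.001
    min_pair_aa_diff: int = 5
    flank_len: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subspecies_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"subspecies weights sum to {total}, expected 1")
        for s in self.subspecies_weights:
            if s not in SUBSPECIES:
                raise ValueError(f"unknown subspecies {s!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.allele_pool is None:
            from csd_typer.catalog import load_reference_catalog

            self.allele_pool = [r.aa_seq for r in load_reference_catalog().records]


@dataclass(frozen=True)
class TruthRow:
    sample_id: str
    subspecies: str
    allele_a: str
    allele_b: str
    haplotype_a: str
    haplotype_b: str


def back_translate(peptide: str, seed: int) -> str:
    """Seed-deterministic back-translation via random synonymous codons."""
    rng = np.random.default_rng(seed)
    out = []
    for aa in peptide.upper():
        codons = _CODONS.get(aa)
        if codons is None:
            raise ValueError(f"invalid amino-acid residue {aa!r}")
        out.append(codons[rng.integers(len(codons))])
    dna = "".join(out)
    assert str(Seq(dna).translate()) == peptide.upper()
    return dna


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    seq = seq.copy()
    # substitute with one of the three other bases
    shift = rng.integers(1, 4, size=len(hits))
    idx = (np.searchsorted(_BASES, seq[hits]) + shift) % 4
    seq[hits] = _BASES[idx]
    return seq


def simulate_sample(
    config: SimConfig,
    sample_id: str,
    subspecies: str,
    allele_a: str,
    allele_b: str,
    rng: np.random.Generator,
) -> tuple[list[Read], TruthRow]:
    """Simulate reads for one diploid sample.

    Each haplotype is flank + back-translated allele + flank, with flanks
    drawn independently per haplotype. Read count per haplotype is
    round(depth * haplotype_len / read_len); starts are uniform, strand
    uniform, substitutions i.i.d. at ``error_rate``.
    """
    if aa_difference(allele_a, allele_b) < config.min_pair_aa_diff:
        raise ValueError(
            f"sample {sample_id!r}: allele pair differs by fewer than "
            f"{config.min_pair_aa_diff} aa"
        )
    reads: list[Read] = []
    haplotypes = []
    for hap_name, allele in (("a", allele_a), ("b", allele_b)):
        bt_seed = int(rng.integers(2**31))
        hap = (
            _random_dna(config.flank_len, rng)
            + back_translate(allele, bt_seed)
            + _random_dna(config.flank_len, rng)
        )
        haplotypes.append(hap)
        if len(hap) < config.read_len:
            raise ValueError(
                f"haplotype length {len(hap)} shorter than read length "
                f"{config.read_len}; increase flank_len"
            )
        n_reads = round(config.depth * len(hap) / config.read_len)
        hap_arr = np.frombuffer(hap.encode(), dtype=np.uint8)
        starts = rng.integers(0, len(hap) - config.read_len + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for k, (start, minus) in enumerate(zip(starts, strands)):
            frag = hap_arr[start : start + config.read_len]
            frag = _mutate(frag, config.error_rate, rng)
            seq = frag.tobytes().decode()
            if minus:
                from csd_typer.assembler import revcomp

                seq = revcomp(seq)
            reads.append(
                Read(
                    id=f"{sample_id}_h{hap_name}_r{k:04d}",
                    seq=seq,
                    qual="I" * config.read_len,
                )
            )
    truth = TruthRow(sample_id, subspecies, allele_a, allele_b, *haplotypes)
    return reads, truth


def aa_difference(a: str, b: str) -> int:
    """Alignment-based amino-acid difference count (edit distance)."""
    if a == b:
        return 0
    import edlib

    return edlib.align(a, b, mode="NW")["editDistance"]


def generate_cohort(
    config: SimConfig,
    out_dir: Optional[str] = None,
    max_retries: int = 200,
) -> tuple[SampleSheet, dict[str, list[Read]], list[TruthRow]]:
    """Generate a full synthetic cohort, optionally writing it to disk.

    Sample allele pairs are drawn without replacement from the pool and
    redrawn until they differ by at least ``min_pair_aa_diff`` amino
    acids. With ``out_dir`` set, per-sample FASTQ files, the sample sheet
    and the truth table are written there. Fully deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pool = list(config.allele_pool)
    if len(pool) < 2:
        raise ValueError("allele pool must contain at least 2 alleles")
    subs = sorted(config.subspecies_weights)
    weights = np.array([config.subspecies_weights[s] for s in subs])
    weights = weights / weights.sum()

    rows = []
    reads_by_sample: dict[str, list[Read]] = {}
    truth: list[TruthRow] = []
    for i in range(config.n_samples):
        sample_id = f"sample{i + 1:03d}"
        subspecies = subs[rng.choice(len(subs), p=weights)]
        for attempt in range(max_retries):
            a, b = (pool[k] for k in rng.choice(len(pool), size=2, replace=False))
            if aa_difference(a, b) >= config.min_pair_aa_diff:
                break
        else:
            raise ValueError(
                f"could not draw an allele pair differing by >= "
                f"{config.min_pair_aa_diff} aa in {max_retries} tries"
            )
        reads, row = simulate_sample(config, sample_id, subspecies, a, b, rng)
        reads_by_sample[sample_id] = reads
        truth.append(row)
        path = os.path.join(out_dir, f"{sample_id}.fastq") if out_dir else f"{sample_id}.fastq"
        rows.append((sample_id, subspecies, path))
    sheet = SampleSheet(rows)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for sample_id, reads in reads_by_sample.items():
            write_fastq(reads, os.path.join(out_dir, f"{sample_id}.fastq"))
        sheet.write_tsv(os.path.join(out_dir, "sample_sheet.tsv"))
        with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
            fh.write(
                "sample_id\tsubspecies\tallele_a\tallele_b\t"
                "haplotype_a\thaplotype_b\n"
            )
            for r in truth:
                fh.write(
                    f"{r.sample_id}\t{r.subspecies}\t{r.allele_a}\t"
                    f"{r.allele_b}\t{r.haplotype_a}\t{r.haplotype_b}\n"
                )
    return sheet, reads_by_sample, truth
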