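"""Sequence/alignment I/O and HVR region extraction.

Coordinates are 1-based inclusive throughout (samtools region-string
convention); the default HVR interval on the Amel_HAv3.1 assembly,
NC_037640.1:11771976-11772119, spans 144 bp of csd exon 7.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam
from Bio import SeqIO

SUBSPECIES = (
    "ligustica",
    "buckfast",
    "sicula",
    "carnica",
    "hybrid_carnica",
    "mellifera",
    "cecropia",
)


class FormatError(ValueError):
    """Malformed input file (message carries file and line context)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_region_string(cls, region: str) -> "GenomicInterval":
        """Parse ``CHR:START-END`` (commas in numbers tolerated)."""
        try:
            chrom, span = region.rsplit(":", 1)
            lo, hi = span.replace(",", "").split("-")
            return cls(chrom, int(lo), int(hi))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"cannot parse region string {region!r}") from exc


#: csd HVR interval on chromosome 3 of Amel_HAv3.1 (144 bp of exon 7).
HVR_INTERVAL = GenomicInterval("NC_037640.1", 11771976, 11772119)


@dataclass(frozen=True)
class Read:
    """A single sequencing read.

    ``qual`` is a Sanger-offset quality string of the same length as ``seq``
    when present. ``mapped_span`` records the reference interval the read
    aligned to, when it came out of a SAM file.
    """

    id: str
    seq: str
    qual: Optional[str] = None
    mapped_span: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass
class SampleSheet:
    """Rows of (sample_id, subspecies, path); sample ids unique."""

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        for sid, sub, _path in self.rows:
            if sub not in SUBSPECIES:
                raise ValueError(
                    f"sample {sid!r}: unknown subspecies {sub!r} "
                    f"(expected one of {SUBSPECIES})"
                )

    @classmethod
    def read_tsv(cls, path: str) -> "SampleSheet":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "sample_id":  # header
                    continue
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 columns")
                rows.append((fields[0], fields[1], fields[2]))
        return cls(rows)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tsubspecies\tpath\n")
            for row in self.rows:
                fh.write("\t".join(row) + "\n")


def read_fasta(path: str) -> list[Read]:
    """Read a FASTA file; ids are headers up to the first whitespace."""
    _validate_first_char(path, ">", "FASTA")
    try:
        return [Read(id=rec.id, seq=str(rec.seq).upper())
                for rec in SeqIO.parse(path, "fasta")]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTA record: {exc}") from exc


def write_fasta(reads: Iterable[Read], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


def read_fastq(path: str) -> list[Read]:
    """Read a FASTQ file (Sanger-offset qualities)."""
    _validate_first_char(path, "@", "FASTQ")
    out = []
    try:
        for rec in SeqIO.parse(path, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            out.append(Read(id=rec.id, seq=str(rec.seq).upper(), qual=qual))
    except ValueError as exc:
        raise FormatError(
            f"{path}: malformed FASTQ near record {len(out) + 1} "
            f"(approx. line {4 * len(out) + 1}): {exc}"
        ) from exc
    return out


def write_fastq(reads: Iterable[Read], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def _validate_first_char(path: str, char: str, fmt: str) -> None:
    with open(path) as fh:
        first = fh.read(1)
    if first and first != char:
        raise FormatError(f"{path}:1: not a {fmt} file (expected {char!r})")


def extract_region_reads(
    sam_path: str,
    interval: GenomicInterval = HVR_INTERVAL,
    min_overlap_bp: int = 1,
) -> list[Read]:
    """Extract primary-alignment reads overlapping ``interval``.

    A read qualifies when its reference span overlaps the interval by at
    least ``min_overlap_bp`` bases. Secondary and supplementary alignments
    are skipped; duplicates are kept. Sequences are returned in reference
    orientation, exactly as stored in the SAM file. An unmapped-only file
    yields an empty list; a chromosome absent from the header is an error.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    out: list[Read] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        if interval.chrom not in sam.references:
            raise ValueError(
                f"chromosome {interval.chrom!r} absent from {sam_path} header"
            )
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_name != interval.chrom:
                continue
            # pysam spans are 0-based half-open; convert to 1-based inclusive
            ref_start = aln.reference_start + 1
            ref_end = aln.reference_end  # half-open end == inclusive 1-based end
            if ref_end is None:
                continue
            overlap = min(ref_end, interval.end) - max(ref_start, interval.start) + 1
            if overlap < min_overlap_bp:
                continue
            qual = None
            if aln.query_qualities is not None:
                qual = "".join(chr(q + 33) for q in aln.query_qualities)
            out.append(
                Read(
                    id=aln.query_name,
                    seq=(aln.query_sequence or "").upper(),
                    qual=qual,
                    mapped_span=GenomicInterval(interval.chrom, ref_start, ref_end),
                )
            )
    return out


def write_report_tables(catalog, genotypes, out_dir: str, funnel=None) -> dict[str, str]:
    """Materialize the cohort reports as deterministic TSV files.

    Writes ``alleles.tsv`` (one row per allele with copies, population and
    per-subspecies percentages, known matches), ``genotypes.tsv``,
    ``sharing.tsv`` and, when a funnel report is given, ``funnel.tsv``.
    Percentages are formatted to 2 decimals with half-up rounding; raw
    fractions are included so downstream consumers need not undo rounding.
    Rewriting identical inputs yields byte-identical files.
    """
    from csd_typer.catalog import sharing_classes as _sharing

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    p = os.path.join(out_dir, "alleles.tsv")
    with open(p, "w") as fh:
        cols = ["allele_id", "peptide", "length", "copies", "pop_freq_pct", "pop_freq_raw"]
        cols += [f"freq_pct_{s}" for s in SUBSPECIES]
        cols.append("known_match_ids")
        fh.write("\t".join(cols) + "\n")
        for rec in catalog.records:
            row = [
                str(rec.allele_id),
                rec.aa_seq,
                str(rec.length),
                str(rec.copies),
                _fmt_pct(rec.pop_freq_pct),
                repr(rec.copies / catalog.total_sequences),
            ]
            for s in SUBSPECIES:
                row.append(_fmt_pct(rec.subspecies_freq_pct.get(s)))
            row.append(",".join(rec.known_matches))
            fh.write("\t".join(row) + "\n")
    paths["alleles"] = p

    p = os.path.join(out_dir, "genotypes.tsv")
    with open(p, "w") as fh:
        fh.write("sample_id\tsubspecies\tallele_a\tallele_b\tflags\n")
        for g in genotypes:
            a, b = g.alleles
            fh.write(
                f"{g.sample_id}\t{g.subspecies}\t{a.aa_seq}\t{b.aa_seq}\t"
                + ",".join(sorted(g.flags))
                + "\n"
            )
    paths["genotypes"] = p

    p = os.path.join(out_dir, "sharing.tsv")
    classes = _sharing(catalog)
    with open(p, "w") as fh:
        fh.write("class\tn_alleles\tallele_ids\n")
        for name, ids in (
            ("private", classes.private),
            ("shared2", classes.shared2),
            ("shared3plus", classes.shared3plus),
        ):
            fh.write(f"{name}\t{len(ids)}\t" + ",".join(map(str, sorted(ids))) + "\n")
    paths["sharing"] = p

    if funnel is not None:
        p = os.path.join(out_dir, "funnel.tsv")
        with open(p, "w") as fh:
            fh.write("stage\tcount\n")
            for stage, count in funnel.as_rows():
                fh.write(f"{stage}\t{count}\n")
        paths["funnel"] = p
    return paths


def _fmt_pct(value) -> str:
    return "" if value is None else f"{value:.2f}"
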