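"""Six-frame translation of contigs and selection of valid HVR peptides.

An HVR allele peptide is delimited by the conserved anchors shared by every
catalogued allele: it starts with ``SSLS`` and ends with ``IEQI``. A frame
whose translation carries that motif span with no internal stop codon (and
no ambiguity character) yields the candidate allele; translations truncated
by an internal stop are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

START_ANCHOR = "SSLS"
END_ANCHOR = "IEQI"


@dataclass(frozen=True)
class HvrPeptide:
    """A validated HVR allele peptide clipped to the anchor span."""

    aa_seq: str
    frame: int  # 1..3 forward, 4..6 reverse complement
    source_contig: str = ""

    def __post_init__(self) -> None:
        validate_hvr_peptide(self.aa_seq)
        if not 1 <= self.frame <= 6:
            raise ValueError(f"frame must be 1..6, got {self.frame}")

    def __len__(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class Rejection:
    """Why a contig produced no valid HVR peptide."""

    reason: str  # no_motif | internal_stop | ambiguous_multi_frame | length_out_of_range
    detail: str = ""

    def __bool__(self) -> bool:
        return False


def validate_hvr_peptide(
    aa_seq: str,
    start_anchor: str = START_ANCHOR,
    end_anchor: str = END_ANCHOR,
    min_len: int = 20,
    max_len: int = 80,
) -> None:
    """Raise ValueError unless ``aa_seq`` satisfies the HVR allele invariants."""
    if not aa_seq.startswith(start_anchor):
        raise ValueError(f"peptide does not start with {start_anchor}: {aa_seq[:8]}...")
    if not aa_seq.endswith(end_anchor):
        raise ValueError(f"peptide does not end with {end_anchor}: ...{aa_seq[-8:]}")
    if "*" in aa_seq:
        raise ValueError("peptide contains a stop symbol")
    if "X" in aa_seq:
        raise ValueError("peptide contains an ambiguity symbol")
    if not min_len <= len(aa_seq) <= max_len:
        raise ValueError(
            f"peptide length {len(aa_seq)} outside [{min_len}, {max_len}]"
        )


def six_frame_translate(dna: str) -> list[str]:
    """Translate ``dna`` in all six frames under the standard genetic code.

    Frames 1-3 read the forward strand at offsets 0-2; frames 4-6 read the
    reverse complement likewise. Stop codons render as ``*``, codons with
    undetermined bases as ``X``; 1-2 trailing nucleotides are ignored.
    """
    if len(dna) < 3:
        raise ValueError(f"need at least one codon, got {len(dna)} nt")
    seq = Seq(dna.upper())
    frames = []
    for strand in (seq, seq.reverse_complement()):
        for off in range(3):
            sub = strand[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(sub.translate()))
    return frames


def select_hvr_peptide(
    contig,
    start_anchor: str = START_ANCHOR,
    end_anchor: str = END_ANCHOR,
    min_len: int = 20,
    max_len: int = 80,
) -> HvrPeptide | Rejection:
    """Scan all six frames of a contig for the anchored HVR peptide.

    The candidate span in a frame runs from the first ``start_anchor`` to
    the end of the last ``end_anchor``. A span containing ``*`` is a
    truncated translation; one containing ``X`` reflects consensus
    ambiguity — both are rejected rather than allowed to fabricate an
    allele. If more than one frame yields a valid peptide the call is
    ambiguous and rejected. ``contig`` may be a Contig or a plain DNA string.
    """
    dna = contig if isinstance(contig, str) else contig.consensus
    source = "" if isinstance(contig, str) else contig.id
    valid: list[HvrPeptide] = []
    saw_stop = False
    saw_bad_length = False
    for frame_no, aa in enumerate(six_frame_translate(dna), 1):
        lo = aa.find(start_anchor)
        if lo < 0:
            continue
        hi = aa.rfind(end_anchor)
        if hi < 0 or hi < lo:
            continue
        span = aa[lo : hi + len(end_anchor)]
        if "*" in span or "X" in span:
            saw_stop = True
            continue
        if not min_len <= len(span) <= max_len:
            saw_bad_length = True
            continue
        valid.append(HvrPeptide(span, frame_no, source))
    if len(valid) == 1:
        return valid[0]
    if len(valid) > 1:
        return Rejection(
            "ambiguous_multi_frame",
            f"frames {[p.frame for p in valid]} all yield valid peptides",
        )
    if saw_stop:
        return Rejection("internal_stop", "anchored span interrupted by stop/ambiguity")
    if saw_bad_length:
        return Rejection("length_out_of_range", "anchored span outside length bounds")
    return Rejection("no_motif", f"no frame contains {start_anchor}...{end_anchor}")
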