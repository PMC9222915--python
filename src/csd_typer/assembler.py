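"""Greedy overlap-layout-consensus assembly of HVR reads.

Reimplements the user-visible contract of a classical OLC clustering step:
reads (and partial contigs) are merged greedily on their best gap-free
suffix-prefix or containment overlap, subject to a minimum overlap length
(default 40 columns) and minimum overlap identity (default 90%), until no
qualifying overlap remains. Unmerged reads are reported as singletons.

Overlap search is exact: for read-scale sequences every diagonal that could
host a qualifying overlap is enumerated. At assembly scale a k-mer seeding
shortcut restricts diagonals to those sharing an exact 8-mer, which is
provably lossless here — any overlap of length L >= 40 with identity >= 0.9
has at most floor(L/10) mismatches, so its longest exact run is at least
ceil((L - floor(L/10)) / (floor(L/10) + 1)) >= 8 for all L >= 40.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from csd_typer.io_formats import Read

# base encoding: concrete bases 0..3, N = 4 (never a match)
_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

SEED_K = 8


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode()


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return _decode(_revcomp(_encode(seq)))


@dataclass(frozen=True)
class Overlap:
    """A qualifying gap-free overlap between two sequences.

    ``orientation`` is "forward" when b aligned as given, "rc" when the
    reverse complement of b aligned; ``b_start`` is an offset in the
    oriented copy of b. ``score`` = matches - mismatch_penalty * mismatches.
    """

    a_id: str
    b_id: str
    orientation: str
    a_start: int
    b_start: int
    length: int
    matches: int
    score: float

    @property
    def identity(self) -> float:
        return self.matches / self.length


@dataclass
class Contig:
    """Assembled consensus with its member layout and per-column depth."""

    id: str
    consensus: str
    members: list[tuple[str, str, int]]  # (read_id, "+"/"-", offset)
    depth: np.ndarray

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class Assembly:
    """Contigs (>= 2 members each) plus leftover singleton read ids.

    Every input read appears exactly once, either in one contig's member
    list or as one singleton.
    """

    contigs: list[Contig] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)

    def n_reads(self) -> int:
        return sum(len(c.members) for c in self.contigs) + len(self.singletons)


def _check_params(min_overlap: int, min_identity: float) -> None:
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    if not (0.0 < min_identity <= 1.0):
        raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")


def _diagonal_stats(a: np.ndarray, b: np.ndarray, d: int) -> tuple[int, int, int, int]:
    """Matches over the overlap of b placed at diagonal d (b[0] at a-coord d).

    Returns (a_start, b_start, length, matches). N columns never match.
    """
    a_start = max(0, d)
    a_end = min(len(a), d + len(b))
    length = a_end - a_start
    b_start = a_start - d
    asl = a[a_start:a_end]
    bsl = b[b_start : b_start + length]
    matches = int(np.count_nonzero((asl == bsl) & (asl != 4)))
    return a_start, b_start, length, matches


def _kmer_positions(arr: np.ndarray, k: int = SEED_K) -> dict[int, list[int]]:
    """Positions of each exact (N-free) k-mer, packed as a base-4 integer."""
    if len(arr) < k:
        return {}
    x = arr.astype(np.int64)
    valid = x != 4
    # rolling pack; invalidate windows containing N
    packed = np.zeros(len(arr) - k + 1, dtype=np.int64)
    ok = np.ones(len(arr) - k + 1, dtype=bool)
    for j in range(k):
        packed = packed * 4 + np.where(valid[j : j + len(packed)], x[j : j + len(packed)], 0)
        ok &= valid[j : j + len(packed)]
    out: dict[int, list[int]] = {}
    for pos in np.nonzero(ok)[0]:
        out.setdefault(int(packed[pos]), []).append(int(pos))
    return out


def _candidate_diagonals(
    a_kmers: dict[int, list[int]], b_kmers: dict[int, list[int]]
) -> set[int]:
    diags: set[int] = set()
    small, large = (a_kmers, b_kmers) if len(a_kmers) <= len(b_kmers) else (b_kmers, a_kmers)
    swap = small is b_kmers
    for kmer, positions in small.items():
        other = large.get(kmer)
        if other is None:
            continue
        for p in positions:
            for q in other:
                diags.add(q - p if swap else p - q)
    return diags


def _best_oriented_overlap(
    a: np.ndarray,
    b: np.ndarray,
    diagonals,
    min_overlap: int,
    min_identity: float,
    mismatch_penalty: float,
) -> Optional[tuple[float, int, int, int, int, int]]:
    """Best (score, length, a_start, b_start, matches, diag) among diagonals."""
    best = None
    for d in sorted(diagonals):
        if d < -(len(b) - min_overlap) or d > len(a) - min_overlap:
            continue
        a_start, b_start, length, matches = _diagonal_stats(a, b, d)
        if length < min_overlap or matches / length < min_identity:
            continue
        score = matches - mismatch_penalty * (length - matches)
        cand = (score, length, a_start, b_start, matches, d)
        if best is None or (cand[0], cand[1], -cand[5]) > (best[0], best[1], -best[5]):
            best = cand
    return best


def find_best_overlap(
    a: str,
    b: str,
    min_overlap: int = 40,
    min_identity: float = 0.90,
    mismatch_penalty: float = 2.0,
    a_id: str = "a",
    b_id: str = "b",
) -> Optional[Overlap]:
    """Best qualifying gap-free overlap between a and b, both orientations.

    Exhaustively scores every diagonal admitting >= min_overlap columns, in
    b's forward orientation and reverse complement, keeping alignments with
    identity >= min_identity. Score ties break toward the longer overlap,
    then the forward orientation. Returns None when nothing qualifies.
    """
    _check_params(min_overlap, min_identity)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = _encode(a), _encode(b)
    results = []
    for orient, eb_o in (("forward", eb), ("rc", _revcomp(eb))):
        diagonals = range(-(len(eb_o) - min_overlap), len(ea) - min_overlap + 1)
        best = _best_oriented_overlap(
            ea, eb_o, diagonals, min_overlap, min_identity, mismatch_penalty
        )
        if best is not None:
            results.append((orient, best))
    if not results:
        return None
    # ties: longer length, then forward orientation
    results.sort(key=lambda r: (-r[1][0], -r[1][1], r[0] != "forward"))
    orient, (score, length, a_start, b_start, matches, _d) = results[0]
    return Overlap(a_id, b_id, orient, a_start, b_start, length, matches, score)


def consensus(
    members: list[tuple[str, str, int]],
    reads: dict[str, str],
    quals: Optional[dict[str, str]] = None,
) -> str:
    """Per-column majority consensus over a gap-free layout of reads.

    ``members`` holds (read_id, "+"/"-", offset) placements; ``reads`` maps
    read id to its as-input sequence. Ties go to the higher summed quality
    when qualities are given, else alphabetically among the tied bases; N
    never beats a concrete base.
    """
    enc_reads = {rid: _encode(seq) for rid, seq in reads.items()}
    enc_quals = None
    if quals:
        enc_quals = {
            rid: np.frombuffer(q.encode(), dtype=np.uint8).astype(np.float64) - 33.0
            for rid, q in quals.items()
        }
    cons, _depth, _members = _consensus_from_layout(members, enc_reads, enc_quals)
    return _decode(cons)


class _Unit:
    """A live assembly unit: one read or a partial contig."""

    __slots__ = ("label", "consensus", "consensus_rc", "members", "kmers",
                 "kmers_rc", "alive", "reads")

    def __init__(self, label, consensus, members, reads):
        self.label = label  # lexicographically smallest member read id
        self.consensus = consensus  # np.uint8 array
        self.consensus_rc = _revcomp(consensus)
        self.members = members  # [(read_id, strand, offset)]
        self.reads = reads  # read_id -> oriented-as-input np array
        self.kmers = _kmer_positions(consensus)
        self.kmers_rc = _kmer_positions(self.consensus_rc)
        self.alive = True


def _consensus_from_layout(
    members: list[tuple[str, str, int]],
    reads: dict[str, np.ndarray],
    quals: Optional[dict[str, np.ndarray]] = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str, int]]]:
    """Per-column majority consensus over a gap-free layout.

    Ties break by higher summed quality when qualities are available, else
    alphabetically among tied concrete bases; N never wins against a
    concrete base. Offsets are renormalized so the leftmost member is 0.
    Returns (consensus, depth, shifted_members).
    """
    if not members:
        raise ValueError("empty layout")
    lo = min(off for _, _, off in members)
    members = [(rid, strand, off - lo) for rid, strand, off in members]
    length = max(off + len(reads[rid]) for rid, _, off in members)
    counts = np.zeros((5, length), dtype=np.int32)
    qsum = np.zeros((5, length), dtype=np.float64)
    for rid, strand, off in members:
        arr = reads[rid] if strand == "+" else _revcomp(reads[rid])
        idx = np.arange(off, off + len(arr))
        np.add.at(counts, (arr, idx), 1)
        if quals is not None and rid in quals:
            q = quals[rid] if strand == "+" else quals[rid][::-1]
            np.add.at(qsum, (arr, idx), q)
        else:
            np.add.at(qsum, (arr, idx), 0.0)
    concrete = counts[:4]
    # majority among concrete bases; alphabetical tie-break via argmax order;
    # quality tie-break applied before alphabetical
    best_count = concrete.max(axis=0)
    # rank: (count, qsum, -base_index) maximized -> lexicographic argmax trick
    rank = concrete.astype(np.float64) * 1e12 + qsum[:4] * 1e3
    cons = np.argmax(rank, axis=0).astype(np.uint8)
    cons[best_count == 0] = 4  # all-N columns
    depth = counts.sum(axis=0)
    return cons, depth, members


def _merge_units(ua: _Unit, ub: _Unit, orient: str, diag: int, quals) -> _Unit:
    members = list(ua.members)
    b_members = ub.members
    if orient == "rc":
        blen = len(ub.consensus)
        b_members = [
            (rid, "-" if strand == "+" else "+", blen - (off + len(ub.reads[rid])))
            for rid, strand, off in b_members
        ]
    members += [(rid, strand, off + diag) for rid, strand, off in b_members]
    reads = {**ua.reads, **ub.reads}
    cons, depth, members = _consensus_from_layout(members, reads, quals)
    label = min(ua.label, ub.label)
    unit = _Unit(label, cons, members, reads)
    return unit


def _pair_best(
    ua: _Unit,
    ub: _Unit,
    min_overlap: int,
    min_identity: float,
    mismatch_penalty: float,
    exhaustive: bool,
) -> Optional[tuple[float, int, str, int]]:
    """Best (score, length, orient, diag) between two unit consensuses."""
    ea, eb = ua.consensus, ub.consensus
    results = []
    for orient, eb_o, km in (
        ("forward", eb, ub.kmers),
        ("rc", ub.consensus_rc, ub.kmers_rc),
    ):
        if exhaustive:
            diagonals = range(-(len(eb_o) - min_overlap), len(ea) - min_overlap + 1)
        else:
            diagonals = _candidate_diagonals(ua.kmers, km)
        best = _best_oriented_overlap(
            ea, eb_o, diagonals, min_overlap, min_identity, mismatch_penalty
        )
        if best is not None:
            results.append((orient, best))
    if not results:
        return None
    results.sort(key=lambda r: (-r[1][0], -r[1][1], r[0] != "forward"))
    orient, (score, length, _a0, _b0, _m, d) = results[0]
    return score, length, orient, d


def assemble(
    reads: Sequence[Read],
    min_overlap: int = 40,
    min_identity: float = 0.90,
    mismatch_penalty: float = 2.0,
    min_contig_depth: int = 0,
    exhaustive: bool = False,
) -> Assembly:
    """Greedy OLC assembly of a sample's reads into contigs and singletons.

    Repeatedly merges the highest-scoring qualifying overlap among current
    units (reads or partial contigs), rebuilding the merged consensus from
    the full read layout, until no qualifying overlap remains. Determinism:
    score ties break by longer overlap, forward orientation, then the
    lexicographically smaller pair of unit labels.

    ``min_contig_depth`` > 0 additionally demotes contigs whose minimum
    per-column depth falls below the cutoff (an automatable stand-in for
    manual inspection of poorly supported assemblies); default off.
    ``exhaustive=True`` disables k-mer seeding and scans every diagonal
    (identical results, only slower; useful for oracle comparisons).
    """
    _check_params(min_overlap, min_identity)
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate read ids: {dupes}")
    if not reads:
        return Assembly([], [])

    quals = {
        r.id: np.frombuffer(r.qual.encode(), dtype=np.uint8).astype(np.float64) - 33.0
        for r in reads
        if r.qual is not None
    } or None
    units: list[_Unit] = []
    for r in reads:
        arr = _encode(r.seq)
        units.append(_Unit(r.id, arr, [(r.id, "+", 0)], {r.id: arr}))

    heap: list[tuple] = []

    def push_pairs(i: int, js) -> None:
        for j in js:
            if i == j or not units[j].alive:
                continue
            a, b = (i, j) if units[i].label <= units[j].label else (j, i)
            best = _pair_best(
                units[a], units[b], min_overlap, min_identity,
                mismatch_penalty, exhaustive,
            )
            if best is not None:
                score, length, orient, d = best
                heapq.heappush(
                    heap,
                    (-score, -length, orient != "forward",
                     units[a].label, units[b].label, a, b, orient, d),
                )

    for i in range(len(units)):
        push_pairs(i, range(i + 1, len(units)))

    while heap:
        _ns, _nl, _rc, la, lb, a, b, orient, d = heapq.heappop(heap)
        if not (units[a].alive and units[b].alive):
            continue
        if units[a].label != la or units[b].label != lb:
            continue  # stale entry from before a merge
        units[a].alive = False
        units[b].alive = False
        merged = _merge_units(units[a], units[b], orient, d, quals)
        units.append(merged)
        push_pairs(len(units) - 1, [k for k in range(len(units) - 1) if units[k].alive])

    contigs: list[Contig] = []
    singletons: list[str] = []
    final = [u for u in units if u.alive]
    final.sort(key=lambda u: (-len(u.members), u.label))
    for u in final:
        if len(u.members) == 1:
            singletons.append(u.members[0][0])
            continue
        cons, depth, members = _consensus_from_layout(u.members, u.reads, quals)
        contig = Contig(
            id="", consensus=_decode(cons), members=members, depth=depth
        )
        if min_contig_depth > 0 and int(depth.min()) < min_contig_depth:
            singletons.extend(m[0] for m in members)
        else:
            contigs.append(contig)
    for k, c in enumerate(contigs, 1):
        c.id = f"contig{k}"
    singletons.sort()
    return Assembly(contigs, singletons)


def write_layout(assembly: Assembly, path: str) -> None:
    """Dump a plain-text layout of each contig (debugging aid)."""
    with open(path, "w") as fh:
        for c in assembly.contigs:
            fh.write(f"CO {c.id} len={len(c.consensus)} members={len(c.members)}\n")
            fh.write(c.consensus + "\n")
            for rid, strand, off in sorted(c.members, key=lambda m: m[2]):
                fh.write(f"  {rid} {strand} @{off}\n")
        for s in assembly.singletons:
            fh.write(f"SG {s}\n")
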