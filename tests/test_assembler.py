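import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csd_typer.assembler import (
    Assembly,
    Overlap,
    assemble,
    consensus,
    find_best_overlap,
    revcomp,
)
from csd_typer.io_formats import Read
from conftest import tiling_reads


def brute_force_best_overlap(a, b, min_overlap=40, min_identity=0.90,
                             mismatch_penalty=2.0):
    """Independent oracle: score every offset in both orientations directly."""
    best = None
    for orient, bo in (("forward", b), ("rc", revcomp(b))):
        for d in range(-(len(bo) - min_overlap), len(a) - min_overlap + 1):
            a0, a1 = max(0, d), min(len(a), d + len(bo))
            length = a1 - a0
            if length < min_overlap:
                continue
            matches = sum(
                1
                for i in range(a0, a1)
                if a[i] == bo[i - d] and a[i] in "ACGT"
            )
            if matches / length < min_identity:
                continue
            score = matches - mismatch_penalty * (length - matches)
            key = (score, length, orient == "forward")
            if best is None or key > best[0]:
                best = (key, orient, d, length, matches)
    return best


def random_dna(n, rng):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


class TestFindBestOverlap:
    def test_identical_sequences_full_containment(self):
        rng = np.random.default_rng(0)
        s = random_dna(60, rng)
        ov = find_best_overlap(s, s)
        assert (ov.length, ov.matches, ov.identity) == (60, 60, 1.0)
        assert ov.orientation == "forward"

    def test_45_base_dovetail_with_2_mismatches_retained(self):
        rng = np.random.default_rng(1)
        shared = list(random_dna(45, rng))
        a = random_dna(15, rng) + "".join(shared)
        b_shared = shared.copy()
        for pos in (10, 30):  # two substitutions inside the dovetail
            b_shared[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b_shared[pos]]
        b = "".join(b_shared) + random_dna(15, rng)
        ov = find_best_overlap(a, b)
        assert ov is not None
        assert ov.length == 45 and ov.matches == 43
        assert ov.identity == pytest.approx(43 / 45)
        oracle = brute_force_best_overlap(a, b)
        assert (ov.score, ov.length) == (oracle[0][0], oracle[3])

    def test_39_base_exact_dovetail_below_threshold(self):
        rng = np.random.default_rng(2)
        shared = random_dna(39, rng)
        a = random_dna(21, rng) + shared
        b = shared + random_dna(21, rng)
        # guard against an accidental longer overlap elsewhere
        assert brute_force_best_overlap(a, b) is None
        assert find_best_overlap(a, b) is None

    def test_reverse_complement_overlap_found(self):
        rng = np.random.default_rng(3)
        s = random_dna(60, rng)
        ov = find_best_overlap(s, revcomp(s))
        assert ov.orientation == "rc" and ov.length == 60

    @pytest.mark.parametrize("kwargs", [
        {"min_overlap": 0}, {"min_identity": 0.0}, {"min_identity": 1.2},
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            find_best_overlap("ACGT" * 20, "ACGT" * 20, **kwargs)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            base = random_dna(100, rng)
            cut = int(rng.integers(20, 80))
            a = base[: cut + 45]
            b = base[cut:]
            if rng.random() < 0.5:
                b = revcomp(b)
            got = find_best_overlap(a, b)
            want = brute_force_best_overlap(a, b)
            if want is None:
                assert got is None
            else:
                assert (got.score, got.length, got.orientation) == (
                    want[0][0], want[3], want[1],
                )


class TestConsensus:
    def test_majority_column(self):
        members = [("r1", "+", 0), ("r2", "+", 0), ("r3", "+", 0)]
        reads = {"r1": "A", "r2": "A", "r3": "G"}
        assert consensus(members, reads) == "A"

    def test_tie_breaks_alphabetically_without_qualities(self):
        members = [("r1", "+", 0), ("r2", "+", 0)]
        assert consensus(members, {"r1": "A", "r2": "G"}) == "A"

    def test_tie_breaks_by_quality_when_available(self):
        members = [("r1", "+", 0), ("r2", "+", 0)]
        reads = {"r1": "A", "r2": "G"}
        quals = {"r1": "#", "r2": "I"}  # G has much higher quality
        assert consensus(members, reads, quals) == "G"

    def test_n_never_wins_against_concrete_base(self):
        members = [("r1", "+", 0), ("r2", "+", 0), ("r3", "+", 0)]
        assert consensus(members, {"r1": "N", "r2": "N", "r3": "T"}) == "T"

    def test_error_free_layout_reproduces_haplotype(self):
        rng = np.random.default_rng(5)
        hap = random_dna(400, rng)
        reads = tiling_reads(hap, read_len=100, step=10)
        members = []
        seqs = {}
        for i, r in enumerate(reads):
            off = hap.find(r.seq)
            members.append((r.id, "+", off))
            seqs[r.id] = r.seq
        assert consensus(members, seqs) == hap

    def test_empty_layout_is_error(self):
        with pytest.raises(ValueError):
            consensus([], {})


class TestAssemble:
    def test_empty_input(self):
        asm = assemble([])
        assert asm.contigs == [] and asm.singletons == []

    def test_single_read_is_singleton(self):
        asm = assemble([Read("only", "ACGT" * 40)])
        assert asm.contigs == [] and asm.singletons == ["only"]

    def test_duplicate_ids_rejected(self):
        r = Read("dup", "ACGT" * 40)
        with pytest.raises(ValueError, match="duplicate"):
            assemble([r, r])

    def test_two_haplotypes_recovered_exactly_from_tiling_reads(
        self, reference_peptides
    ):
        from conftest import embedded_allele_dna

        hap_a = embedded_allele_dna(reference_peptides[0], seed=10)
        hap_b = embedded_allele_dna(reference_peptides[30], seed=11)
        reads = tiling_reads(hap_a, step=15, prefix="a") + tiling_reads(
            hap_b, step=15, prefix="b"
        )
        asm = assemble(reads)
        assert len(asm.contigs) == 2 and asm.singletons == []
        assert sorted(c.consensus for c in asm.contigs) == sorted([hap_a, hap_b])

    def test_read_conservation_and_determinism(self, small_cohort):
        _sheet, reads_by_sample, _truth = small_cohort
        sample = sorted(reads_by_sample)[0]
        reads = reads_by_sample[sample]
        asm1 = assemble(reads)
        asm2 = assemble(reads)
        assert asm1.n_reads() == len(reads)
        assert [c.consensus for c in asm1.contigs] == [
            c.consensus for c in asm2.contigs
        ]
        assert asm1.singletons == asm2.singletons
        ids = [m[0] for c in asm1.contigs for m in c.members] + asm1.singletons
        assert sorted(ids) == sorted(r.id for r in reads)

    def test_seeded_search_equals_exhaustive(self):
        rng = np.random.default_rng(6)
        hap = random_dna(320, rng)
        reads = tiling_reads(hap, read_len=80, step=20)
        fast = assemble(reads)
        slow = assemble(reads, exhaustive=True)
        assert [c.consensus for c in fast.contigs] == [
            c.consensus for c in slow.contigs
        ]
        assert fast.singletons == slow.singletons

    def test_separation_of_divergent_haplotypes(self):
        # >= 5 substitutions inside every 40-base window: any cross-haplotype
        # overlap of qualifying length falls below 90% identity
        rng = np.random.default_rng(7)
        hap_a = random_dna(300, rng)
        hb = list(hap_a)
        for pos in range(3, 300, 7):
            hb[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[hb[pos]]
        hap_b = "".join(hb)
        reads = tiling_reads(hap_a, read_len=100, step=10, prefix="a") + \
            tiling_reads(hap_b, read_len=100, step=10, prefix="b")
        asm = assemble(reads)
        assert len(asm.contigs) == 2 and not asm.singletons
        consensuses = {c.consensus for c in asm.contigs}
        assert hap_a in consensuses and hap_b in consensuses

    def test_junctions_validated_by_exhaustive_enumeration(self):
        # on tiny instances every merged junction must satisfy the thresholds
        rng = np.random.default_rng(8)
        hap = random_dna(200, rng)
        reads = tiling_reads(hap, read_len=80, step=25)[:8]
        asm = assemble(reads)
        for contig in asm.contigs:
            placed = sorted(contig.members, key=lambda m: m[2])
            seqs = {r.id: r.seq for r in reads}
            for (id1, s1, o1), (id2, s2, o2) in zip(placed, placed[1:]):
                a = seqs[id1] if s1 == "+" else revcomp(seqs[id1])
                b = seqs[id2] if s2 == "+" else revcomp(seqs[id2])
                ov = brute_force_best_overlap(a, b)
                assert ov is not None  # adjacent members overlap validly

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.lists(
        st.text(alphabet="ACGT", min_size=45, max_size=90),
        min_size=0, max_size=6, unique=True,
    ))
    def test_read_conservation_property(self, seqs):
        reads = [Read(f"r{i}", s) for i, s in enumerate(seqs)]
        asm = assemble(reads)
        assert asm.n_reads() == len(reads)
        ids = [m[0] for c in asm.contigs for m in c.members] + asm.singletons
        assert sorted(ids) == sorted(r.id for r in reads)
        for c in asm.contigs:
            assert len(c.members) >= 2
            assert (c.depth >= 1).all()
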