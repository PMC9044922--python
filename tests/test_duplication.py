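from functools import lru_cache

import pytest
from Bio.Align import substitution_matrices

from gfam.core_io import GeneLocus, ProteinRecord
from gfam.duplication_analysis import (
    call_segmental,
    call_tandem,
    find_duplications,
    global_align,
    identity_similarity,
    score_all_pairs,
)
from gfam.synthetic_data import generate_loci_with_duplicates

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_best_score(a, b, gap_open=10.0, gap_extend=0.5):
    """Exhaustive global alignment oracle for short strings (affine gaps:
    a length-k gap costs open + (k-1) * extend)."""

    @lru_cache(maxsize=None)
    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = -float("inf")
        if i < len(a) and j < len(b):
            best = max(best, BLOSUM62[a[i]][b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "D" else gap_open
            best = max(best, -cost + rec(i + 1, j, "D"))
        if j < len(b):
            cost = gap_extend if prev == "I" else gap_open
            best = max(best, -cost + rec(i, j + 1, "I"))
        return best

    return rec(0, 0, "start")


def record(pid, seq):
    return ProteinRecord(pid, seq)


def locus(gid, chrom, start, end):
    return GeneLocus(gid, chrom, start, end, "+", ((start, end),))


class TestGlobalAlign:
    def test_identity_alignment_has_no_gaps(self):
        pair = global_align(record("a", "MKV"), record("b", "MKV"))
        assert pair.aligned_a == pair.aligned_b == "MKV"

    @pytest.mark.parametrize(
        "a,b",
        [("MKV", "MV"), ("MKVW", "MW"), ("ACDEF", "ACEF"), ("MK", "MKVWA")],
    )
    def test_score_matches_exhaustive_enumeration(self, a, b):
        pair = global_align(record("a", a), record("b", b))
        assert pair.score == pytest.approx(brute_force_best_score(a, b))

    def test_score_symmetry(self):
        ab = global_align(record("a", "MKVWACD"), record("b", "MKWACDE"))
        ba = global_align(record("b", "MKWACDE"), record("a", "MKVWACD"))
        assert ab.score == ba.score

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("a", "")


class TestIdentitySimilarity:
    def test_identical_sequences_score_100(self):
        score = identity_similarity(global_align(record("a", "MKVWACD"), record("b", "MKVWACD")))
        assert score.identity_pct == score.similarity_pct == score.coverage_pct == 100.0

    def test_hand_counted_mismatch(self):
        # A<->G scores 0 in BLOSUM62: not similar
        score = identity_similarity(global_align(record("a", "AAAA"), record("b", "AAAG")))
        assert score.identity_pct == pytest.approx(75.0)
        assert score.similarity_pct == pytest.approx(75.0)

    def test_normalization_by_longer_length(self):
        score = identity_similarity(global_align(record("a", "AAAA"), record("b", "AA")))
        assert score.identity_pct == pytest.approx(50.0)

    def test_similarity_counts_positive_blosum_pairs(self):
        # K<->R scores +2: similar but not identical
        score = identity_similarity(global_align(record("a", "MKVW"), record("b", "MRVW")))
        assert score.identity_pct == pytest.approx(75.0)
        assert score.similarity_pct == pytest.approx(100.0)

    def test_identity_bounded_by_similarity(self, random_protein):
        a, b = random_protein(80, "a"), random_protein(80, "b")
        score = identity_similarity(global_align(a, b))
        assert 0 <= score.identity_pct <= score.similarity_pct <= 100


class TestCallSegmental:
    @staticmethod
    def score(identity, coverage):
        from gfam.duplication_analysis import PairScore

        return PairScore("a", "b", identity, identity, coverage)

    @pytest.mark.parametrize(
        "identity,coverage,called",
        [
            (99.18, 100.0, True),
            (85.0, 100.0, False),
            (95.0, 80.0, False),
            (90.0, 100.0, False),  # strict inequality at the 90% gate
            (90.01, 90.01, True),
        ],
    )
    def test_threshold_gates(self, identity, coverage, called):
        result = call_segmental([self.score(identity, coverage)])
        assert bool(result) is called


class TestCallTandem:
    def setup_method(self):
        from gfam.duplication_analysis import DuplicationPair

        self.pair = DuplicationPair("a", "b", 99.0, 99.5, 100.0, "SEGMENTAL")

    def test_close_pair_on_one_chromosome_is_tandem(self):
        loci = {"a": locus("a", "5B", 0, 1000), "b": locus("b", "5B", 3510, 4510)}
        (called,) = call_tandem([self.pair], loci)
        assert called.call == "TANDEM"
        assert called.distance_bp == 2510

    def test_different_chromosomes_stay_segmental(self):
        loci = {"a": locus("a", "5D", 0, 1000), "b": locus("b", "5B", 2000, 3000)}
        (called,) = call_tandem([self.pair], loci)
        assert called.call == "SEGMENTAL"

    def test_distance_gate_at_100kb(self):
        loci = {"a": locus("a", "5B", 0, 1000), "b": locus("b", "5B", 151_000, 152_000)}
        (called,) = call_tandem([self.pair], loci)
        assert called.call == "SEGMENTAL"

    def test_intervening_family_gene_blocks_tandem(self):
        loci = {
            "a": locus("a", "5B", 0, 1000),
            "b": locus("b", "5B", 50_000, 51_000),
            "c": locus("c", "5B", 20_000, 21_000),
        }
        (called,) = call_tandem([self.pair], loci)
        assert called.call == "SEGMENTAL"

    def test_missing_locus_warns_and_stays_segmental(self, caplog):
        with caplog.at_level("WARNING", logger="gfam"):
            (called,) = call_tandem([self.pair], {"a": locus("a", "5B", 0, 1000)})
        assert called.call == "SEGMENTAL"
        assert "locus missing" in caplog.text


class TestPlantedRecovery:
    def test_low_mutation_pairs_called_high_not(self):
        proteins, loci, truth = generate_loci_with_duplicates(
            n_genes=6, n_segmental=3, n_tandem=1, mutation_rate=0.05, seed=7
        )
        pairs = find_duplications(proteins, {l.gene_id: l for l in loci})
        called = {(p.id_a, p.id_b): p.call for p in pairs}
        expected = {(t["id_a"], t["id_b"]): t["call"] for t in truth.pairs}
        assert called == expected

        proteins15, loci15, _ = generate_loci_with_duplicates(
            n_genes=4, n_segmental=2, n_tandem=0, mutation_rate=0.15, seed=8
        )
        assert find_duplications(proteins15, {l.gene_id: l for l in loci15}) == []

    def test_mutation_identity_matches_hamming_on_gapfree_pairs(self):
        proteins, _, truth = generate_loci_with_duplicates(
            n_genes=2, n_segmental=2, n_tandem=0, mutation_rate=0.05, seed=9
        )
        by_id = {p.id: p for p in proteins}
        for t in truth.pairs:
            a, b = by_id[t["id_a"]], by_id[t["id_b"]]
            pair = global_align(a, b)
            if "-" in pair.aligned_a or "-" in pair.aligned_b:
                continue
            hamming = sum(x != y for x, y in zip(a.sequence, b.sequence))
            score = identity_similarity(pair)
            assert score.identity_pct == pytest.approx(
                100.0 * (1 - hamming / len(a.sequence))
            )

    def test_tandem_is_subset_of_segmental_criteria(self):
        proteins, loci, _ = generate_loci_with_duplicates(
            n_genes=5, n_segmental=3, n_tandem=2, mutation_rate=0.03, seed=10
        )
        scores = score_all_pairs(proteins)
        segmental_keys = {
            frozenset((p.id_a, p.id_b)) for p in call_segmental(scores)
        }
        tandem = [
            p
            for p in call_tandem(call_segmental(scores), {l.gene_id: l for l in loci})
            if p.call == "TANDEM"
        ]
        assert tandem  # planted tandem pairs exist
        for p in tandem:
            assert frozenset((p.id_a, p.id_b)) in segmental_keys
            assert p.distance_bp is not None and p.distance_bp <= 100_000


class TestMatrixProperties:
    def test_symmetry_and_self_identity(self, random_protein):
        a, b = random_protein(60, "a"), random_protein(60, "b")
        self_score = identity_similarity(global_align(a, a))
        assert self_score.identity_pct == 100.0
        ab = identity_similarity(global_align(a, b))
        ba = identity_similarity(global_align(b, a))
        assert ab.identity_pct == pytest.approx(ba.identity_pct)
        assert ab.similarity_pct == pytest.approx(ba.similarity_pct)
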