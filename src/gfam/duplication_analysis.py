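"""Pairwise identity/similarity and segmental/tandem duplication calling.

Scores follow the SIAS-style convention: identity, similarity (BLOSUM62
score > 0, identities included) and alignment coverage are all expressed
as percentages of the *longer* sequence's length.  A pair is a segmental
duplicate when the alignment covers more than 90% of the longer gene at
more than 90% identity; segmental duplicates on one chromosome, adjacent
within 100 kb with no family member between them, are tandem duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import GeneLocus, ProteinRecord

logger = logging.getLogger("gfam")

TANDEM_MAX_DISTANCE_BP = 100_000


@dataclass(frozen=True)
class AlignedPair:
    id_a: str
    id_b: str
    aligned_a: str  # gapped strings of equal length
    aligned_b: str
    score: float


@dataclass(frozen=True)
class PairScore:
    id_a: str
    id_b: str
    identity_pct: float
    similarity_pct: float
    coverage_pct: float


@dataclass(frozen=True)
class DuplicationPair:
    id_a: str
    id_b: str
    identity_pct: float
    similarity_pct: float
    coverage_pct: float
    call: str  # SEGMENTAL | TANDEM
    distance_bp: int | None = None


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    seq_a: ProteinRecord,
    seq_b: ProteinRecord,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignedPair:
    """Needleman–Wunsch global alignment with affine gaps (BLOSUM62).

    The first optimal traceback is taken, which is deterministic for a
    given input pair.
    """
    if not seq_a.sequence or not seq_b.sequence:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(seq_a.sequence, seq_b.sequence)[0]
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])
    return AlignedPair(
        id_a=seq_a.id,
        id_b=seq_b.id,
        aligned_a=gapped_a,
        aligned_b=gapped_b,
        score=float(alignment.score),
    )


def identity_similarity(pair: AlignedPair) -> PairScore:
    """Identity / similarity / coverage as % of the longer sequence.

    Similar positions are aligned residue pairs with BLOSUM62 score > 0
    (identities included).  Coverage is the aligned span of the alignment
    excluding terminal gaps.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    a, b = pair.aligned_a, pair.aligned_b
    longer = max(len(a.replace("-", "")), len(b.replace("-", "")))
    identical = similar = 0
    for ra, rb in zip(a, b):
        if ra == "-" or rb == "-":
            continue
        if ra == rb:
            identical += 1
            similar += 1
        elif blosum[ra][rb] > 0:
            similar += 1
    # residues of the longer sequence between the first and last column
    # where both sequences are aligned (terminal gaps excluded)
    longer_gapped = a if len(a.replace("-", "")) >= len(b.replace("-", "")) else b
    both = [i for i, (ra, rb) in enumerate(zip(a, b)) if ra != "-" and rb != "-"]
    if both:
        covered = sum(
            1 for i in range(both[0], both[-1] + 1) if longer_gapped[i] != "-"
        )
    else:
        covered = 0
    return PairScore(
        id_a=pair.id_a,
        id_b=pair.id_b,
        identity_pct=100.0 * identical / longer,
        similarity_pct=100.0 * similar / longer,
        coverage_pct=100.0 * covered / longer,
    )


def score_all_pairs(
    proteins: Sequence[ProteinRecord],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> list[PairScore]:
    """Identity/similarity matrix over all unordered pairs."""
    scores = [
        identity_similarity(global_align(a, b, gap_open, gap_extend))
        for a, b in combinations(proteins, 2)
    ]
    logger.info("score_all_pairs: %d proteins, %d pairs", len(proteins), len(scores))
    return scores


def call_segmental(
    pair_scores: Sequence[PairScore],
    min_coverage: float = 90.0,
    min_identity: float = 90.0,
) -> list[DuplicationPair]:
    """Pairs with coverage > min_coverage and identity > min_identity (strict)."""
    called = [
        DuplicationPair(
            id_a=s.id_a,
            id_b=s.id_b,
            identity_pct=s.identity_pct,
            similarity_pct=s.similarity_pct,
            coverage_pct=s.coverage_pct,
            call="SEGMENTAL",
        )
        for s in pair_scores
        if s.coverage_pct > min_coverage and s.identity_pct > min_identity
    ]
    logger.info("call_segmental: %d/%d pairs called", len(called), len(pair_scores))
    return called


def _gap_between(a: GeneLocus, b: GeneLocus) -> int:
    """bp between the nearer ends of two loci (0 when they touch/overlap)."""
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end)


def call_tandem(
    segmental_pairs: Sequence[DuplicationPair],
    loci: Mapping[str, GeneLocus],
) -> list[DuplicationPair]:
    """Upgrade co-located adjacent segmental pairs to TANDEM.

    A pair is tandem when both members sit on the same chromosome, the gap
    between their nearer ends is at most 100 kb, and no other gene from
    ``loci`` lies between them (the pair is adjacent within the family).
    Pairs with a missing locus stay SEGMENTAL with a warning.
    """
    out: list[DuplicationPair] = []
    for pair in segmental_pairs:
        locus_a, locus_b = loci.get(pair.id_a), loci.get(pair.id_b)
        if locus_a is None or locus_b is None:
            logger.warning(
                "tandem check skipped for (%s, %s): locus missing", pair.id_a, pair.id_b
            )
            out.append(pair)
            continue
        if locus_a.chromosome != locus_b.chromosome:
            out.append(pair)
            continue
        gap = _gap_between(locus_a, locus_b)
        if gap > TANDEM_MAX_DISTANCE_BP:
            out.append(pair)
            continue
        lo = min(locus_a.end, locus_b.end)
        hi = max(locus_a.start, locus_b.start)
        intervening = any(
            other.chromosome == locus_a.chromosome and other.start >= lo and other.end <= hi
            for gid, other in loci.items()
            if gid not in (pair.id_a, pair.id_b)
        )
        if intervening:
            out.append(pair)
            continue
        out.append(replace(pair, call="TANDEM", distance_bp=gap))
    n_tandem = sum(1 for p in out if p.call == "TANDEM")
    logger.info("call_tandem: %d/%d segmental pairs are tandem", n_tandem, len(out))
    return out


def find_duplications(
    proteins: Sequence[ProteinRecord],
    loci: Mapping[str, GeneLocus] | None = None,
    min_coverage: float = 90.0,
    min_identity: float = 90.0,
) -> list[DuplicationPair]:
    """Full pipeline: all-vs-all scores -> segmental calls -> tandem refinement."""
    scores = score_all_pairs(proteins)
    segmental = call_segmental(scores, min_coverage, min_identity)
    if loci is None:
        return segmental
    return call_tandem(segmental, loci)
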