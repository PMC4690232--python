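"""Deterministic pairwise-alignment kernels.

Three primitives back the rest of the pipeline: affine-gap global and local
alignment (Needleman-Wunsch / Smith-Waterman semantics), and an
align-gap-excise realignment that splits two windows into best-aligning 5'
prefixes and 3' suffixes, excising the middle of each as the variant
alleles.  The excise step implements the split-maximization core of the AGE
family of breakpoint refiners, not the full five-matrix formulation.

Similarity is summarized by two numbers used throughout the variant
characterization rules: *identity* (matches divided by alignment columns,
gap columns included) and *aligned ratio* (aligned query bases divided by
query length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

__all__ = [
    "Scoring",
    "AlignmentResult",
    "global_align",
    "local_align",
    "age_realign",
    "identity_and_aligned_ratio",
]


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring: a gap of length L costs open + (L-1)*extend."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open > self.gap_extend or self.gap_extend > 0:
            raise ValueError("require gap_open <= gap_extend <= 0")


DEFAULT_SCORING = Scoring()


@dataclass
class AlignmentResult:
    score: float
    identity: float  # matches / alignment columns, in [0, 1]
    aligned_ratio: float  # aligned query (first sequence) bases / query length
    ops: list[tuple[str, int]]  # cigar-like, ops in {M, I, D}
    query_start: int
    query_end: int
    target_start: int
    target_end: int


def _aligner(scoring: Scoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _empty_result(query: str) -> AlignmentResult:
    return AlignmentResult(0.0, 0.0, 0.0, [], 0, 0, 0, 0)


def _summarize(alignment, query: str, target: str, mode: str) -> AlignmentResult:
    q_blocks, t_blocks = alignment.aligned
    if len(q_blocks) == 0:
        return _empty_result(query)
    matches = 0
    columns = 0
    aligned_q = 0
    ops: list[tuple[str, int]] = []

    def push(op: str, length: int) -> None:
        if length <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    if mode == "global":
        push("I", int(q_blocks[0][0]))
        push("D", int(t_blocks[0][0]))
        columns += int(q_blocks[0][0]) + int(t_blocks[0][0])
    prev_q = int(q_blocks[0][0])
    prev_t = int(t_blocks[0][0])
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        qs, qe, ts, te = int(qs), int(qe), int(ts), int(te)
        push("I", qs - prev_q)
        push("D", ts - prev_t)
        columns += (qs - prev_q) + (ts - prev_t)
        seg_q, seg_t = query[qs:qe], target[ts:te]
        matches += sum(x == y for x, y in zip(seg_q, seg_t))
        push("M", qe - qs)
        columns += qe - qs
        aligned_q += qe - qs
        prev_q, prev_t = qe, te
    if mode == "global":
        push("I", len(query) - prev_q)
        push("D", len(target) - prev_t)
        columns += (len(query) - prev_q) + (len(target) - prev_t)
    identity = matches / columns if columns else 0.0
    return AlignmentResult(
        score=float(alignment.score),
        identity=identity,
        aligned_ratio=aligned_q / len(query) if query else 0.0,
        ops=ops,
        query_start=0 if mode == "global" else int(q_blocks[0][0]),
        query_end=len(query) if mode == "global" else int(q_blocks[-1][1]),
        target_start=0 if mode == "global" else int(t_blocks[0][0]),
        target_end=len(target) if mode == "global" else int(t_blocks[-1][1]),
    )


def global_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal affine-gap global alignment of query ``a`` against target ``b``."""
    if not a or not b:
        raise ValueError("global_align requires nonempty sequences")
    alignment = _aligner(scoring, "global").align(a, b)[0]
    return _summarize(alignment, a, b, "global")


def local_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Best Smith-Waterman local alignment of query ``a`` against target ``b``."""
    if not a or not b:
        raise ValueError("local_align requires nonempty sequences")
    alignments = _aligner(scoring, "local").align(a, b)
    if alignments.score <= 0:
        return _empty_result(a)
    return _summarize(alignments[0], a, b, "local")


#: above this query*target size, similarity screening switches to the
#: bit-parallel semi-global aligner (edlib) instead of full Smith-Waterman
EDLIB_CELL_THRESHOLD = 20_000_000


def identity_and_aligned_ratio(
    query: str, target: str, scoring: Scoring = DEFAULT_SCORING
) -> tuple[float, float]:
    """(identity, aligned ratio) of the best local alignment of query to target.

    For very large targets (query x target beyond ``EDLIB_CELL_THRESHOLD``
    cells) the measurement falls back to a bit-parallel semi-global
    alignment: the whole query is aligned against the best-matching target
    infix, identity is derived from the edit distance, and the aligned
    ratio is 1 by construction -- the identity criterion then carries the
    screening.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    if len(query) * len(target) > EDLIB_CELL_THRESHOLD:
        import edlib

        hit = edlib.align(query, target, mode="HW", task="locations")
        start, end = hit["locations"][0]
        columns = max(end - start + 1, len(query))
        identity = max(1.0 - hit["editDistance"] / columns, 0.0)
        return identity, 1.0
    result = local_align(query, target, scoring)
    return result.identity, result.aligned_ratio


# --- align-gap-excise realignment ----------------------------------------

_NEG = -1e18


def _prefix_score_matrix(a: str, b: str, sc: Scoring) -> np.ndarray:
    """H[i, j] = best affine-gap global alignment score of a[:i] vs b[:j].

    Row-vectorized three-state DP.  Opening a horizontal gap from a cell
    whose best path ends in a horizontal gap is dominated by extending
    (gap_open <= gap_extend), so the in-row scan over the gap-free state is
    exact.
    """
    n, m = len(a), len(b)
    go, ge = sc.gap_open, sc.gap_extend
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, 0] = 0.0
    if m:
        H[0, 1:] = go + ge * np.arange(m)
    Fv = np.full(m + 1, _NEG)  # vertical-gap state of the previous row
    jj = np.arange(1, m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        Fv = np.maximum(Fv + ge, H[i - 1] + go)
        sub = np.where(b_arr == ord(a[i - 1]), sc.match, sc.mismatch)
        H0 = np.empty(m + 1)
        H0[0] = go + ge * (i - 1)
        if m:
            H0[1:] = np.maximum(H[i - 1, :-1] + sub, Fv[1:])
            C = H0[:-1] + go - ge * jj
            E = ge * jj + np.maximum.accumulate(C)
            H[i] = H0
            H[i, 1:] = np.maximum(H0[1:], E)
        else:
            H[i] = H0
    return H


def global_score(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> float:
    """Affine-gap global alignment score (empty sequences allowed)."""
    return float(_prefix_score_matrix(a, b, scoring)[len(a), len(b)])


def age_realign(
    ref_window: str, alt_window: str, scoring: Scoring = DEFAULT_SCORING
) -> tuple[int, int, int, int, str, str]:
    """Split two windows to maximize 5'-prefix plus 3'-suffix alignment score.

    Returns ``(left_ref, right_ref, left_alt, right_alt, excised_ref,
    excised_alt)`` where the excised middles ``ref_window[left_ref:right_ref]``
    and ``alt_window[left_alt:right_alt]`` are the variant alleles.  Among
    score-optimal splits the leftmost is returned (smallest ``(left_ref,
    left_alt)``, then smallest ``(right_ref, right_alt)``); if the
    optimal excision is empty on both sides (no variant) the breakpoints are
    reported at the window ends.
    """
    n, m = len(ref_window), len(alt_window)
    if n < 2 or m < 2:
        raise ValueError("windows must be at least 2 bp")
    F = _prefix_score_matrix(ref_window, alt_window, scoring)
    Brev = _prefix_score_matrix(ref_window[::-1], alt_window[::-1], scoring)
    B = Brev[::-1, ::-1]  # B[i, j] = score of ref[i:] vs alt[j:]
    # suffix max of B over (i2 >= i, j2 >= j)
    Bmax = np.maximum.accumulate(B[::-1], axis=0)[::-1]
    Bmax = np.maximum.accumulate(Bmax[:, ::-1], axis=1)[:, ::-1]
    total = F + Bmax
    best = total.max()
    i1, j1 = np.unravel_index(int(np.argmax(total == best)), total.shape)
    target = best - F[i1, j1]
    feasible = B[i1:, j1:] >= target - 1e-9
    di, dj = np.unravel_index(int(np.argmax(feasible)), feasible.shape)
    i2, j2 = i1 + int(di), j1 + int(dj)
    if i1 == i2 and j1 == j2:
        return n, n, m, m, "", ""
    return (
        int(i1),
        int(i2),
        int(j1),
        int(j2),
        ref_window[i1:i2],
        alt_window[j1:j2],
    )
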