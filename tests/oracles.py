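"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive: plain-Python three-state Gotoh
dynamic programming, exhaustive enumerations and direct formula
evaluations, sharing no code with the implementation under test.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")


def brute_global_prefix_matrix(
    a, b, match=1.0, mismatch=-2.0, gap_open=-4.0, gap_extend=-1.0
):
    """H[i][j] = affine-gap global score of a[:i] vs b[:j], by explicit
    three-state DP (a gap of length L costs gap_open + (L-1)*gap_extend)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # last column aligned
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
        for j in range(0, m + 1):
            if i >= 1:
                X[i][j] = max(
                    X[i - 1][j] + gap_extend,
                    M[i - 1][j] + gap_open,
                    Y[i - 1][j] + gap_open,
                )
        for j in range(1, m + 1):
            Y[i][j] = max(
                Y[i][j - 1] + gap_extend,
                M[i][j - 1] + gap_open,
                X[i][j - 1] + gap_open,
            )
    return [
        [max(M[i][j], X[i][j], Y[i][j]) for j in range(m + 1)]
        for i in range(n + 1)
    ]


def brute_global_score(a, b, **scoring):
    return brute_global_prefix_matrix(a, b, **scoring)[len(a)][len(b)]


def brute_age_split_score(a, b, **scoring):
    """Best prefix+suffix split score by exhaustive enumeration over all
    (i1 <= i2, j1 <= j2), with prefix/suffix scores from the brute DP."""
    F = brute_global_prefix_matrix(a, b, **scoring)
    Brev = brute_global_prefix_matrix(a[::-1], b[::-1], **scoring)
    n, m = len(a), len(b)
    best = NEG
    for i1 in range(n + 1):
        for j1 in range(m + 1):
            for i2 in range(i1, n + 1):
                for j2 in range(j1, m + 1):
                    best = max(best, F[i1][j1] + Brev[n - i2][m - j2])
    return best


def brute_local_score(a, b, **scoring):
    """Smith-Waterman score as the max global score over all substring pairs."""
    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, brute_global_score(a[i1:i2], b[j1:j2], **scoring))
    return best


def column_scan_variants(ref_row, query_row, ref_start):
    """Naive per-column variant scan of one gapped block.

    Returns (kind, ref_position, ref_bases, query_bases) tuples where the
    position of an indel is the 0-based coordinate of its first affected
    reference base (insertions: the base to their right).
    """
    out = []
    rpos = ref_start
    i = 0
    cols = list(zip(ref_row, query_row))
    while i < len(cols):
        r, q = cols[i]
        if r != "-" and q != "-":
            if r != q:
                out.append(("snp", rpos, r, q))
            rpos += 1
            i += 1
        elif q == "-":
            start = rpos
            bases = ""
            while i < len(cols) and cols[i][1] == "-":
                bases += cols[i][0]
                rpos += 1
                i += 1
            out.append(("del", start, bases, ""))
        else:
            bases = ""
            while i < len(cols) and cols[i][0] == "-":
                bases += cols[i][1]
                i += 1
            out.append(("ins", rpos, "", bases))
    return out


def leftmost_indel_position(ref_seq, pos, deleted, inserted):
    """Leftmost equivalent placement of replacing ref[pos:pos+len(deleted)]
    with ``inserted``, found by comparing the edited haplotypes of every
    candidate position."""
    target = ref_seq[:pos] + inserted + ref_seq[pos + len(deleted) :]
    dl, il = len(deleted), len(inserted)
    for p in range(pos + 1):
        # any replacement of ref[p:p+dl] by some same-length string gives
        # `target` iff the flanks agree; the replacement itself is then
        # target[p:p+il] (rotations of the original allele are equivalent)
        if ref_seq[:p] == target[:p] and ref_seq[p + dl :] == target[p + il :]:
            return p
    return pos


def mendelian_consistent(child, father, mother):
    """27-case transmission check on alt-allele doses (0/1/2)."""
    transmit = {0: {0}, 1: {0, 1}, 2: {1}}
    return any(
        fa + mo == child for fa in transmit[father] for mo in transmit[mother]
    )


def mannwhitney_auc(pos_scores, neg_scores):
    """AUC as the normalized Mann-Whitney U statistic (tie-corrected)."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))
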