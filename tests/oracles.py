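"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately written from the definitions (textbook Gotoh DP,
split enumeration, substring scans) and share no code with the package's
implementations.
"""

NEG = -1e9


def gotoh_end_scores(q, r, match=2, mismatch=-4, gap_open=-4, gap_extend=-2):
    """best[i] = best score of a local alignment of q[:i] vs r ending
    exactly at query position i (any ref position), affine gaps.

    A gap run of length L costs gap_open + gap_extend * L."""
    n, m = len(q), len(r)
    open_cost = gap_open + gap_extend
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = [NEG] * (n + 1)
    best[0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            F[i][j] = max(H[i - 1][j] + open_cost, F[i - 1][j] + gap_extend)
            E[i][j] = max(H[i][j - 1] + open_cost, E[i][j - 1] + gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + s, s, E[i][j], F[i][j])
        row = H[i][1:]
        best[i] = max(row) if row else NEG
    return best


def jump_oracle(q, r1, r2, jump_penalty=0.0, per_inserted_base=0.0, **scores):
    """Exhaustive enumeration over all query split points of constrained
    two-piece local alignment: an end-anchored piece of q[:i1] vs ref1
    plus a start-anchored piece of q[i2:] vs ref2 (empty pieces score 0),
    plus the jump terms; pure single-region alignments compete without a
    jump."""
    n = len(q)
    F1 = gotoh_end_scores(q, r1, **scores)
    G_rev = gotoh_end_scores(q[::-1], r2[::-1], **scores)
    G = [G_rev[n - i] for i in range(n + 1)]  # start-anchored at query i
    best = 0.0
    for i2 in range(n + 1):
        p2 = G[i2] if i2 < n else 0.0
        if p2 < -1e8:
            continue
        for i1 in range(i2 + 1):
            p1 = F1[i1] if i1 > 0 else 0.0
            if p1 < -1e8:
                continue
            best = max(best, p1 + p2 + jump_penalty
                       + per_inserted_base * (i2 - i1))
    best = max(best, max(F1), max(G))
    return best


def polya_oracle(seq, window=30, min_len=10, min_frac=0.8):
    """Brute-force scan over all terminal run lengths: the longest k such
    that the last k bases (A, 3' side) or first k bases (T, 5' side)
    contain at least min_frac base purity and end on the tail base."""
    best = None
    for side, term, base in (("3'", seq[-window:][::-1], "A"),
                             ("5'", seq[:window], "T")):
        for k in range(len(term), 0, -1):
            sub = term[:k]
            if sub[0] != base or sub[-1] != base:
                continue
            if sub.count(base) / k >= min_frac and k >= min_len:
                if best is None or k > best[0]:
                    best = (k, side)
                break
    return best
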