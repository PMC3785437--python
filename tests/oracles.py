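"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and self-contained: plain-Python
dynamic programming, exhaustive enumeration and position-by-position scans,
sharing no code with the package paths they check.
"""

from __future__ import annotations

import math

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}


def sw_score_dp(a, b, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Plain-Python affine-gap Smith-Waterman (gap of k costs open+(k-1)ext)."""
    neg = float("-inf")
    m, n = len(a), len(b)
    best = 0.0
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]
    F = [[neg] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def sw_score_enum(a, b, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Exhaustive enumeration of every local alignment path (tiny inputs only).

    Alignments start and end on aligned columns (trailing gaps cannot raise
    a score under negative gap penalties); interior gap runs are charged
    open + (k-1) * extend.
    """
    m, n = len(a), len(b)
    best = 0.0

    def rec(i, j, score, last):
        nonlocal best
        if i < m and j < n:
            s2 = score + (match if a[i] == b[j] else mismatch)
            best = max(best, s2)
            rec(i + 1, j + 1, s2, "M")
        if last is not None:
            if i < m:
                rec(i + 1, j, score + (gap_extend if last == "D" else gap_open), "D")
            if j < n:
                rec(i, j + 1, score + (gap_extend if last == "I" else gap_open), "I")

    for i in range(m):
        for j in range(n):
            rec(i, j, 0.0, None)
    return best


def iupac_scan(pattern, text, max_mismatch=0):
    """Position-by-position degenerate pattern scan (1-based starts)."""
    hits = []
    for start in range(len(text) - len(pattern) + 1):
        mm = 0
        for p, t in zip(pattern, text[start : start + len(pattern)]):
            if not (IUPAC.get(p.upper(), set()) & IUPAC.get(t.upper(), set())):
                mm += 1
        if mm <= max_mismatch:
            hits.append(start + 1)
    return hits


def p_dist(a, b):
    """Pairwise-deletion p-distance (None when no comparable site)."""
    diff = comp = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        comp += 1
        if not (IUPAC[x] & IUPAC[y]):
            diff += 1
    return diff / comp if comp else None


def window_success(seqs, species, start, w):
    """Naive nearest-neighbour identification success for one window.

    ``seqs``/``species`` are parallel lists; returns (I or None, n_evaluated).
    """
    subs = [s[start - 1 : start - 1 + w] for s in seqs]
    n_eval = correct = 0
    for i in range(len(subs)):
        dists = {}
        for j in range(len(subs)):
            if j == i:
                continue
            d = p_dist(subs[i], subs[j])
            if d is not None:
                dists[j] = d
        singleton = species.count(species[i]) == 1
        if singleton:
            het = [d for j, d in dists.items() if species[j] != species[i]]
            if not het:
                continue
            n_eval += 1
            correct += min(het) > 0
        else:
            if not dists:
                continue
            n_eval += 1
            dmin = min(dists.values())
            nearest = [j for j, d in dists.items() if d == dmin]
            correct += all(species[j] == species[i] for j in nearest)
    return (correct / n_eval if n_eval else None), n_eval


def anova_ss(groups):
    """Sum-of-squares decomposition for one-way ANOVA."""
    ally = [y for g in groups for y in g]
    grand = sum(ally) / len(ally)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((y - sum(g) / len(g)) ** 2 for g in groups for y in g)
    df1 = len(groups) - 1
    df2 = len(ally) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return f, df1, df2


def bisect_lambda(p_match, s_match, s_mismatch, tol=1e-12):
    """Bisection root of p*exp(l*s1) + (1-p)*exp(l*s2) = 1 on l > 0."""
    f = lambda l: p_match * math.exp(l * s_match) + (1 - p_match) * math.exp(l * s_mismatch) - 1
    lo, hi = tol, 1.0
    while f(hi) < 0:
        hi *= 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
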