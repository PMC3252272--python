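"""Exhaustive-enumeration oracles for small duplex alignment problems.

Two independent searches, neither using dynamic programming:

* ``enumerate_paths`` walks every feasible move sequence (pair /
  miRNA-bulge / target-bulge with the production feasibility rules).  Its
  path count explodes combinatorially, so it is only used at tiny sizes to
  cross-validate the chain enumerator below.
* ``brute_force_optima`` enumerates every monotone chain of both-consuming
  columns (an alignment is fully determined by that chain: all remaining
  bases are bulged), scoring each chain directly.  This covers the same
  alignment space exactly -- a gap of a miRNA and b target bases between
  consecutive columns is realizable under the bulge-run cap iff
  b <= cap*(a+1) and a <= cap*(b+1) -- while keeping the enumeration within
  C(m+n, m) leaves.
"""

from __future__ import annotations

import math
from typing import Iterator

from mirduplex.duplex import (
    EnergyParams,
    PairState,
    ScoringParams,
    pair_state,
)

_PAIR, _BM, _BT = 0, 1, 2


def _gap_ok(a: int, b: int, cap: int) -> bool:
    return b <= cap * (a + 1) and a <= cap * (b + 1)


def enumerate_paths(mir: str, tgt_rev: str, params: ScoringParams) -> Iterator[list[tuple[int, int, int]]]:
    """Every feasible complete move sequence [(move, i, j), ...] (tiny sizes only)."""
    m, n = len(mir), len(tgt_rev)
    rule = params.require_paired_10_11 and m >= 11
    cap = params.max_bulge_len

    def rec(i, j, rt, rl, path):
        if i == m and j == n:
            yield list(path)
            return
        if j < n and not (rt == _BT and rl >= cap) and not (rule and i == 10):
            path.append((_BT, i, j))
            yield from rec(i, j + 1, _BT, rl + 1 if rt == _BT else 1, path)
            path.pop()
        if i < m and not (rt == _BM and rl >= cap) and not (rule and i in (9, 10)):
            path.append((_BM, i, j))
            yield from rec(i + 1, j, _BM, rl + 1 if rt == _BM else 1, path)
            path.pop()
        if i < m and j < n:
            st = pair_state(mir[i], tgt_rev[j])
            if not (rule and i in (9, 10) and st is PairState.MISMATCH):
                path.append((_PAIR, i, j))
                yield from rec(i + 1, j + 1, _PAIR, 0, path)
                path.pop()

    yield from rec(0, 0, _PAIR, 0, [])


def path_score(mir: str, tgt_rev: str, path, params: ScoringParams) -> float:
    pen = {PairState.WATSON_CRICK: 0.0,
           PairState.GU_WOBBLE: params.wobble_penalty,
           PairState.MISMATCH: params.mismatch_penalty}
    s = 0.0
    for move, i, j in path:
        if move == _PAIR:
            s += pen[pair_state(mir[i], tgt_rev[j])]
        else:
            s += params.bulge_penalty_per_nt
    return s


def brute_force_optima(
    mir: str,
    win: str,
    params: ScoringParams | None = None,
    energy: EnergyParams | None = None,
) -> tuple[float, float]:
    """(min penalty score, min ΔG over alignments with >= 2 canonical pairs).

    Either value is +inf when no feasible alignment (resp. no alignment with
    two canonical pairs) exists.
    """
    params = params or ScoringParams()
    ep = energy or EnergyParams()
    tgt = win[::-1]
    m, n = len(mir), len(tgt)
    rule = params.require_paired_10_11 and m >= 11
    cap = params.max_bulge_len
    colpen = [[0.0] * n for _ in range(m)]
    canonical = [[False] * n for _ in range(m)]
    mismatch = [[False] * n for _ in range(m)]
    for i in range(m):
        for j in range(n):
            st = pair_state(mir[i], tgt[j])
            canonical[i][j] = st is not PairState.MISMATCH
            mismatch[i][j] = st is PairState.MISMATCH
            colpen[i][j] = (0.0 if st is PairState.WATSON_CRICK
                            else params.wobble_penalty
                            if st is PairState.GU_WOBBLE
                            else params.mismatch_penalty)
    bp = params.bulge_penalty_per_nt

    def rule_col_ok(i, j):
        # columns at miRNA indices 9/10 must be canonical pairs
        return not (rule and i in (9, 10) and mismatch[i][j])

    def rule_chain_ok(chain):
        if not rule:
            return True
        idx = {i for i, _ in chain}
        if 9 not in idx or 10 not in idx:
            return False
        j9 = next(j for i, j in chain if i == 9)
        j10 = next(j for i, j in chain if i == 10)
        return j10 == j9 + 1  # no bulged target base between positions 10/11

    # --- minimum penalty over all chains of both-consuming columns --------
    best_score = math.inf

    def rec_score(i, j, acc, ncols):
        nonlocal best_score
        # option: stop (remaining bases all bulged)
        a, b = m - 1 - i, n - 1 - j
        if _gap_ok(a, b, cap) and not (rule and i < 10):
            total = acc + bp * (a + b)
            if total < best_score:
                best_score = total
        for i2 in range(i + 1, m):
            for j2 in range(j + 1, n):
                a, b = i2 - i - 1, j2 - j - 1
                if not _gap_ok(a, b, cap) or not rule_col_ok(i2, j2):
                    continue
                if rule and (i < 9 < i2 or i < 10 < i2):
                    continue
                if rule and i == 9 and i2 == 10 and b != 0:
                    continue
                rec_score(i2, j2, acc + bp * (a + b) + colpen[i2][j2], ncols + 1)

    # empty chain: everything bulged
    if _gap_ok(m, n, cap) and not rule:
        best_score = bp * (m + n)
    for i in range(m):
        for j in range(n):
            if not _gap_ok(i, j, cap) or not rule_col_ok(i, j):
                continue
            if rule and i > 9:
                continue
            rec_score(i, j, bp * (i + j) + colpen[i][j], 1)

    # --- minimum ΔG over chains of canonical pairs ------------------------
    best_dg = math.inf

    def rec_dg(i, j, acc, npairs, has9, has10):
        nonlocal best_dg
        a, b = m - 1 - i, n - 1 - j
        if (npairs >= 2 and _gap_ok(a, b, cap)
                and (not rule or (has9 and has10))):
            total = acc + ep.terminal(mir[i], tgt[j])
            if total < best_dg:
                best_dg = total
        for i2 in range(i + 1, m):
            for j2 in range(j + 1, n):
                if not canonical[i2][j2]:
                    continue
                a, b = i2 - i - 1, j2 - j - 1
                if not _gap_ok(a, b, cap):
                    continue
                if rule and (i < 9 < i2 or i < 10 < i2):
                    continue
                if rule and i == 9 and i2 == 10 and b != 0:
                    continue
                if a == 0 and b == 0:
                    loop = ep.stack(mir[i], tgt[j], mir[i2], tgt[j2])
                elif a == 0 or b == 0:
                    loop = ep.bulge(a + b)
                    if a + b == 1:
                        loop += ep.stack(mir[i], tgt[j], mir[i2], tgt[j2])
                else:
                    loop = ep.internal(a, b)
                rec_dg(i2, j2, acc + loop, npairs + 1,
                       has9 or i2 == 9, has10 or i2 == 10)

    for i in range(m):
        for j in range(n):
            if not canonical[i][j] or not _gap_ok(i, j, cap):
                continue
            if rule and i > 9:
                continue
            rec_dg(i, j,
                   ep.duplex_initiation + ep.terminal(mir[i], tgt[j]),
                   1, i == 9, False)

    return best_score, best_dg
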