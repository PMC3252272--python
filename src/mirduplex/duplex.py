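"""Bulge-aware miRNA:target duplex alignment and hybridization energetics.

A mature miRNA is aligned antiparallel to a candidate target window
(miRNA 5'->3' against target 3'->5') by dynamic programming over three move
types: a pairing column (Watson-Crick, G:U wobble or mismatch), a bulged
miRNA base, or a bulged target base.  The penalty score follows the
empirically derived plant target-prediction convention (mismatch 1, G:U 0.5,
bulged nucleotide 1, with a configurable cap); pairing of miRNA positions
10-11 -- the AGO cleavage site -- is required by default.

Duplex free energies use an embedded Turner-2004-style nearest-neighbor
parameter set: stack terms for adjacent canonical pairs (including G:U),
length-dependent bulge and internal-loop initiations with a Ninio asymmetry
term, a terminal AU/GU penalty, and an intermolecular initiation term.
Single-nucleotide bulges retain the stack of their closing pairs.  Coaxial
stacking and dangling ends are deliberately omitted: the quantities of
interest are ΔΔG values between duplexes sharing their termini, where those
terms cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence

from .seqio import MatureMiRNA, RnaSequence, normalize_rna

__all__ = [
    "PairState",
    "Column",
    "ScoringParams",
    "EnergyParams",
    "DuplexAlignment",
    "align_duplex",
    "score_alignment",
    "duplex_delta_g",
    "delta_delta_g",
    "render_duplex",
    "pair_state",
]


class PairState(Enum):
    WATSON_CRICK = "WC"
    GU_WOBBLE = "GU"
    MISMATCH = "MM"
    BULGE_MIRNA = "BM"   # consumes one miRNA base only
    BULGE_TARGET = "BT"  # consumes one target base only


_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


def pair_state(mir_base: str, tgt_base: str) -> PairState:
    """Classify an opposed base pair."""
    duo = (mir_base, tgt_base)
    if duo in _WC:
        return PairState.WATSON_CRICK
    if duo in _GU:
        return PairState.GU_WOBBLE
    return PairState.MISMATCH


class Column(NamedTuple):
    """One alignment column.

    ``mir_index`` is the 0-based miRNA index counted from the miRNA 5' end
    (miRNA *position* p = mir_index + 1); ``window_index`` is the 0-based
    position in the target window read 5'->3'.  Bulge columns carry ``None``
    on the side they do not consume.
    """

    state: PairState
    mir_index: int | None
    window_index: int | None


@dataclass(frozen=True)
class ScoringParams:
    """Penalty weights of the plant complementarity rule."""

    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    bulge_penalty_per_nt: float = 1.0
    max_score: float = 5.0
    require_paired_10_11: bool = True
    max_bulge_len: int = 3

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.wobble_penalty, self.bulge_penalty_per_nt) < 0:
            raise ValueError("penalties must be non-negative")
        if self.max_bulge_len < 1:
            raise ValueError("max_bulge_len must be >= 1")


# ---------------------------------------------------------------------------
# Turner-2004-style nearest-neighbor parameters (ΔG°37, kcal/mol)
# ---------------------------------------------------------------------------

_PAIR_INDEX = {("C", "G"): 0, ("G", "C"): 1, ("G", "U"): 2,
               ("U", "G"): 3, ("A", "U"): 4, ("U", "A"): 5}

# stack[p1][p2] for 5'-a b-3' / 3'-a' b'-5' with p1 = (a, a'), p2 = (b', b)
_STACK_DG = (
    (-2.40, -3.30, -2.10, -1.40, -2.10, -2.10),  # CG
    (-3.30, -3.40, -2.50, -1.50, -2.20, -2.40),  # GC
    (-2.10, -2.50, +1.30, -0.50, -1.40, -1.30),  # GU
    (-1.40, -1.50, -0.50, +0.30, -0.60, -1.00),  # UG
    (-2.10, -2.20, -1.40, -0.60, -1.10, -0.90),  # AU
    (-2.10, -2.40, -1.30, -1.00, -0.90, -1.30),  # UA
)

# initiation by loop length, index 1..30
_BULGE_DG = (math.inf, 3.80, 2.80, 3.20, 3.60, 4.00, 4.40, 4.60, 4.70, 4.80,
             4.90, 5.00, 5.10, 5.20, 5.30, 5.40, 5.40, 5.50, 5.50, 5.60,
             5.70, 5.70, 5.80, 5.80, 5.80, 5.90, 5.90, 6.00, 6.00, 6.00, 6.10)

# initiation by total loop size (unpaired on both strands), index 2..30
_INTERNAL_DG = (math.inf, math.inf, 1.00, 1.00, 1.10, 2.00, 2.00, 2.10, 2.30,
                2.40, 2.50, 2.60, 2.70, 2.80, 2.90, 2.90, 3.00, 3.10, 3.10,
                3.20, 3.30, 3.30, 3.40, 3.40, 3.50, 3.50, 3.50, 3.60, 3.60,
                3.70, 3.70)


def _default_stack_table() -> dict[tuple[str, str, str, str], float]:
    """Stack ΔG keyed by (x1, y1, x2, y2): pair x1·y1 5' of pair x2·y2."""
    table = {}
    for (a, ap), i in _PAIR_INDEX.items():
        for (bp, b), j in _PAIR_INDEX.items():
            table[(a, ap, b, bp)] = _STACK_DG[i][j]
    return table


@dataclass(frozen=True)
class EnergyParams:
    """Nearest-neighbor free-energy parameters (kcal/mol at 37 °C)."""

    stack_table: dict[tuple[str, str, str, str], float] = field(
        default_factory=_default_stack_table
    )
    bulge_loop_penalty: tuple[float, ...] = _BULGE_DG
    internal_loop_penalty: tuple[float, ...] = _INTERNAL_DG
    terminal_au_penalty: float = 0.50
    duplex_initiation: float = 4.10
    ninio_per_asymmetry: float = 0.60
    ninio_max: float = 3.00

    def stack(self, x1: str, y1: str, x2: str, y2: str) -> float:
        return self.stack_table[(x1, y1, x2, y2)]

    def bulge(self, length: int) -> float:
        idx = min(length, len(self.bulge_loop_penalty) - 1)
        return self.bulge_loop_penalty[idx]

    def internal(self, a: int, b: int) -> float:
        size = min(a + b, len(self.internal_loop_penalty) - 1)
        asym = min(self.ninio_per_asymmetry * abs(a - b), self.ninio_max)
        return self.internal_loop_penalty[size] + asym

    def terminal(self, x: str, y: str) -> float:
        return self.terminal_au_penalty if "U" in (x, y) else 0.0


DEFAULT_ENERGY = EnergyParams()
DEFAULT_SCORING = ScoringParams()


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplexAlignment:
    """A complete antiparallel alignment of one miRNA against one window.

    Columns run in miRNA 5'->3' order (window indices descending); every
    miRNA and window base is consumed exactly once.  ``score`` is the penalty
    under the plant complementarity rule; ``delta_g`` the nearest-neighbor
    hybridization free energy (NaN when fewer than two canonical pairs).
    A "no site" sentinel has empty columns and infinite score.
    """

    mirna: MatureMiRNA | RnaSequence
    target_window: RnaSequence
    columns: tuple[Column, ...]
    score: float
    delta_g: float

    @property
    def is_site(self) -> bool:
        return math.isfinite(self.score)

    @property
    def mir_seq(self) -> str:
        return self.mirna.seq.seq if isinstance(self.mirna, MatureMiRNA) else self.mirna.seq

    def paired_columns(self) -> list[Column]:
        return [c for c in self.columns
                if c.state in (PairState.WATSON_CRICK, PairState.GU_WOBBLE)]

    def counts(self) -> dict[PairState, int]:
        out = {s: 0 for s in PairState}
        for c in self.columns:
            out[c.state] += 1
        return out

    def bulge_positions(self) -> list[tuple[str, int]]:
        """Bulge columns as (side, miRNA position the bulge follows)."""
        out = []
        last_mir = 0
        for c in self.columns:
            if c.state is PairState.BULGE_TARGET:
                out.append(("target", last_mir))
            elif c.state is PairState.BULGE_MIRNA:
                out.append(("mirna", c.mir_index + 1))
                last_mir = c.mir_index + 1
            else:
                last_mir = c.mir_index + 1
        return out

    @classmethod
    def no_site(cls, mirna, window) -> "DuplexAlignment":
        return cls(mirna, window, (), math.inf, math.nan)


def _as_rna(x, default_id: str) -> RnaSequence:
    if isinstance(x, MatureMiRNA):
        return x.seq
    if isinstance(x, RnaSequence):
        return x
    return RnaSequence(default_id, normalize_rna(str(x)))


# ---------------------------------------------------------------------------
# Penalty-score DP
# ---------------------------------------------------------------------------

_PAIR, _BM, _BT = 0, 1, 2  # move codes; also gap-run types (0 = none/pair)


def _column_penalty(state: PairState, p: ScoringParams) -> float:
    if state is PairState.WATSON_CRICK:
        return 0.0
    if state is PairState.GU_WOBBLE:
        return p.wobble_penalty
    if state is PairState.MISMATCH:
        return p.mismatch_penalty
    return p.bulge_penalty_per_nt


def _score_dp(mir: str, tgt: str, p: ScoringParams):
    """Suffix DP: best (penalty, gap_columns) to consume mir[i:] and tgt[j:].

    ``tgt`` is the window *reversed* so both strings read in pairing order.
    Returns the memo table; reconstruction walks it forward preferring, at
    equal keys, BULGE_TARGET then BULGE_MIRNA then pairing, which places gap
    columns as close to the miRNA 5' end as a tie allows.
    """
    m, n = len(mir), len(tgt)
    rule = p.require_paired_10_11 and m >= 11
    cap = p.max_bulge_len
    INF = (math.inf, math.inf)
    memo: dict[tuple[int, int, int, int], tuple[float, float]] = {}

    def moves(i: int, j: int, rt: int, rl: int):
        """Yield (move, cost, next_state); feasibility rules applied here."""
        if j < n:  # bulged target base
            if not (rt == _BT and rl >= cap) and not (rule and i == 10):
                yield _BT, p.bulge_penalty_per_nt, (i, j + 1, _BT, rl + 1 if rt == _BT else 1)
        if i < m:  # bulged miRNA base
            if not (rt == _BM and rl >= cap) and not (rule and i in (9, 10)):
                yield _BM, p.bulge_penalty_per_nt, (i + 1, j, _BM, rl + 1 if rt == _BM else 1)
        if i < m and j < n:
            state = pair_state(mir[i], tgt[j])
            if not (rule and i in (9, 10) and state is PairState.MISMATCH):
                yield _PAIR, _column_penalty(state, p), (i + 1, j + 1, _PAIR, 0)

    def best(i: int, j: int, rt: int, rl: int) -> tuple[float, float]:
        if i == m and j == n:
            return (0.0, 0.0)
        key = (i, j, rt, rl)
        hit = memo.get(key)
        if hit is not None:
            return hit
        memo[key] = INF  # cycle guard (graph is acyclic; placeholder only)
        out = INF
        for move, cost, nxt in moves(i, j, rt, rl):
            tail = best(*nxt)
            cand = (cost + tail[0], (move != _PAIR) + tail[1])
            if cand < out:
                out = cand
        memo[key] = out
        return out

    return best, moves


def _reconstruct_score(mir: str, tgt: str, p: ScoringParams) -> tuple[list[tuple[int, int, int]], float] | None:
    """Return ([(move, i, j), ...], score) for the optimal alignment, or None."""
    best, moves = _score_dp(mir, tgt, p)
    total = best(0, 0, _PAIR, 0)
    if not math.isfinite(total[0]):
        return None
    path: list[tuple[int, int, int]] = []
    i, j, rt, rl = 0, 0, _PAIR, 0
    remaining = total
    while (i, j) != (len(mir), len(tgt)):
        # preference order is the order `moves` yields: BT, BM, PAIR
        for move, cost, nxt in moves(i, j, rt, rl):
            tail = best(*nxt)
            cand = (cost + tail[0], (move != _PAIR) + tail[1])
            if abs(cand[0] - remaining[0]) < 1e-9 and abs(cand[1] - remaining[1]) < 1e-9:
                path.append((move, i, j))
                i, j, rt, rl = nxt
                remaining = tail
                break
        else:  # pragma: no cover - DP consistency guard
            raise RuntimeError("traceback failed")
    return path, total[0]


# ---------------------------------------------------------------------------
# Energy-optimal DP (minimum ΔG over feasible alignments)
# ---------------------------------------------------------------------------

def _gap_feasible(a: int, b: int, cap: int) -> bool:
    """Can a loop with ``a`` miRNA and ``b`` target unpaired bases be written
    as alignment columns whose same-side bulge runs never exceed ``cap``?"""
    return b <= cap * (a + 1) and a <= cap * (b + 1)


def _fill_gap(a: int, b: int, mir_at: int, win_at: int, cap: int) -> list[Column]:
    """Deterministic column sequence for an (a, b) loop.

    ``mir_at`` is the next unconsumed miRNA index, ``win_at`` the next
    unconsumed window index counting *down* (window indices descend as the
    alignment advances).  Unpaired both-strand columns are labelled MISMATCH
    regardless of base identity (structural, not sequence, meaning).
    """
    cols: list[Column] = []
    while a > 0 or b > 0:
        if b > a:
            for _ in range(min(cap, b - a)):
                cols.append(Column(PairState.BULGE_TARGET, None, win_at))
                win_at -= 1
                b -= 1
        elif a > b:
            for _ in range(min(cap, a - b)):
                cols.append(Column(PairState.BULGE_MIRNA, mir_at, None))
                mir_at += 1
                a -= 1
        if a > 0 and b > 0:
            cols.append(Column(PairState.MISMATCH, mir_at, win_at))
            mir_at += 1
            win_at -= 1
            a -= 1
            b -= 1
    return cols


def _energy_chain(mir: str, tgt: str, p: ScoringParams, ep: EnergyParams):
    """Minimum-ΔG chain of canonical pairs (i, j) in reversed-window space."""
    m, n = len(mir), len(tgt)
    rule = p.require_paired_10_11 and m >= 11
    cap = p.max_bulge_len
    pairable = [(i, j) for i in range(m) for j in range(n)
                if pair_state(mir[i], tgt[j]) is not PairState.MISMATCH]

    def link(i: int, j: int, i2: int, j2: int) -> float | None:
        """Loop/stack ΔG between consecutive pairs, or None if infeasible."""
        if i2 <= i or j2 <= j:
            return None
        a, b = i2 - i - 1, j2 - j - 1
        if not _gap_feasible(a, b, cap):
            return None
        if rule and (any(i < q < i2 for q in (9, 10))
                     or (i == 9 and i2 == 10 and b != 0)):
            return None
        if a == 0 and b == 0:
            return ep.stack(mir[i], tgt[j], mir[i2], tgt[j2])
        if a == 0 or b == 0:
            loop = ep.bulge(a + b)
            if a + b == 1:
                loop += ep.stack(mir[i], tgt[j], mir[i2], tgt[j2])
            return loop
        return ep.internal(a, b)

    @lru_cache(maxsize=None)
    def tail(i: int, j: int) -> tuple[float, tuple]:
        """Best (ΔG continuation, chain) after a pair at (i, j); may stop."""
        out: tuple[float, tuple] = (math.inf, ())
        if (not rule or i >= 10) and _gap_feasible(m - 1 - i, n - 1 - j, cap):
            out = (ep.terminal(mir[i], tgt[j]), ())
        for i2, j2 in pairable:
            loop = link(i, j, i2, j2)
            if loop is None:
                continue
            cont = tail(i2, j2)
            cand = (loop + cont[0], ((i2, j2),) + cont[1])
            if cand[0] < out[0] - 1e-12:
                out = cand
        return out

    # enumerate the first two pairs explicitly so the >= 2 canonical-pair
    # requirement cannot be undercut by an early stop in the tail
    best: tuple[float, tuple] = (math.inf, ())
    for i, j in pairable:
        if rule and i > 9:
            continue
        if not _gap_feasible(i, j, cap):
            continue
        head = ep.duplex_initiation + ep.terminal(mir[i], tgt[j])
        for i2, j2 in pairable:
            loop = link(i, j, i2, j2)
            if loop is None:
                continue
            cont = tail(i2, j2)
            chain = ((i, j), (i2, j2)) + cont[1]
            if rule and not any(q[0] == 10 for q in chain):
                continue
            cand = (head + loop + cont[0], chain)
            if cand[0] < best[0] - 1e-12:
                best = cand
    tail.cache_clear()
    return best


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def align_duplex(
    mirna: MatureMiRNA | RnaSequence | str,
    window: RnaSequence | str,
    params: ScoringParams | None = None,
    energy: EnergyParams | None = None,
    objective: str = "penalty",
) -> DuplexAlignment:
    """Globally align one miRNA antiparallel to one target window.

    ``objective="penalty"`` minimizes the complementarity penalty score;
    ``objective="energy"`` minimizes the nearest-neighbor ΔG.  Both respect
    the same feasibility rules (bulge-run cap; pairing of miRNA positions
    10-11 when required and the miRNA is long enough to have them).  If no
    feasible alignment exists, a "no site" sentinel with infinite score is
    returned.
    """
    params = params or DEFAULT_SCORING
    energy = energy or DEFAULT_ENERGY
    mir_rna = _as_rna(mirna, "mirna")
    win_rna = _as_rna(window, "window")
    mirna = mirna if isinstance(mirna, MatureMiRNA) else mir_rna
    m, n = len(mir_rna), len(win_rna)
    if not (m - 3 <= n <= m + 3):
        raise ValueError(f"window length {n} outside band [{m - 3}, {m + 3}]")
    mir, tgt = mir_rna.seq, win_rna.seq[::-1]  # tgt now 3'->5' of the window

    if objective == "penalty":
        rec = _reconstruct_score(mir, tgt, params)
        if rec is None:
            return DuplexAlignment.no_site(mirna, win_rna)
        path, score = rec
        cols = []
        for move, i, j in path:
            if move == _PAIR:
                cols.append(Column(pair_state(mir[i], tgt[j]), i, n - 1 - j))
            elif move == _BM:
                cols.append(Column(PairState.BULGE_MIRNA, i, None))
            else:
                cols.append(Column(PairState.BULGE_TARGET, None, n - 1 - j))
    elif objective == "energy":
        dg, chain = _energy_chain(mir, tgt, params, energy)
        if not math.isfinite(dg):
            return DuplexAlignment.no_site(mirna, win_rna)
        cols = []
        pi, pj = -1, -1
        for i, j in chain:
            cols.extend(_fill_gap(i - pi - 1, j - pj - 1, pi + 1,
                                  n - 1 - (pj + 1), params.max_bulge_len))
            cols.append(Column(pair_state(mir[i], tgt[j]), i, n - 1 - j))
            pi, pj = i, j
        cols.extend(_fill_gap(m - 1 - pi, len(tgt) - 1 - pj, pi + 1,
                              n - 1 - (pj + 1), params.max_bulge_len))
        score = sum(_column_penalty(c.state, params) for c in cols)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    aln = DuplexAlignment(mirna, win_rna, tuple(cols), float(score), math.nan)
    n_paired = len(aln.paired_columns())
    dg = duplex_delta_g(aln, energy) if n_paired >= 2 else math.nan
    return DuplexAlignment(mirna, win_rna, tuple(cols), float(score), dg)


def min_penalty_capped(
    mirna: MatureMiRNA | RnaSequence | str,
    window: RnaSequence | str,
    params: ScoringParams | None = None,
    cap: float | None = None,
) -> float:
    """Optimal penalty of a window, or +inf if it exceeds ``cap``.

    Iterative forward DP identical in feasibility rules to ``align_duplex``
    but pruning partial alignments above the cap (all move costs are
    non-negative), so scanning long transcripts stays cheap.  Used as an
    exact prescreen: it never reports a finite value that ``align_duplex``
    would not reproduce.
    """
    params = params or DEFAULT_SCORING
    cap = params.max_score if cap is None else cap
    mir_rna = _as_rna(mirna, "mirna")
    win_rna = _as_rna(window, "window")
    mirna = mirna if isinstance(mirna, MatureMiRNA) else mir_rna
    m, n = len(mir_rna), len(win_rna)
    if not (m - 3 <= n <= m + 3):
        raise ValueError(f"window length {n} outside band [{m - 3}, {m + 3}]")
    mir, tgt = mir_rna.seq, win_rna.seq[::-1]
    rule = params.require_paired_10_11 and m >= 11
    brl = params.max_bulge_len
    bulge_pen = params.bulge_penalty_per_nt
    eps = 1e-9
    pen, is_mm = {}, {}
    for x in "ACGU":
        for y in "ACGU":
            st = pair_state(x, y)
            pen[x + y] = _column_penalty(st, params)
            is_mm[x + y] = st is PairState.MISMATCH

    inf = math.inf
    # layer[j] maps (run_type, run_len) -> best cost with j target bases consumed
    layer: list[dict[tuple[int, int], float]] = [dict() for _ in range(n + 1)]
    layer[0][(_PAIR, 0)] = 0.0
    for i in range(m + 1):
        # close bulged-target moves within this miRNA layer (j ascending)
        if not (rule and i == 10):
            for j in range(n):
                nxt_bucket = layer[j + 1]
                for (rt, rl), cost in list(layer[j].items()):
                    if rt == _BT and rl >= brl:
                        continue
                    nc = cost + bulge_pen
                    nk = (_BT, rl + 1 if rt == _BT else 1)
                    if nc <= cap + eps and nc < nxt_bucket.get(nk, inf) - 1e-12:
                        nxt_bucket[nk] = nc
        if i == m:
            break
        nxt: list[dict[tuple[int, int], float]] = [dict() for _ in range(n + 1)]
        mm_banned = rule and i in (9, 10)
        x = mir[i]
        empty = True
        for j in range(n + 1):
            bucket = layer[j]
            if not bucket:
                continue
            if j < n:
                duo = x + tgt[j]
                p = pen[duo]
                pair_ok = not (mm_banned and is_mm[duo])
                pair_bucket = nxt[j + 1]
            bm_bucket = nxt[j]
            for (rt, rl), cost in bucket.items():
                if j < n and pair_ok:
                    nc = cost + p
                    if nc <= cap + eps and nc < pair_bucket.get((_PAIR, 0), inf) - 1e-12:
                        pair_bucket[(_PAIR, 0)] = nc
                        empty = False
                if not mm_banned and not (rt == _BM and rl >= brl):
                    nc = cost + bulge_pen
                    nk = (_BM, rl + 1 if rt == _BM else 1)
                    if nc <= cap + eps and nc < bm_bucket.get(nk, inf) - 1e-12:
                        bm_bucket[nk] = nc
                        empty = False
        layer = nxt
        if empty:
            return inf
    finals = layer[n].values()
    return min(finals) if finals else inf


def score_alignment(aln: DuplexAlignment, params: ScoringParams | None = None) -> float:
    """Penalty score of an alignment from its column census."""
    params = params or DEFAULT_SCORING
    return float(sum(_column_penalty(c.state, params) for c in aln.columns))


def duplex_delta_g(aln: DuplexAlignment, ep: EnergyParams | None = None) -> float:
    """Additive nearest-neighbor ΔG (kcal/mol) of an alignment.

    Initiation + stacks over adjacent canonical pairs + bulge/internal-loop
    initiations for each maximal unpaired run between pairs (1-nt bulges keep
    their closing stack) + terminal AU/GU penalties.  Bases outside the
    outermost pairs contribute nothing (no dangling-end terms).
    """
    ep = ep or DEFAULT_ENERGY
    mir = aln.mir_seq
    win = aln.target_window.seq
    pairs = [c for c in aln.columns
             if c.state in (PairState.WATSON_CRICK, PairState.GU_WOBBLE)]
    if len(pairs) < 2:
        raise ValueError("duplex energy needs at least two paired columns")
    dg = ep.duplex_initiation
    first, last = pairs[0], pairs[-1]
    dg += ep.terminal(mir[first.mir_index], win[first.window_index])
    dg += ep.terminal(mir[last.mir_index], win[last.window_index])
    for c0, c1 in zip(pairs, pairs[1:]):
        a = c1.mir_index - c0.mir_index - 1
        b = c0.window_index - c1.window_index - 1  # window indices descend
        x1, y1 = mir[c0.mir_index], win[c0.window_index]
        x2, y2 = mir[c1.mir_index], win[c1.window_index]
        if a == 0 and b == 0:
            dg += ep.stack(x1, y1, x2, y2)
        elif a == 0 or b == 0:
            dg += ep.bulge(a + b)
            if a + b == 1:
                dg += ep.stack(x1, y1, x2, y2)
        else:
            dg += ep.internal(a, b)
    return dg


def delta_delta_g(
    aln_a: DuplexAlignment, aln_b: DuplexAlignment, ep: EnergyParams | None = None
) -> float:
    """ΔΔG = ΔG(b) - ΔG(a); negative means b binds the shared window more strongly."""
    if aln_a.target_window.seq != aln_b.target_window.seq:
        raise ValueError("alignments must share the same target window")
    ep = ep or DEFAULT_ENERGY
    return duplex_delta_g(aln_b, ep) - duplex_delta_g(aln_a, ep)


def render_duplex(aln: DuplexAlignment) -> str:
    """Three-line rendering: target 5'->3' on top, miRNA 3'->5' below."""
    top, mid, bot = [], [], []
    for c in reversed(aln.columns):  # left-to-right = target 5'->3'
        if c.state is PairState.BULGE_TARGET:
            top.append(aln.target_window.seq[c.window_index])
            mid.append(" ")
            bot.append("-")
        elif c.state is PairState.BULGE_MIRNA:
            top.append("-")
            mid.append(" ")
            bot.append(aln.mir_seq[c.mir_index])
        else:
            top.append(aln.target_window.seq[c.window_index])
            bot.append(aln.mir_seq[c.mir_index])
            mid.append({PairState.WATSON_CRICK: "|",
                        PairState.GU_WOBBLE: "o",
                        PairState.MISMATCH: " "}[c.state])
    return (
        "5' " + "".join(top) + " 3'  (target)\n"
        "   " + "".join(mid) + "\n"
        "3' " + "".join(bot) + " 5'  (miRNA)"
    )
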