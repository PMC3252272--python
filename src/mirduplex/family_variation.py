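"""Per-position sequence variation within miRNA families.

For each family a consensus is computed (per-position majority over the
5'-anchored members) and deviations from the consensus are counted at each
position.  Counts are normalized by family size so every family contributes
at most 1 per position, and family profiles are summed into a per-position
variation summary.  Families can be merged (members pooled and the profile
recomputed) -- e.g. miR159 and miR319, which are conventionally treated as
one superfamily.

Length heterogeneity is handled by 5' anchoring: a missing base at a
position (shorter member, or member extending past the trimmed consensus)
counts as a deviation there.  By default an indel-carrying member deviates
at every out-of-register downstream position too; the optional ``gapped``
mode re-aligns each member to the consensus with a single-gap allowance and
registers one deviation at the gap position instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import MatureMiRNA, RnaSequence

logger = logging.getLogger("mirduplex")

_BASE_ORDER = "ACGU"  # consensus tie-break: lexicographic

__all__ = [
    "FamilyProfile",
    "VariationSummary",
    "family_consensus",
    "family_profile",
    "variation_profile",
    "merge_families",
]


@dataclass(frozen=True)
class FamilyProfile:
    family_id: str
    n_members: int
    consensus: RnaSequence
    deviations: tuple[int, ...]          # d_p, p = 1..P (5'-anchored)
    normalized: tuple[float, ...]        # v_p = d_p / n_members


@dataclass(frozen=True)
class VariationSummary:
    """Per-position totals V_p = sum over families of v_p (positions 1..P)."""

    profiles: tuple[FamilyProfile, ...]

    @property
    def n_positions(self) -> int:
        return max((len(p.normalized) for p in self.profiles), default=0)

    @property
    def totals(self) -> tuple[float, ...]:
        P = self.n_positions
        v = [0.0] * P
        for prof in self.profiles:
            for i, x in enumerate(prof.normalized):
                v[i] += x
        return tuple(v)

    def contributing_families(self, position: int) -> list[str]:
        """Families with nonzero normalized deviation at a 1-based position."""
        i = position - 1
        return [p.family_id for p in self.profiles
                if i < len(p.normalized) and p.normalized[i] > 0]


def _seqs(members: Sequence[MatureMiRNA | RnaSequence | str]) -> list[str]:
    out = []
    for m in members:
        if isinstance(m, MatureMiRNA):
            out.append(m.seq.seq)
        elif isinstance(m, RnaSequence):
            out.append(m.seq)
        else:
            out.append(str(m))
    return out


def family_consensus(members: Sequence[MatureMiRNA | RnaSequence | str],
                     family_id: str = "family") -> RnaSequence:
    """Per-position majority base over 5'-anchored members.

    Ties break lexicographically (A < C < G < U).  Trailing positions where
    fewer than half the members have a base are trimmed.  A single-member
    family returns that member (with a warning: no variation measurable).
    """
    seqs = _seqs(members)
    if not seqs:
        raise ValueError("empty family")
    if len(seqs) == 1:
        logger.warning("family %s has a single member; no variation measurable",
                       family_id)
        return RnaSequence(f"{family_id}-consensus", seqs[0])
    P = max(len(s) for s in seqs)
    cons = []
    for p in range(P):
        bases = [s[p] for s in seqs if p < len(s)]
        if len(bases) * 2 < len(seqs):
            break  # fewer than half the members reach this position
        counts = {b: bases.count(b) for b in set(bases)}
        best = max(counts.items(), key=lambda kv: (kv[1], -_BASE_ORDER.index(kv[0])))
        cons.append(best[0])
    return RnaSequence(f"{family_id}-consensus", "".join(cons))


def _deviates_ungapped(seq: str, cons: str, P: int) -> list[bool]:
    return [
        (p >= len(seq)) != (p >= len(cons)) or
        (p < len(seq) and p < len(cons) and seq[p] != cons[p])
        for p in range(P)
    ]


def _deviates_gapped(seq: str, cons: str, P: int) -> list[bool]:
    """Single-gap realignment: if lengths differ by exactly 1, try every gap
    placement in the shorter string and keep the one minimizing mismatches;
    the gap registers one deviation at its position."""
    if abs(len(seq) - len(cons)) != 1:
        return _deviates_ungapped(seq, cons, P)
    short, long_ = (seq, cons) if len(seq) < len(cons) else (cons, seq)
    best_gap, best_mm = None, None
    for g in range(len(long_)):
        gapped = short[:g] + "-" + short[g:]
        mm = sum(1 for a, b in zip(gapped, long_) if a != b and a != "-")
        if best_mm is None or mm < best_mm:
            best_gap, best_mm = g, mm
    dev = [False] * P
    gapped = short[:best_gap] + "-" + short[best_gap:]
    for p, (a, b) in enumerate(zip(gapped, long_)):
        if p < P and (a == "-" or a != b):
            dev[p] = True
    return dev


def family_profile(
    family_id: str,
    members: Sequence[MatureMiRNA | RnaSequence | str],
    gapped: bool = False,
    count_mode: str = "position",
) -> FamilyProfile:
    """Deviation counts d_p and normalized v_p = d_p / n for one family.

    ``count_mode="position"`` counts every deviating position of every
    member; ``"sequence"`` counts each deviating member once, at its first
    deviating position.
    """
    if count_mode not in ("position", "sequence"):
        raise ValueError("count_mode must be 'position' or 'sequence'")
    seqs = _seqs(members)
    cons = family_consensus(members, family_id)
    P = max(max((len(s) for s in seqs), default=0), len(cons.seq))
    d = [0] * P
    for s in seqs:
        dev = (_deviates_gapped if gapped else _deviates_ungapped)(s, cons.seq, P)
        if count_mode == "sequence":
            first = next((p for p, x in enumerate(dev) if x), None)
            dev = [p == first for p in range(P)]
        for p, x in enumerate(dev):
            d[p] += x
    n = len(seqs)
    return FamilyProfile(family_id, n, cons, tuple(d), tuple(x / n for x in d))


def variation_profile(
    families: Mapping[str, Sequence[MatureMiRNA]] | Sequence[Sequence[MatureMiRNA]],
    gapped: bool = False,
    count_mode: str = "position",
) -> VariationSummary:
    """Profiles for every family, normalized so each contributes equally."""
    if isinstance(families, Mapping):
        items = list(families.items())
    else:
        items = []
        for fam in families:
            fam = list(fam)
            fam_id = fam[0].family if isinstance(fam[0], MatureMiRNA) else "family"
            items.append((fam_id, fam))
    profiles = [family_profile(fid, members, gapped=gapped, count_mode=count_mode)
                for fid, members in items]
    return VariationSummary(tuple(profiles))


def merge_families(
    families: Mapping[str, Sequence[MatureMiRNA]],
    merge_spec: Mapping[str, str],
    gapped: bool = False,
    count_mode: str = "position",
) -> VariationSummary:
    """Pool families mapped to a common id in ``merge_spec`` and recompute.

    Deviations are recomputed from the pooled membership (never averaged).
    Merging families of different canonical lengths proceeds under 5'
    anchoring with a warning.
    """
    pooled: dict[str, list[MatureMiRNA]] = {}
    for fid, members in families.items():
        target = merge_spec.get(fid, fid)
        pooled.setdefault(target, []).extend(members)
    for fid, members in pooled.items():
        lengths = {len(m.seq.seq if isinstance(m, MatureMiRNA) else m) for m in members}
        if len(lengths) > 1:
            logger.warning("merged family %s mixes lengths %s; using 5' anchoring",
                           fid, sorted(lengths))
    return variation_profile(pooled, gapped=gapped, count_mode=count_mode)


def summary_to_tsv(summary: VariationSummary, path: str | Path) -> None:
    import pandas as pd

    P = summary.n_positions
    data = {"position": list(range(1, P + 1)),
            "V": [round(v, 6) for v in summary.totals]}
    for prof in summary.profiles:
        col = list(prof.normalized) + [0.0] * (P - len(prof.normalized))
        data[prof.family_id] = [round(v, 6) for v in col]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
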