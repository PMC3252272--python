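"""Scan spliced transcripts for miRNA target sites.

Every window of length |miRNA| ± 3 at every offset is aligned; windows whose
optimal penalty is at or below the score cap are reported, overlapping
windows are merged to the best-scoring one, and each site carries its
junction flag and the predicted cleavage coordinate (the target base paired
to miRNA position 10; AGO cleaves between the bases paired to positions 10
and 11).  Transcripts are mRNAs in sense orientation; the aligner handles
the antiparallel geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .duplex import (
    DEFAULT_SCORING,
    DuplexAlignment,
    PairState,
    ScoringParams,
    align_duplex,
    min_penalty_capped,
    render_duplex,
)
from .seqio import MatureMiRNA, RnaSequence, TranscriptModel

__all__ = ["TargetSite", "search_targets", "map_cleavage_site", "sites_to_tsv"]


@dataclass(frozen=True)
class TargetSite:
    """A scored site on a spliced transcript (1-based inclusive coordinates)."""

    transcript_id: str
    start: int
    end: int
    alignment: DuplexAlignment
    spans_junction: bool
    cleavage_coord: int | None

    @property
    def score(self) -> float:
        return self.alignment.score


def map_cleavage_site(site: "TargetSite") -> int:
    """Spliced 1-based coordinate of the target base opposite miRNA position 10.

    Bulged target bases shift the coordinate relative to the miRNA 5' anchor;
    bulged miRNA bases do not (they consume no target base).  Raises if the
    alignment does not canonically pair miRNA positions 10 and 11 with no
    bulge between them.
    """
    cols = site.alignment.columns
    by_mir = {c.mir_index: c for c in cols if c.mir_index is not None}
    c10, c11 = by_mir.get(9), by_mir.get(10)
    paired = (PairState.WATSON_CRICK, PairState.GU_WOBBLE)
    if c10 is None or c11 is None or c10.state not in paired or c11.state not in paired:
        raise ValueError("miRNA positions 10-11 are not paired; site not cleavable")
    if c10.window_index - c11.window_index != 1:
        raise ValueError("bulge between miRNA positions 10 and 11; site not cleavable")
    return site.start + c10.window_index


def _alignment_to_site(
    transcript: TranscriptModel, aln: DuplexAlignment, start0: int
) -> TargetSite:
    """Wrap an alignment of transcript[start0:start0+L] into a TargetSite."""
    n = len(aln.target_window)
    start, end = start0 + 1, start0 + n  # 1-based inclusive
    spans = any(start0 < j < start0 + n for j in transcript.junctions)
    site = TargetSite(transcript.id, start, end, aln, spans, None)
    try:
        cleave = map_cleavage_site(site)
    except ValueError:
        cleave = None
    return TargetSite(transcript.id, start, end, aln, spans, cleave)


def search_targets(
    mirna: MatureMiRNA | RnaSequence | str,
    transcripts: Sequence[TranscriptModel],
    params: ScoringParams | None = None,
) -> list[TargetSite]:
    """Report the best-scoring site for every qualifying window cluster.

    Windows with optimal score <= ``params.max_score`` are collected per
    transcript; overlapping windows are merged keeping the minimum-score
    (ties: leftmost, then shortest) window.  Results are sorted by
    (transcript_id, start, score).
    """
    if not transcripts:
        raise ValueError("no transcripts to search")
    params = params or DEFAULT_SCORING
    mir_len = len(mirna.seq if hasattr(mirna, "seq") else str(mirna))
    sites: list[TargetSite] = []
    for tr in transcripts:
        seq = tr.spliced_seq.seq
        hits: list[TargetSite] = []
        for length in range(mir_len - 3, mir_len + 4):
            if length < 1 or length > len(seq):
                continue
            for start0 in range(0, len(seq) - length + 1):
                window = RnaSequence(
                    f"{tr.id}:{start0 + 1}-{start0 + length}",
                    seq[start0 : start0 + length],
                )
                if not math.isfinite(min_penalty_capped(mirna, window, params)):
                    continue
                aln = align_duplex(mirna, window, params)
                if aln.is_site and aln.score <= params.max_score + 1e-9:
                    hits.append(_alignment_to_site(tr, aln, start0))
        sites.extend(_merge_overlaps(hits))
    sites.sort(key=lambda s: (s.transcript_id, s.start, s.score))
    return sites


def _merge_overlaps(hits: list[TargetSite]) -> list[TargetSite]:
    """Cluster overlapping windows; keep min score, tie -> leftmost, shortest."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda s: (s.start, s.end))
    merged: list[list[TargetSite]] = [[hits[0]]]
    reach = hits[0].end
    for h in hits[1:]:
        if h.start <= reach:  # overlaps the current cluster
            merged[-1].append(h)
        else:
            merged.append([h])
        reach = max(reach, h.end)
    out = []
    for cluster in merged:
        out.append(min(cluster, key=lambda s: (s.score, s.start, s.end)))
    return out


def sites_to_tsv(sites: Iterable[TargetSite], path: str | Path) -> None:
    """Tab-separated site table ('.' for missing values)."""
    import pandas as pd

    rows = []
    for s in sites:
        mirna = s.alignment.mirna
        rows.append(
            {
                "mirna_id": getattr(mirna, "id", "mirna"),
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "score": s.score,
                "delta_g": round(s.alignment.delta_g, 2)
                if math.isfinite(s.alignment.delta_g) else ".",
                "spans_junction": s.spans_junction,
                "cleavage_coord": s.cleavage_coord if s.cleavage_coord else ".",
                "duplex_render": render_duplex(s.alignment).replace("\n", "\\n"),
            }
        )
    pd.DataFrame(
        rows,
        columns=["mirna_id", "transcript_id", "start", "end", "score", "delta_g",
                 "spans_junction", "cleavage_coord", "duplex_render"],
    ).to_csv(path, sep="\t", index=False)
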