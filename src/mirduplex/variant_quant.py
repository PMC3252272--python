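"""Relative abundance of miRNA sequence variants in small-RNA libraries.

Reads are matched to variants with an exact 5' end and a tolerant 3' end
(default +-2 nt), mirroring miRNA biology: the 5' region defines targeting
while sequencing reads of the same miRNA commonly differ in 3' length
(isomiRs).  A read consistent with several variants is split fractionally
between them by default (strict mode discards it); unmatched reads are
counted and reported, never silently assigned.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .seqio import MatureMiRNA, RnaSequence, normalize_rna

logger = logging.getLogger("mirduplex")

__all__ = [
    "VariantCount",
    "CountingResult",
    "count_variant_reads",
    "relative_abundance",
    "load_reads",
    "match_variants",
]

#: collapsed small-RNA FASTA dialect: ">id_xN" means the read occurs N times
_COLLAPSED = re.compile(r"_x(\d+)$")


@dataclass(frozen=True)
class VariantCount:
    variant_id: str
    library_id: str
    count: float          # fractional when ambiguous reads are split
    abundance: float      # in [0, 1]; 0 before normalization of an empty library


class CountingResult(list):
    """List of VariantCount plus library-level bookkeeping."""

    def __init__(self, counts: Iterable[VariantCount], n_reads: float,
                 n_unmatched: float, n_ambiguous: float):
        super().__init__(counts)
        self.n_reads = n_reads
        self.n_unmatched = n_unmatched
        self.n_ambiguous = n_ambiguous


def _variant_seq(v: MatureMiRNA | RnaSequence | str) -> str:
    if isinstance(v, MatureMiRNA):
        return v.seq.seq
    if isinstance(v, RnaSequence):
        return v.seq
    return normalize_rna(str(v))


def _variant_id(v, fallback: str) -> str:
    return getattr(v, "id", fallback)


def _matches(read: str, variant: str, trim_tol: int) -> bool:
    """Read == variant up to +-trim_tol bases at the 3' end, 5' ends exact."""
    if abs(len(read) - len(variant)) > trim_tol:
        return False
    k = min(len(read), len(variant))
    return read[:k] == variant[:k]


def match_variants(read: str, variants: Sequence[tuple[str, str]],
                   trim_tol: int) -> list[str]:
    """Ids of all variants the read is consistent with."""
    return [vid for vid, vseq in variants if _matches(read, vseq, trim_tol)]


def count_variant_reads(
    reads: Sequence[RnaSequence | str] | Sequence[tuple[str, int]],
    variants: Sequence[MatureMiRNA | RnaSequence | str],
    trim_tol: int = 2,
    library_id: str = "library",
    ambiguous: str = "split",
) -> CountingResult:
    """Count reads per variant in one library.

    ``reads`` may be plain sequences or (sequence, multiplicity) pairs (the
    collapsed-read dialect).  ``ambiguous="split"`` divides a multi-variant
    read equally among its matches; ``"strict"`` discards it.
    """
    if trim_tol < 0:
        raise ValueError("trim_tol must be >= 0")
    if ambiguous not in ("split", "strict"):
        raise ValueError("ambiguous must be 'split' or 'strict'")
    var_pairs = [(_variant_id(v, f"variant{i + 1}"), _variant_seq(v))
                 for i, v in enumerate(variants)]
    for i, (vid_a, seq_a) in enumerate(var_pairs):
        for vid_b, seq_b in var_pairs[i + 1:]:
            if _matches(seq_a, seq_b, trim_tol):
                raise ValueError(
                    f"variants {vid_a} and {vid_b} are indistinguishable "
                    f"under the matching rule (trim_tol={trim_tol})"
                )

    counts = {vid: 0.0 for vid, _ in var_pairs}
    n_reads = n_unmatched = n_ambiguous = 0.0
    for item in reads:
        if isinstance(item, tuple):
            seq, mult = normalize_rna(item[0]), float(item[1])
        elif isinstance(item, RnaSequence):
            seq, mult = item.seq, _multiplicity(item.id)
        else:
            seq, mult = normalize_rna(str(item)), 1.0
        n_reads += mult
        hits = match_variants(seq, var_pairs, trim_tol)
        if not hits:
            n_unmatched += mult
        elif len(hits) == 1:
            counts[hits[0]] += mult
        else:
            n_ambiguous += mult
            if ambiguous == "split":
                for vid in hits:
                    counts[vid] += mult / len(hits)
    if n_unmatched:
        logger.info("%s: %.0f of %.0f reads matched no variant",
                    library_id, n_unmatched, n_reads)
    result = CountingResult(
        (VariantCount(vid, library_id, c, 0.0) for vid, c in counts.items()),
        n_reads, n_unmatched, n_ambiguous,
    )
    return relative_abundance(result)


def relative_abundance(counts: Sequence[VariantCount]) -> CountingResult:
    """Normalize counts of one library to abundances summing to 1."""
    libs = {c.library_id for c in counts}
    if len(libs) > 1:
        raise ValueError(f"counts from multiple libraries: {sorted(libs)}")
    total = sum(c.count for c in counts)
    if total == 0:
        logger.warning("library %s has zero matched reads; abundances set to 0",
                       next(iter(libs), "?"))
    out = [
        VariantCount(c.variant_id, c.library_id, c.count,
                     c.count / total if total > 0 else 0.0)
        for c in counts
    ]
    meta = counts if isinstance(counts, CountingResult) else None
    return CountingResult(out,
                          meta.n_reads if meta else total,
                          meta.n_unmatched if meta else 0.0,
                          meta.n_ambiguous if meta else 0.0)


def _multiplicity(identifier: str) -> float:
    m = _COLLAPSED.search(identifier)
    return float(m.group(1)) if m else 1.0


def load_reads(path: str | Path) -> list[tuple[str, int]]:
    """Load FASTA or FASTQ reads as (sequence, multiplicity) pairs.

    FASTQ quality values are ignored; collapsed-FASTA "id_xN" headers are
    honored as multiplicities.  Format is chosen by extension (.fq/.fastq
    vs anything else).
    """
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        out.append((normalize_rna(str(rec.seq)), int(_multiplicity(rec.id))))
    return out


def counts_to_tsv(counts: Sequence[VariantCount], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"variant_id": c.variant_id, "library_id": c.library_id,
          "count": round(c.count, 3), "abundance": round(c.abundance, 6)}
         for c in counts]
    ).to_csv(path, sep="\t", index=False)
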