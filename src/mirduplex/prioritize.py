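"""Evidence funnel: intersect predicted sites with mutant up-regulation.

A predicted target is kept when its gene is up-regulated by at least the
fold threshold (default 30%, i.e. linear fold change >= 1.30, closed
threshold) in the required miRNA-pathway mutant genotypes.  The default
genotype set is the three biogenesis mutants {hyl1, se, dcl1} and the
default mode requires concordance across all of them.  This is a
deterministic threshold rule, not a hypothesis test; no multiple-testing
correction applies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import ExpressionMatrix
from .target_search import TargetSite

logger = logging.getLogger("mirduplex")

DEFAULT_GENOTYPES = ("hyl1", "se", "dcl1")

__all__ = ["PrioritizedTarget", "filter_by_expression", "DEFAULT_GENOTYPES"]


@dataclass(frozen=True)
class PrioritizedTarget:
    gene_id: str
    sites: tuple[TargetSite, ...]
    per_genotype_fc: dict[str, float]
    passes: bool
    evidence_summary: str

    @property
    def min_fold(self) -> float:
        return min(self.per_genotype_fc.values()) if self.per_genotype_fc else math.nan


def filter_by_expression(
    sites: Sequence[TargetSite],
    expr: ExpressionMatrix,
    genotypes: Sequence[str] = DEFAULT_GENOTYPES,
    min_fold: float = 1.30,
    mode: str = "all",
) -> list[PrioritizedTarget]:
    """One record per gene; ``passes`` is True iff fold change >= ``min_fold``
    in every (mode="all") or any (mode="any") listed genotype.

    Site genes absent from the matrix are reported (``passes=False``, noted
    in the evidence summary and logged), never silently dropped.  Output is
    sorted by minimum per-genotype fold change, descending; genes without
    expression data sort last.
    """
    if mode not in ("all", "any"):
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    missing_genotypes = [g for g in genotypes if g not in expr.table.columns]
    if missing_genotypes:
        raise ValueError(f"genotype(s) absent from matrix: {', '.join(missing_genotypes)}")

    by_gene: dict[str, list[TargetSite]] = {}
    for s in sites:
        by_gene.setdefault(s.transcript_id, []).append(s)

    out: list[PrioritizedTarget] = []
    for gene, gene_sites in by_gene.items():
        if gene not in expr.table.index:
            logger.warning("gene %s has predicted sites but no expression data", gene)
            out.append(
                PrioritizedTarget(gene, tuple(gene_sites), {}, False,
                                  "absent from expression matrix")
            )
            continue
        fc = {g: float(expr.table.at[gene, g]) for g in genotypes}
        hits = {g: v >= min_fold for g, v in fc.items()}
        passes = all(hits.values()) if mode == "all" else any(hits.values())
        summary = "; ".join(
            f"{g}: {v:.2f}{'*' if hits[g] else ''}" for g, v in fc.items()
        )
        out.append(PrioritizedTarget(gene, tuple(gene_sites), fc, passes, summary))

    out.sort(key=lambda t: (-t.min_fold if not math.isnan(t.min_fold) else math.inf,
                            t.gene_id))
    return out


def prioritized_to_tsv(targets: Iterable[PrioritizedTarget], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for t in targets:
        row = {"gene_id": t.gene_id, "n_sites": len(t.sites), "passes": t.passes}
        row.update({g: round(v, 4) for g, v in t.per_genotype_fc.items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep=".")
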