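"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure the analysis assumes --
transcripts with planted target sites of controlled mismatch/wobble/bulge
architecture (optionally split across an exon junction), mutant-vs-wild-type
fold-change matrices in which true targets are up-regulated by a stated
factor, and small-RNA libraries drawn multinomially from stated variant
proportions with 3'-end length heterogeneity -- and returns a TruthTable
recording everything needed to verify downstream claims without
re-generation.  All randomness flows through an explicit seed; no global
RNG state is touched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .duplex import (
    DEFAULT_SCORING,
    PairState,
    ScoringParams,
    align_duplex,
    min_penalty_capped,
)
from .prioritize import DEFAULT_GENOTYPES
from .seqio import (
    ExpressionMatrix,
    MatureMiRNA,
    RnaSequence,
    TranscriptModel,
    build_transcript,
    write_fasta,
    write_gff3,
)
from .sequences import reverse_complement

__all__ = [
    "SiteSpec",
    "PlantedSite",
    "TruthTable",
    "gen_transcriptome",
    "gen_expression",
    "gen_library",
    "write_transcriptome",
]

_BASES = "ACGU"
_WC_PARTNER = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}


@dataclass(frozen=True)
class SiteSpec:
    """Architecture of one planted target site.

    ``bulge_position=(p, p+1)`` places a target-side bulge between the target
    bases pairing miRNA positions p and p+1, or (for a miRNA-side bulge)
    removes the target bases opposite miRNA positions p+1..p+len.
    ``junction_split=k`` puts an exon boundary after the k-th base of the
    site.  ``decoy`` marks a spec intended to score above the search cap.
    """

    mismatches: int = 0
    wobbles: int = 0
    bulge: str = "none"  # none | target | mirna
    bulge_len: int = 1
    bulge_position: tuple[int, int] = (7, 8)
    junction_split: int | None = None
    decoy: bool = False

    def expected_score(self, params: ScoringParams = DEFAULT_SCORING) -> float:
        s = (self.mismatches * params.mismatch_penalty
             + self.wobbles * params.wobble_penalty)
        if self.bulge != "none":
            s += self.bulge_len * params.bulge_penalty_per_nt
        return s


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    start: int                 # 1-based inclusive spliced coordinates
    end: int
    score: float
    spans_junction: bool
    cleavage_coord: int | None
    bulge_positions: tuple[tuple[str, int], ...]
    spec: SiteSpec


@dataclass
class TruthTable:
    """Planted ground truth for one generated data set."""

    kind: str
    seed: int
    data: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(
            {"kind": self.kind, "seed": self.seed, "data": self.data},
            indent=1, default=default))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _build_site(mir: str, spec: SiteSpec, rng: np.random.Generator,
                params: ScoringParams) -> str | None:
    """One attempt at a site sequence realizing ``spec``; None if the draw
    produced an architecture the aligner resolves differently."""
    m = len(mir)
    partners = {p: _WC_PARTNER[mir[p - 1]] for p in range(1, m + 1)}  # miRNA pos -> target base
    protected = {1, 2, 10, 11, m}
    if spec.bulge != "none":
        protected |= {spec.bulge_position[0], spec.bulge_position[1]}

    free = [p for p in range(1, m + 1) if p not in protected]
    wobble_ok = [p for p in free if mir[p - 1] in _WOBBLE_PARTNER]
    if spec.mismatches + spec.wobbles > len(free) or spec.wobbles > len(wobble_ok):
        raise ValueError("spec wants more modified positions than available")
    wob = list(rng.choice(wobble_ok, size=spec.wobbles, replace=False)) if spec.wobbles else []
    rest = [p for p in free if p not in wob]
    mm = list(rng.choice(rest, size=spec.mismatches, replace=False)) if spec.mismatches else []

    for p in wob:
        partners[p] = _WOBBLE_PARTNER[mir[p - 1]]
    for p in mm:
        x = mir[p - 1]
        banned = {_WC_PARTNER[x], _WOBBLE_PARTNER.get(x, "")}
        choices = [b for b in _BASES if b not in banned]
        partners[p] = choices[rng.integers(0, len(choices))]

    # assemble target 3'->5' along miRNA 5'->3', then reverse into sense strand
    three_to_five = []
    for p in range(1, m + 1):
        if (spec.bulge == "mirna"
                and spec.bulge_position[0] < p <= spec.bulge_position[0] + spec.bulge_len):
            continue  # these miRNA bases get no partner (miRNA-side bulge)
        three_to_five.append(partners[p])
        if spec.bulge == "target" and p == spec.bulge_position[0]:
            for _ in range(spec.bulge_len):
                x_prev, x_next = mir[p - 1], mir[p]
                banned = {_WC_PARTNER[x_prev], _WOBBLE_PARTNER.get(x_prev, ""),
                          _WC_PARTNER[x_next], _WOBBLE_PARTNER.get(x_next, "")}
                choices = [b for b in _BASES if b not in banned] or list(_BASES)
                three_to_five.append(choices[rng.integers(0, len(choices))])
    return "".join(reversed(three_to_five))


def gen_transcriptome(
    mirna: MatureMiRNA | RnaSequence | str,
    n_transcripts: int,
    site_specs: Sequence[SiteSpec],
    seed: int,
    transcript_length: int = 300,
    params: ScoringParams | None = None,
) -> tuple[list[TranscriptModel], TruthTable]:
    """Uniform-background transcripts with sites planted per spec.

    Spec k is planted in transcript k (one per transcript; extra transcripts
    carry no site).  Every planted site is verified against the aligner at
    generation time: non-decoy sites must realize their closed-form score,
    decoys must leave no window at or below the cap anywhere around them.
    """
    params = params or DEFAULT_SCORING
    mir = mirna.seq.seq if isinstance(mirna, MatureMiRNA) else (
        mirna.seq if isinstance(mirna, RnaSequence) else str(mirna))
    if len(site_specs) > n_transcripts:
        raise ValueError("more site specs than transcripts")
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptModel] = []
    planted: list[PlantedSite] = []

    for k in range(n_transcripts):
        tid = f"tx{k + 1:03d}"
        spec = site_specs[k] if k < len(site_specs) else None
        if spec is None:
            transcripts.append(build_transcript(tid, [_random_rna(rng, transcript_length)]))
            continue
        for _attempt in range(200):
            site = _build_site(mir, spec, rng, params)
            L = len(site)
            offset = int(rng.integers(10, transcript_length - L - 10))
            background = _random_rna(rng, transcript_length)
            seq = background[:offset] + site + background[offset + L:]
            region = seq[max(0, offset - L): offset + 2 * L]
            if spec.decoy:
                if _region_clean(mir, region, params):
                    break
            else:
                aln = align_duplex(mir, RnaSequence("w", site), params)
                if (aln.is_site and abs(aln.score - spec.expected_score(params)) < 1e-9
                        and _region_unique(mir, seq, offset, L, params, aln.score)):
                    break
        else:
            raise ValueError(f"could not realize site spec {spec} after 200 attempts")

        if spec.junction_split is not None:
            if not 1 <= spec.junction_split < L:
                raise ValueError("junction_split outside site bounds")
            cut = offset + spec.junction_split
            model = build_transcript(tid, [seq[:cut], seq[cut:]])
        else:
            model = build_transcript(tid, [seq])
        transcripts.append(model)

        if spec.decoy:
            continue
        cleave = None
        by_mir = {c.mir_index: c for c in aln.columns if c.mir_index is not None}
        c10 = by_mir.get(9)
        if c10 is not None and c10.state in (PairState.WATSON_CRICK, PairState.GU_WOBBLE):
            cleave = offset + 1 + c10.window_index
        spans = (spec.junction_split is not None
                 and 0 < spec.junction_split < L)
        planted.append(PlantedSite(
            tid, offset + 1, offset + L, aln.score, spans, cleave,
            tuple(aln.bulge_positions()), spec))

    truth = TruthTable("transcriptome", seed, {
        "mirna": mir,
        "sites": planted,
        "n_transcripts": n_transcripts,
        "transcript_length": transcript_length,
    })
    return transcripts, truth


def _region_unique(mir: str, seq: str, offset: int, L: int,
                   params: ScoringParams, site_score: float) -> bool:
    """No window overlapping the planted one beats or ties it elsewhere."""
    m = len(mir)
    for length in range(m - 3, m + 4):
        for s in range(max(0, offset - length + 1), min(len(seq) - length, offset + L) + 1):
            if s == offset and length == L:
                continue
            window = seq[s: s + length]
            val = min_penalty_capped(mir, RnaSequence("w", window), params)
            if val <= site_score + 1e-9:
                return False
    return True


def _region_clean(mir: str, region: str, params: ScoringParams) -> bool:
    """No window in the region scores at or below the cap (decoy check)."""
    m = len(mir)
    for length in range(m - 3, m + 4):
        for s in range(0, len(region) - length + 1):
            window = region[s: s + length]
            if np.isfinite(min_penalty_capped(mir, RnaSequence("w", window), params)):
                return False
    return True


def gen_expression(
    genes: Sequence[str],
    true_targets: Sequence[str],
    fold_range: tuple[float, float] = (1.3, 2.0),
    noise_sd: float = 0.05,
    genotypes: Sequence[str] = DEFAULT_GENOTYPES,
    seed: int = 0,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Mutant/wild-type fold-change matrix with planted true targets.

    True targets draw a base fold uniformly from ``fold_range`` and a
    multiplicative lognormal noise factor per genotype; the draw is repeated
    (seeded rejection) until the realized fold change lies inside
    ``fold_range``, so a planted true target *is* a gene up-regulated by at
    least the stated factor in every genotype -- matching how true targets
    are defined by the expression screen itself.  All other genes get pure
    lognormal noise around 1.
    """
    import pandas as pd

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = fold_range
    if not 1.0 < lo <= hi:
        raise ValueError("fold_range must lie above 1")
    unknown = set(true_targets) - set(genes)
    if unknown:
        raise ValueError(f"true targets not in gene list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    truth_folds: dict[str, dict[str, float]] = {}
    rows = []
    for gene in genes:
        if gene in set(true_targets):
            base = rng.uniform(lo, hi)
            fcs = {}
            for g in genotypes:
                fc = base * rng.lognormal(0.0, noise_sd) if noise_sd > 0 else base
                while not (lo <= fc <= hi):
                    fc = base * rng.lognormal(0.0, noise_sd)
                fcs[g] = fc
            truth_folds[gene] = fcs
            rows.append([fcs[g] for g in genotypes])
        else:
            rows.append([rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
                        for _ in genotypes])
    table = pd.DataFrame(rows, index=list(genes), columns=list(genotypes))
    truth = TruthTable("expression", seed, {
        "true_targets": list(true_targets),
        "fold_range": list(fold_range),
        "noise_sd": noise_sd,
        "folds": truth_folds,
    })
    return ExpressionMatrix(table), truth


def gen_library(
    variants: Sequence[MatureMiRNA | RnaSequence | str],
    proportions: Sequence[float],
    depth: int,
    trim_profile: Mapping[int, float] | None = None,
    seed: int = 0,
    library_id: str = "library",
) -> tuple[list[RnaSequence], TruthTable]:
    """Multinomial small-RNA library with 3'-end length heterogeneity.

    ``trim_profile`` maps a 3' offset (negative = truncation, positive =
    templated-length extension with random bases) to its probability.
    """
    props = np.asarray(proportions, dtype=float)
    if (props < 0).any():
        raise ValueError("negative proportion")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(props) != len(variants):
        raise ValueError("one proportion per variant required")
    trim_profile = trim_profile if trim_profile is not None else {0: 1.0}
    offsets = sorted(trim_profile)
    probs = np.asarray([trim_profile[o] for o in offsets], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("trim_profile probabilities must sum to 1")

    rng = np.random.default_rng(seed)
    seqs = []
    for v in variants:
        seqs.append(v.seq.seq if isinstance(v, MatureMiRNA)
                    else (v.seq if isinstance(v, RnaSequence) else str(v)))
    draws = rng.multinomial(depth, props)
    reads: list[RnaSequence] = []
    k = 0
    for vi, n in enumerate(draws):
        offs = rng.choice(offsets, size=n, p=probs) if n else []
        for o in offs:
            k += 1
            s = seqs[vi]
            o = int(o)
            if o < 0:
                s = s[:o]
            elif o > 0:
                s = s + _random_rna(rng, o)
            reads.append(RnaSequence(f"read{k:06d}_x1", s))
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    truth = TruthTable("library", seed, {
        "library_id": library_id,
        "variant_ids": [getattr(v, "id", f"variant{i + 1}")
                        for i, v in enumerate(variants)],
        "proportions": props.tolist(),
        "draws": draws.tolist(),
        "depth": depth,
        "trim_profile": {str(o): trim_profile[o] for o in offsets},
    })
    return reads, truth


def write_transcriptome(
    transcripts: Sequence[TranscriptModel],
    truth: TruthTable,
    out_dir: str | Path,
    seed: int = 0,
    intron_length: int = 40,
) -> dict[str, Path]:
    """Write spliced FASTA plus, when any transcript is multi-exon, a toy
    genome FASTA and GFF3 (plus strand, exons separated by random introns)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"transcripts": out / "transcripts.fa", "truth": out / "truth.json"}
    write_fasta([t.spliced_seq for t in transcripts], paths["transcripts"])
    truth.to_json(paths["truth"])

    if any(len(t.exon_lengths) > 1 for t in transcripts):
        rng = np.random.default_rng(seed)
        contigs, features = [], []
        for t in transcripts:
            pieces, pos, bounds = [], 0, []
            for i, L in enumerate(t.exon_lengths):
                start = pos + 1
                spliced_off = sum(t.exon_lengths[:i])
                pieces.append(t.spliced_seq.seq[spliced_off: spliced_off + L])
                pos += L
                bounds.append((start, pos))
                if i < len(t.exon_lengths) - 1:
                    pieces.append(_random_rna(rng, intron_length))
                    pos += intron_length
            contigs.append(RnaSequence(f"chr_{t.id}", "".join(pieces)))
            for start, end in bounds:
                features.append((f"chr_{t.id}", t.id, start, end, "+", "mirduplex"))
        paths["genome"] = out / "genome.fa"
        paths["gff"] = out / "exons.gff3"
        write_fasta(contigs, paths["genome"])
        write_gff3(features, paths["gff"])
    return paths
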