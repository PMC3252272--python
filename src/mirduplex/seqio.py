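"""Sequence and table I/O plus spliced-transcript bookkeeping.

All sequences are normalized on input to uppercase RNA (T becomes U), so DNA
sources (ESTs, genomes) can be fed anywhere RNA is expected.  Coordinates are
0-based half-open internally; everything user-facing (GFF3, reported target
sites, cleavage positions) is 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .sequences import reverse_complement

logger = logging.getLogger("mirduplex")

_RNA_ALPHABET = frozenset("ACGU")


class FastaParseError(ValueError):
    """Raised for malformed FASTA/GFF records."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U; reject anything outside {A,C,G,U}."""
    s = str(seq).upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise FastaParseError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return s


@dataclass(frozen=True)
class RnaSequence:
    """A named 5'->3' RNA sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "seq", normalize_rna(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA with miRBase-style species/family annotation."""

    id: str
    species: str
    family: str
    seq: RnaSequence

    def __post_init__(self) -> None:
        if not 19 <= len(self.seq) <= 24:
            raise ValueError(
                f"{self.id}: mature miRNA length {len(self.seq)} outside [19, 24]"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript and the spliced coordinates of its exon junctions.

    ``junctions`` holds 0-based spliced positions *after which* an exon
    boundary falls, i.e. the cumulative sums of all but the last exon length.
    """

    id: str
    spliced_seq: RnaSequence
    exon_lengths: tuple[int, ...]
    junctions: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.exon_lengths):
            raise ValueError(f"{self.id}: exon lengths must be positive")
        if sum(self.exon_lengths) != len(self.spliced_seq):
            raise ValueError(
                f"{self.id}: exon lengths sum to {sum(self.exon_lengths)}, "
                f"spliced sequence is {len(self.spliced_seq)} nt"
            )
        cum = 0
        junctions = []
        for l in self.exon_lengths[:-1]:
            cum += l
            junctions.append(cum)
        object.__setattr__(self, "junctions", frozenset(junctions))


@dataclass
class ExpressionMatrix:
    """Linear-scale mutant/wild-type fold changes, genes x genotypes."""

    table: pd.DataFrame  # index: gene ids, columns: genotype ids

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.table.columns.duplicated().any():
            raise ValueError("duplicate genotype ids in expression matrix")
        if (self.table.to_numpy() <= 0).any():
            raise ValueError("fold changes must be positive (linear scale)")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def genotypes(self) -> list[str]:
        return list(self.table.columns)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into normalized RNA records (order preserved)."""
    records: list[RnaSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            records.append(RnaSequence(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise FastaParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(records: Iterable[RnaSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# miRBase mature dialect
# ---------------------------------------------------------------------------

#: e.g. "ath-miR396a", "osa-miR396e-5p", "ath-MIR159b"
_MIR_ID = re.compile(
    r"^(?P<species>[a-z]{3})-(?P<fam>mir|miR|MIR)(?P<num>\d+)(?P<rest>[a-z]*(?:[-._].*)?)$",
    re.IGNORECASE,
)


def parse_mirbase_id(identifier: str) -> tuple[str, str] | None:
    """Split a miRBase id into (species, family).

    The family is the numeric token ("miR396" from "osa-miR396e-5p"); lettered
    paralog suffixes and -3p/-5p arm tags are stripped, matching how families
    are grouped for variation profiling.
    """
    m = _MIR_ID.match(identifier)
    if not m:
        return None
    return m.group("species").lower(), f"miR{m.group('num')}"


def read_mirbase_mature(path: str | Path) -> list[MatureMiRNA]:
    """Read a miRBase "mature" FASTA; records without a miR token are skipped."""
    out: list[MatureMiRNA] = []
    skipped = 0
    for rec in read_fasta(path):
        parsed = parse_mirbase_id(rec.id)
        if parsed is None:
            skipped += 1
            logger.warning("skipping record %r: no miR/MIR family token", rec.id)
            continue
        species, family = parsed
        out.append(MatureMiRNA(rec.id, species, family, rec))
    if skipped:
        logger.warning("%d record(s) skipped while reading %s", skipped, path)
    return out


def group_by_family(mirnas: Sequence[MatureMiRNA]) -> dict[str, list[MatureMiRNA]]:
    """Partition mature miRNAs into families (insertion order preserved)."""
    families: dict[str, list[MatureMiRNA]] = {}
    for m in mirnas:
        families.setdefault(m.family, []).append(m)
    return families


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------

def build_transcript(transcript_id: str, exon_seqs: Sequence[RnaSequence | str]) -> TranscriptModel:
    """Concatenate exon sequences into a spliced transcript with junctions."""
    if not exon_seqs:
        raise ValueError("at least one exon required")
    seqs = [e.seq if isinstance(e, RnaSequence) else normalize_rna(e) for e in exon_seqs]
    if any(not s for s in seqs):
        raise ValueError("empty exon")
    spliced = RnaSequence(transcript_id, "".join(seqs))
    return TranscriptModel(transcript_id, spliced, tuple(len(s) for s in seqs))


def read_gff3_exons(gff_path: str | Path, fasta_path: str | Path) -> list[TranscriptModel]:
    """Build spliced transcript models from GFF3 exon features plus a genome FASTA.

    Exons must carry a ``Parent`` transcript id; coordinates are 1-based
    inclusive.  Minus-strand transcripts are reverse complemented and their
    exons ordered in transcription order.
    """
    import gffutils

    genome = {rec.id: rec.seq for rec in read_fasta(fasta_path)}
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_parent: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent")
        if not parents:
            raise FastaParseError(f"exon at {feat.seqid}:{feat.start}-{feat.end} has no Parent")
        for parent in parents:
            by_parent.setdefault(parent, []).append(feat)

    models: list[TranscriptModel] = []
    for tid in sorted(by_parent):
        exons = by_parent[tid]
        strands = {e.strand for e in exons}
        if len(strands) > 1:
            raise FastaParseError(f"transcript {tid}: exons on mixed strands")
        strand = strands.pop()
        exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
        pieces: list[str] = []
        for e in exons:
            contig = genome.get(e.seqid)
            if contig is None:
                raise FastaParseError(f"transcript {tid}: contig {e.seqid!r} not in FASTA")
            if e.start < 1 or e.end > len(contig):
                raise FastaParseError(
                    f"transcript {tid}: exon {e.start}-{e.end} outside contig "
                    f"{e.seqid} (length {len(contig)})"
                )
            piece = contig[e.start - 1 : e.end]
            if strand == "-":
                piece = reverse_complement(piece)
            pieces.append(piece)
        models.append(build_transcript(tid, pieces))
    return models


def write_gff3(
    exons: Iterable[tuple[str, str, int, int, str, str]], path: str | Path
) -> None:
    """Write exon features; tuples are (seqid, transcript_id, start, end, strand, source)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, tid, start, end, strand, source in exons:
            fh.write(
                f"{seqid}\t{source}\texon\t{start}\t{end}\t.\t{strand}\t.\tParent={tid}\n"
            )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """TSV with a header row; column 1 = gene id, remaining columns = genotypes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return ExpressionMatrix(df.astype(float))


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.table.to_csv(path, sep="\t", index_label="gene")
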