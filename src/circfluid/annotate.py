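"""Gene assignment and genomic-feature classification of junctions.

Each junction is assigned every gene whose transcript interval overlaps it
by at least one base, then classified against one chosen transcript into a
single structural class:

``multi_exon_spanning_intron``
    the junction intersects two or more exons (hence contains an intron) —
    the canonical exonic circRNA;
``single_exon``
    both junction boundaries fall within one exon;
``intronic``
    the junction lies entirely within one intron (lariat-derived circles);
``boundary_outside_exon``
    a gene overlaps but at least one boundary falls in no exon of the
    chosen transcript;
``intergenic``
    no transcript overlaps.

UTR flags (``five_prime_utr`` / ``three_prime_utr``) are added when the
junction interval intersects the transcript region outside the CDS on the
corresponding side, following transcript strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io import TranscriptModel
from .junctions import BackspliceJunction

__all__ = [
    "FeatureAnnotation",
    "TranscriptIndex",
    "assign_genes",
    "classify",
    "annotate_junctions",
]

PRIMARY_CLASSES = (
    "multi_exon_spanning_intron",
    "single_exon",
    "intronic",
    "boundary_outside_exon",
    "intergenic",
)


@dataclass
class FeatureAnnotation:
    junction_key: str
    genes: list[str]
    chosen_transcript: str | None
    n_exons_spanned: int
    classes: set[str] = field(default_factory=set)

    @property
    def primary_class(self) -> str:
        for c in PRIMARY_CLASSES:
            if c in self.classes:
                return c
        raise ValueError(f"{self.junction_key}: no primary class assigned")


class TranscriptIndex:
    """Interval-tree index of transcripts for overlap queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        for tx in transcripts:
            self._trees.setdefault(tx.chrom, IntervalTree()).addi(
                tx.tx_start0, tx.tx_end0, tx
            )

    def overlapping(self, j: BackspliceJunction) -> list[TranscriptModel]:
        tree = self._trees.get(j.chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(j.start0, j.end0)),
            key=lambda tx: tx.name,
        )


def assign_genes(
    junction: BackspliceJunction,
    transcripts: TranscriptIndex | Sequence[TranscriptModel],
) -> list[str]:
    """Names of genes whose transcript overlaps the junction by >= 1 bp."""
    if not isinstance(transcripts, TranscriptIndex):
        transcripts = TranscriptIndex(transcripts)
    return sorted({tx.name for tx in transcripts.overlapping(junction)})


def _in_exon(pos: int, exons: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in exons)


def _exons_spanned(j: BackspliceJunction, exons: list[tuple[int, int]]) -> int:
    return sum(1 for s, e in exons if s < j.end0 and e > j.start0)


def classify(
    junction: BackspliceJunction,
    transcripts: TranscriptIndex | Sequence[TranscriptModel],
) -> FeatureAnnotation:
    """Classify one junction against the overlapping transcript models.

    When several transcripts overlap, the one whose exons best explain the
    junction is chosen: prefer both boundaries landing in exons, then the
    most exons spanned, then the lexicographically smallest name.
    """
    if not isinstance(transcripts, TranscriptIndex):
        transcripts = TranscriptIndex(transcripts)
    overlapping = transcripts.overlapping(junction)
    genes = sorted({tx.name for tx in overlapping})
    if not overlapping:
        return FeatureAnnotation(
            junction.key, [], None, 0, {"intergenic"}
        )

    b1 = junction.start0          # first base of the circle
    b2 = junction.end0 - 1        # last base of the circle

    def score(tx: TranscriptModel):
        exons = tx.exons
        both = _in_exon(b1, exons) and _in_exon(b2, exons)
        return (not both, -_exons_spanned(junction, exons), tx.name)

    chosen = min(overlapping, key=score)
    exons = chosen.exons
    n_spanned = _exons_spanned(junction, exons)

    classes: set[str] = set()
    same_exon = any(s <= b1 and b2 < e for s, e in exons)
    within_intron = any(
        s <= junction.start0 and junction.end0 <= e for s, e in chosen.introns
    )
    if same_exon:
        classes.add("single_exon")
    elif n_spanned >= 2:
        classes.add("multi_exon_spanning_intron")
    elif within_intron:
        classes.add("intronic")
    else:
        # gene overlaps but the junction structure does not fit the exon
        # model: at least one boundary lies in no exon of the transcript
        classes.add("boundary_outside_exon")

    # UTR flags: junction intersects the transcript region outside the CDS
    if chosen.cds_start0 < chosen.cds_end0:
        left = junction.start0 < chosen.cds_start0
        right = junction.end0 > chosen.cds_end0
        if chosen.strand == "-":
            left, right = right, left
        if left:
            classes.add("five_prime_utr")
        if right:
            classes.add("three_prime_utr")

    return FeatureAnnotation(junction.key, genes, chosen.name, n_spanned, classes)


def annotate_junctions(
    junctions: Iterable[BackspliceJunction | str],
    transcripts: Sequence[TranscriptModel] | TranscriptIndex,
):
    """Classify many junctions; returns a list of :class:`FeatureAnnotation`."""
    index = (
        transcripts
        if isinstance(transcripts, TranscriptIndex)
        else TranscriptIndex(transcripts)
    )
    out = []
    for j in junctions:
        if isinstance(j, str):
            j = BackspliceJunction.from_key(j)
        out.append(classify(j, index))
    return out
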