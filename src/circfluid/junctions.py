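"""Canonical back-splice junction representation and coordinate arithmetic.

A circRNA is identified by its back-splice junction: the genomic interval
from the back-splice acceptor base (5' end of the circle) to the donor base
(3' end).  Internally every junction is held in 0-based, half-open (BED)
convention, so ``start0`` is the index of the first base of the circle and
``end0`` is one past the last base (equivalently, the 1-based index of the
donor base).  Caller outputs arrive in two dialect families: CIRCexplorer,
KNIFE and find_circ report 0-based coordinates, while CIRI2, MapSplice and
DCC report 1-based inclusive coordinates; :func:`normalize_coordinates`
folds both into the canonical form.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "BackspliceJunction",
    "CoordinateBasis",
    "CoordinateError",
    "LinearJunction",
    "TOOLS",
    "TOOL_BASIS",
    "normalize_chrom",
    "normalize_coordinates",
    "matches_five_prime_flank",
    "matches_three_prime_flank",
]

#: The six supported circRNA caller identifiers.
TOOLS = ("circexplorer", "ciri2", "dcc", "find_circ", "knife", "mapsplice")

STRANDS = ("+", "-", ".")


class CoordinateError(ValueError):
    """Raised for coordinates that cannot form a valid back-splice junction."""


class CoordinateBasis(str, enum.Enum):
    """Coordinate convention of a caller's native output."""

    zero_based = "zero_based"  # 0-based half-open, BED-style
    one_based = "one_based"    # 1-based fully closed


#: Native coordinate basis of each supported caller.
TOOL_BASIS: dict[str, CoordinateBasis] = {
    "circexplorer": CoordinateBasis.zero_based,
    "knife": CoordinateBasis.zero_based,
    "find_circ": CoordinateBasis.zero_based,
    "ciri2": CoordinateBasis.one_based,
    "mapsplice": CoordinateBasis.one_based,
    "dcc": CoordinateBasis.one_based,
}


@dataclass(frozen=True, order=True)
class BackspliceJunction:
    """A back-splice junction in canonical 0-based half-open coordinates.

    Attributes
    ----------
    chrom : str
        Chromosome name, normalized to the "chr"-prefixed dialect.
    start0 : int
        0-based index of the back-splice acceptor base (first base of the
        circRNA).
    end0 : int
        0-based half-open end; equals the 1-based index of the back-splice
        donor base (last base of the circRNA).
    strand : str
        One of ``+``, ``-`` or ``.`` (unknown).
    """

    chrom: str
    start0: int
    end0: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start0 < 0:
            raise CoordinateError(f"negative start coordinate: {self.start0}")
        if self.end0 <= self.start0:
            raise CoordinateError(
                f"end ({self.end0}) must exceed start ({self.start0})"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> str:
        """Unique stranded key, ``chrom:start0-end0:strand``."""
        return f"{self.chrom}:{self.start0}-{self.end0}:{self.strand}"

    @property
    def unstranded_key(self) -> str:
        """Key ignoring strand, ``chrom:start0-end0``."""
        return f"{self.chrom}:{self.start0}-{self.end0}"

    def key_for(self, strand_aware: bool) -> str:
        return self.key if strand_aware else self.unstranded_key

    @property
    def span(self) -> int:
        """Genomic span of the circle in bases."""
        return self.end0 - self.start0

    def to_bed6(self, score: int | float = 0) -> str:
        """Serialize as a BED6 line (name = the stranded key)."""
        return "\t".join(
            (self.chrom, str(self.start0), str(self.end0), self.key,
             str(score), self.strand)
        )

    @classmethod
    def from_key(cls, key: str) -> "BackspliceJunction":
        """Inverse of :attr:`key` (accepts stranded and unstranded keys)."""
        parts = key.split(":")
        if len(parts) == 2:
            chrom, span = parts
            strand = "."
        elif len(parts) == 3:
            chrom, span, strand = parts
        else:
            raise CoordinateError(f"malformed junction key {key!r}")
        start, _, end = span.partition("-")
        return cls(chrom, int(start), int(end), strand)


@dataclass(frozen=True)
class LinearJunction:
    """A linear (forward) splice junction, STAR SJ.out.tab convention.

    ``intron_start1`` / ``intron_end1`` are the 1-based first and last
    intronic bases; ``unique_reads`` counts uniquely-mapping spliced reads.
    """

    chrom: str
    intron_start1: int
    intron_end1: int
    unique_reads: int

    def __post_init__(self) -> None:
        if self.intron_end1 < self.intron_start1:
            raise CoordinateError(
                f"intron end {self.intron_end1} < start {self.intron_start1}"
            )
        if self.unique_reads < 0:
            raise CoordinateError("negative unique_reads")


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name to the chr-prefixed (UCSC) dialect."""
    chrom = chrom.strip()
    if not chrom:
        raise CoordinateError("empty chromosome name")
    if chrom == "MT":
        return "chrM"
    return chrom if chrom.startswith("chr") else "chr" + chrom


def normalize_coordinates(
    chrom: str,
    start_in: int,
    end_in: int,
    strand: str,
    basis: CoordinateBasis,
) -> BackspliceJunction:
    """Convert caller-native coordinates to a canonical junction.

    For a 1-based inclusive pair ``[s, e]`` the canonical form is
    ``(s - 1, e)``; 0-based half-open input passes through unchanged.
    The two coordinates must already be in (acceptor, donor) order, i.e.
    numerically ascending — readers reorder donor-first records before
    calling this.
    """
    basis = CoordinateBasis(basis)
    if start_in > end_in:
        raise CoordinateError(
            f"start {start_in} > end {end_in} (reorder before normalizing)"
        )
    if basis is CoordinateBasis.one_based:
        if start_in < 1:
            raise CoordinateError(
                f"non-positive 1-based start coordinate: {start_in}"
            )
        start0, end0 = start_in - 1, end_in
    else:
        start0, end0 = start_in, end_in
    if end0 - start0 < 2:
        # a back-splice joins two distinct bases (donor != acceptor): a
        # single-base circle is degenerate
        raise CoordinateError(
            f"degenerate circle of span {end0 - start0} at "
            f"{chrom}:{start0}-{end0}"
        )
    if strand not in STRANDS:
        strand = "."
    return BackspliceJunction(normalize_chrom(chrom), start0, end0, strand)


def matches_five_prime_flank(j: BackspliceJunction, lj: LinearJunction) -> bool:
    """True if ``lj`` shares the circRNA's acceptor splice site.

    A linear intron ending at the base immediately before the circle
    (``intron_end1 == start0``, since intron_end1 is 1-based) uses the same
    3' splice site as the back-splice acceptor.
    """
    return lj.chrom == j.chrom and lj.intron_end1 == j.start0


def matches_three_prime_flank(j: BackspliceJunction, lj: LinearJunction) -> bool:
    """True if ``lj`` shares the circRNA's donor splice site.

    A linear intron starting at the base immediately after the circle
    (``intron_start1 - 1 == end0``) uses the same 5' splice site as the
    back-splice donor.
    """
    return lj.chrom == j.chrom and lj.intron_start1 - 1 == j.end0
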