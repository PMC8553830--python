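"""Readers for the six caller output dialects and the pipeline's side files.

Each caller writes its own tab-delimited layout; only the fields the
downstream analysis needs — chromosome, the two junction coordinates,
strand and the back-spliced read count — are interpreted, and remaining
columns are passed through opaquely in :attr:`ToolCall.extras`.

Dialect contracts
-----------------
circexplorer
    Headerless BED-like, 0-based; columns 1-3 chrom/start/end, column 6
    strand, column 13 readNumber.
ciri2
    Headered, 1-based inclusive; columns circRNA_ID, chr, circRNA_start,
    circRNA_end, junction_reads (col 5), ..., strand (col 11).
dcc (CircRNACount)
    Headered, 1-based; Chr, Start, End, Strand, then either one count
    column per sample (header = sample id) or a single count column.
find_circ
    BED-like, 0-based; columns 1-4 chrom/start/end/name, column 5 n_reads,
    column 6 strand; ``#``-prefixed header lines allowed.
knife
    Headered, 0-based; column 1 is the pipe-delimited junction string
    ``chrom|gene:pos|gene:pos|type|strand``, column 2 the read count.
mapsplice
    Headerless, 1-based; column 1 ``chrom~chrom``, columns 2-3 the (often
    donor-first) coordinate pair, column 5 coverage, column 6 two-character
    strand.

Records whose two coordinates arrive donor-first are reordered by numeric
value before basis normalization, so every reader yields coordinates in
(acceptor, donor) order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .junctions import (
    BackspliceJunction,
    CoordinateBasis,
    CoordinateError,
    LinearJunction,
    TOOL_BASIS,
    TOOLS,
    normalize_chrom,
    normalize_coordinates,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ToolCall",
    "SampleMeta",
    "TranscriptModel",
    "DialectError",
    "read_tool_output",
    "read_star_sj",
    "read_sample_table",
    "read_bed12",
    "read_junction_list",
    "write_junction_bed",
    "write_matrix",
    "read_matrix",
    "canonical_total_from_sj",
]


class DialectError(ValueError):
    """File does not conform to the declared dialect."""


@dataclass
class ToolCall:
    """One caller's report of one back-splice junction in one sample."""

    tool: str
    sample_id: str
    junction: BackspliceJunction
    count: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")
        if self.count < 0:
            raise ValueError("negative read count")


@dataclass
class SampleMeta:
    """Sample-level metadata plus the JRPM denominator components."""

    sample_id: str
    participant_id: str
    biofluid: str
    visit_index: int
    canonical_junction_reads: int
    chimeric_junction_reads: int

    @property
    def total_junction_reads(self) -> int:
        """Canonical + chimeric junction reads — the JRPM denominator."""
        return self.canonical_junction_reads + self.chimeric_junction_reads


@dataclass
class TranscriptModel:
    """A transcript with exon blocks and CDS bounds (BED12 semantics)."""

    chrom: str
    tx_start0: int
    tx_end0: int
    name: str
    strand: str
    cds_start0: int
    cds_end0: int
    block_sizes: tuple[int, ...]
    block_starts: tuple[int, ...]  # relative to tx_start0

    def __post_init__(self) -> None:
        if len(self.block_sizes) != len(self.block_starts) or not self.block_sizes:
            raise ValueError(f"{self.name}: inconsistent exon blocks")
        if self.block_starts[0] != 0:
            raise ValueError(f"{self.name}: first block must start at tx_start")
        for i in range(1, len(self.block_starts)):
            if self.block_starts[i] < self.block_starts[i - 1] + self.block_sizes[i - 1]:
                raise ValueError(f"{self.name}: exon blocks overlap or unsorted")
        last_end = self.tx_start0 + self.block_starts[-1] + self.block_sizes[-1]
        if last_end != self.tx_end0:
            raise ValueError(f"{self.name}: last block must end at tx_end")

    @property
    def exons(self) -> list[tuple[int, int]]:
        """Absolute 0-based half-open exon intervals, sorted."""
        return [
            (self.tx_start0 + rel, self.tx_start0 + rel + size)
            for rel, size in zip(self.block_starts, self.block_sizes)
        ]

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = self.exons
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]

    def to_bed12(self) -> str:
        return "\t".join(
            (
                self.chrom, str(self.tx_start0), str(self.tx_end0), self.name,
                "0", self.strand, str(self.cds_start0), str(self.cds_end0),
                "0", str(len(self.block_sizes)),
                ",".join(map(str, self.block_sizes)) + ",",
                ",".join(map(str, self.block_starts)) + ",",
            )
        )


# ---------------------------------------------------------------------------
# per-dialect row parsers: fields -> (chrom, a, b, strand, count, extras)

def _parse_circexplorer(fields: Sequence[str]):
    if len(fields) < 13:
        raise DialectError("circexplorer rows need >= 13 columns")
    return fields[0], int(fields[1]), int(fields[2]), fields[5], int(fields[12]), {
        "name": fields[3]
    }


def _parse_ciri2(fields: Sequence[str]):
    if len(fields) < 5:
        raise DialectError("ciri2 rows need >= 5 columns")
    strand = fields[10] if len(fields) > 10 else "."
    return fields[1], int(fields[2]), int(fields[3]), strand, int(fields[4]), {
        "circRNA_ID": fields[0]
    }


def _parse_find_circ(fields: Sequence[str]):
    if len(fields) < 6:
        raise DialectError("find_circ rows need >= 6 columns")
    return fields[0], int(fields[1]), int(fields[2]), fields[5], int(fields[4]), {
        "name": fields[3]
    }


def _parse_knife(fields: Sequence[str]):
    if len(fields) < 2:
        raise DialectError("knife rows need >= 2 columns")
    parts = fields[0].split("|")
    if len(parts) != 5:
        raise DialectError(f"malformed knife junction string {fields[0]!r}")
    chrom = parts[0]
    try:
        pos1 = int(parts[1].rsplit(":", 1)[1])
        pos2 = int(parts[2].rsplit(":", 1)[1])
    except (IndexError, ValueError) as exc:
        raise DialectError(f"malformed knife positions in {fields[0]!r}") from exc
    strand = parts[4]
    return chrom, pos1, pos2, strand, int(round(float(fields[1]))), {
        "junction_type": parts[3]
    }


def _parse_mapsplice(fields: Sequence[str]):
    if len(fields) < 6:
        raise DialectError("mapsplice rows need >= 6 columns")
    chroms = fields[0].split("~")
    if len(chroms) != 2 or chroms[0] != chroms[1]:
        raise DialectError(f"trans-chromosomal record {fields[0]!r} rejected")
    strand = fields[5][0] if fields[5] else "."
    return chroms[0], int(fields[1]), int(fields[2]), strand, int(fields[4]), {}


_ROW_PARSERS: dict[str, Callable] = {
    "circexplorer": _parse_circexplorer,
    "ciri2": _parse_ciri2,
    "find_circ": _parse_find_circ,
    "knife": _parse_knife,
    "mapsplice": _parse_mapsplice,
}

_HEADERED = {"ciri2", "knife", "dcc"}


def _looks_like_header(dialect: str, line: str) -> bool:
    if line.startswith("#"):
        return True
    first = line.split("\t", 1)[0].lower()
    return dialect in _HEADERED and first in {"circrna_id", "junction", "chr", "chrom"}


def _read_dcc(path: Path, sample_id: str) -> list[ToolCall]:
    """DCC CircRNACount: multi-sample count columns or a single count column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return []
    required = ["Chr", "Start", "End", "Strand"]
    if list(df.columns[:4]) != required:
        raise DialectError(f"{path}: not a DCC CircRNACount header")
    count_cols = list(df.columns[4:])
    if not count_cols:
        raise DialectError(f"{path}: DCC file has no count column")
    if sample_id in count_cols:
        col = sample_id
    elif len(count_cols) == 1:
        col = count_cols[0]
    else:
        raise DialectError(
            f"{path}: sample {sample_id!r} not among DCC columns {count_cols}"
        )
    calls = []
    for _, row in df.iterrows():
        count = int(row[col])
        if count <= 0:
            continue  # absent in this sample
        junction = normalize_coordinates(
            row["Chr"], int(row["Start"]), int(row["End"]), row["Strand"],
            CoordinateBasis.one_based,
        )
        calls.append(ToolCall("dcc", sample_id, junction, count))
    return calls


def read_tool_output(
    path: str | Path, dialect: str, sample_id: str
) -> list[ToolCall]:
    """Parse one caller's native output file into :class:`ToolCall` records.

    Malformed rows are skipped with a logged warning; if more than half of
    the non-header rows are malformed the file is rejected outright (the
    usual signal that the wrong dialect was requested).
    """
    path = Path(path)
    if dialect not in TOOLS:
        raise DialectError(f"unknown dialect {dialect!r}")
    if dialect == "dcc":
        return _read_dcc(path, sample_id)

    parser = _ROW_PARSERS[dialect]
    basis = TOOL_BASIS[dialect]
    calls: list[ToolCall] = []
    n_bad = n_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and _looks_like_header(dialect, line):
                continue
            if line.startswith("#"):
                continue
            n_rows += 1
            fields = line.split("\t")
            try:
                chrom, a, b, strand, count, extras = parser(fields)
                if a > b:  # donor-first record: reorder by numeric value
                    a, b = b, a
                junction = normalize_coordinates(chrom, a, b, strand, basis)
                if count < 0:
                    raise DialectError("negative read count")
            except (DialectError, CoordinateError, ValueError, IndexError) as exc:
                n_bad += 1
                logger.warning("%s:%d: skipping malformed row (%s)", path, lineno, exc)
                continue
            calls.append(ToolCall(dialect, sample_id, junction, count, extras))
    if n_rows and n_bad / n_rows > 0.5:
        raise DialectError(
            f"{path}: {n_bad}/{n_rows} rows malformed under dialect "
            f"{dialect!r} — wrong dialect?"
        )
    return calls


def read_star_sj(path: str | Path) -> list[LinearJunction]:
    """Parse a STAR SJ.out.tab file (9 columns, 1-based intron coordinates).

    Column 7 (uniquely-mapping spliced reads) is taken as the read count;
    the multi-mapper column is ignored.
    """
    path = Path(path)
    out: list[LinearJunction] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise DialectError(
                    f"{path}:{lineno}: SJ.out.tab rows have 9 columns, "
                    f"got {len(fields)}"
                )
            out.append(
                LinearJunction(
                    normalize_chrom(fields[0]),
                    int(fields[1]),
                    int(fields[2]),
                    int(fields[6]),
                )
            )
    return out


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata TSV (one row per sample)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [
        "sample_id", "participant_id", "biofluid", "visit_index",
        "canonical_junction_reads", "chimeric_junction_reads",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: sample table missing columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise DialectError(f"{path}: duplicate sample_id {sorted(set(dup))}")
    metas = []
    for row in df.itertuples(index=False):
        meta = SampleMeta(
            sample_id=row.sample_id,
            participant_id=row.participant_id,
            biofluid=row.biofluid,
            visit_index=int(row.visit_index),
            canonical_junction_reads=int(row.canonical_junction_reads),
            chimeric_junction_reads=int(row.chimeric_junction_reads),
        )
        if meta.total_junction_reads <= 0:
            raise DialectError(
                f"{path}: sample {meta.sample_id} has no junction reads"
            )
        metas.append(meta)
    return metas


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read a BED12 transcript annotation."""
    models = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise DialectError(f"{path}:{lineno}: BED12 needs 12 columns")
            sizes = tuple(int(x) for x in f[10].rstrip(",").split(","))
            starts = tuple(int(x) for x in f[11].rstrip(",").split(","))
            if len(sizes) != int(f[9]):
                raise DialectError(f"{path}:{lineno}: blockCount mismatch")
            models.append(
                TranscriptModel(
                    chrom=normalize_chrom(f[0]),
                    tx_start0=int(f[1]),
                    tx_end0=int(f[2]),
                    name=f[3],
                    strand=f[5],
                    cds_start0=int(f[6]),
                    cds_end0=int(f[7]),
                    block_sizes=sizes,
                    block_starts=starts,
                )
            )
    return models


def read_junction_list(path: str | Path) -> set[str]:
    """Load a published consensus junction list into canonical keys.

    Accepts one junction per line as either a ``chrom:start-end[:strand]``
    key or the first four columns of a BED row; header lines are skipped.
    Intended for externally deposited catalog files.
    """
    keys: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            token = fields[0]
            try:
                if ":" in token:
                    j = BackspliceJunction.from_key(token)
                else:
                    strand = fields[5] if len(fields) > 5 else "."
                    j = BackspliceJunction(
                        normalize_chrom(fields[0]), int(fields[1]),
                        int(fields[2]), strand,
                    )
            except (ValueError, IndexError):
                continue  # header or annotation line
            keys.add(j.unstranded_key)
    return keys


def write_junction_bed(
    junctions: Iterable[BackspliceJunction | str],
    path: str | Path,
    scores: dict[str, float] | None = None,
) -> None:
    """Write junctions (objects or keys) as BED6; name column = key."""
    with Path(path).open("w") as fh:
        for j in sorted(
            (BackspliceJunction.from_key(j) if isinstance(j, str) else j)
            for j in junctions
        ):
            score = (scores or {}).get(j.key, (scores or {}).get(j.unstranded_key, 0))
            fh.write(j.to_bed6(score) + "\n")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a junction-key x sample matrix as TSV with a header row."""
    matrix.to_csv(path, sep="\t", index=True, index_label="junction_key")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col="junction_key")


def canonical_total_from_sj(linear: Iterable[LinearJunction]) -> int:
    """Sum of unique spliced reads over an SJ.out.tab — a helper for building
    the canonical component of the JRPM denominator when no totals file is
    available."""
    return sum(lj.unique_reads for lj in linear)
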