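"""circRNA expression: JRPM normalization and the circular-to-linear ratio.

JRPM (junction reads per million) normalizes a junction's back-spliced
read count by the sample's total junction reads — canonical plus chimeric,
as counted by the aligner::

    JRPM = count / total_junction_reads * 1e6

The circular-to-linear ratio (CLR) compares the circle to its linear host
at the same splice sites::

    CLR = count / max(linear5, linear3)

where linear5/linear3 are the uniquely-mapping linear spliced reads at the
junction's acceptor- and donor-side flanks.  When neither flank has linear
reads the denominator is a pseudocount of 1, so CLR(count, 0, 0) = count.
Multiple linear junctions sharing a flank splice site (alternative
partners) are summed within the flank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SampleMeta
from .junctions import (
    BackspliceJunction,
    LinearJunction,
)

__all__ = [
    "ExpressionRecord",
    "jrpm",
    "linear_flank_counts",
    "clr",
    "build_expression_table",
    "jrpm_matrix",
    "clr_summary",
]


@dataclass
class ExpressionRecord:
    """Per-junction per-sample expression values."""

    junction_key: str
    sample_id: str
    count: int
    jrpm: float
    linear5: int
    linear3: int
    clr: float


def jrpm(count: int, total_junction_reads: int) -> float:
    """Junction reads per million: count / total * 1e6."""
    if total_junction_reads <= 0:
        raise ValueError("total_junction_reads must be positive")
    if count < 0:
        raise ValueError("negative count")
    return count / total_junction_reads * 1_000_000.0


def _flank_index(
    linear: Iterable[LinearJunction],
) -> tuple[dict[tuple[str, int], int], dict[tuple[str, int], int]]:
    """Index linear junctions by their splice-site coordinates.

    Returns (by_intron_end, by_intron_start) maps keyed on
    (chrom, coordinate) with unique-read counts summed per site.
    """
    by_end: dict[tuple[str, int], int] = {}
    by_start: dict[tuple[str, int], int] = {}
    for lj in linear:
        ke = (lj.chrom, lj.intron_end1)
        ks = (lj.chrom, lj.intron_start1)
        by_end[ke] = by_end.get(ke, 0) + lj.unique_reads
        by_start[ks] = by_start.get(ks, 0) + lj.unique_reads
    return by_end, by_start


def linear_flank_counts(
    junction: BackspliceJunction,
    linear: Iterable[LinearJunction] | tuple[dict, dict],
) -> tuple[int, int]:
    """Linear spliced reads at the junction's 5' and 3' flank splice sites.

    The 5' flank sums reads of linear introns ending at the back-splice
    acceptor (``intron_end1 == start0``); the 3' flank sums those starting
    just after the donor (``intron_start1 - 1 == end0``).  Accepts either
    the raw linear junctions or a pre-built :func:`_flank_index` pair.
    """
    if isinstance(linear, tuple) and len(linear) == 2 and isinstance(linear[0], dict):
        by_end, by_start = linear
    else:
        by_end, by_start = _flank_index(linear)
    linear5 = by_end.get((junction.chrom, junction.start0), 0)
    linear3 = by_start.get((junction.chrom, junction.end0 + 1), 0)
    return linear5, linear3


def clr(count: int, linear5: int, linear3: int) -> float:
    """Circular-to-linear ratio with the zero-flank pseudocount.

    Denominator is the larger flank count, or 1 when both flanks are zero.
    """
    if min(count, linear5, linear3) < 0:
        raise ValueError("counts must be non-negative")
    denom = max(linear5, linear3)
    return count / (denom if denom > 0 else 1)


def build_expression_table(
    counts: pd.DataFrame,
    samples: Sequence[SampleMeta],
    linear_by_sample: Mapping[str, Sequence[LinearJunction]],
) -> pd.DataFrame:
    """Full per-junction per-sample expression table.

    Parameters
    ----------
    counts
        junction_key x sample_id back-spliced read counts.
    samples
        Metadata (JRPM denominators) for every column of ``counts``.
    linear_by_sample
        sample_id -> linear junctions from that sample's SJ.out.tab.

    Returns a long-format frame with columns junction_key, sample_id,
    count, jrpm, linear5, linear3, clr.  Rows are emitted for every
    (junction, sample) cell, including zero counts (jrpm = 0 there).
    """
    meta = {s.sample_id: s for s in samples}
    missing = [c for c in counts.columns if c not in meta]
    if missing:
        raise ValueError(f"no metadata for samples: {missing}")
    rows = []
    for sid in counts.columns:
        total = meta[sid].total_junction_reads
        index = _flank_index(linear_by_sample.get(sid, ()))
        col = counts[sid]
        for key in counts.index:
            n = int(col[key])
            j = BackspliceJunction.from_key(key)
            l5, l3 = linear_flank_counts(j, index)
            rows.append(
                (key, sid, n, jrpm(n, total), l5, l3, clr(n, l5, l3))
            )
    return pd.DataFrame(
        rows,
        columns=["junction_key", "sample_id", "count", "jrpm",
                 "linear5", "linear3", "clr"],
    )


def jrpm_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long expression table into a junction x sample JRPM matrix."""
    return expression.pivot(
        index="junction_key", columns="sample_id", values="jrpm"
    ).fillna(0.0)


def clr_summary(expression: pd.DataFrame) -> dict[str, float]:
    """Fractions of expressed junctions whose circle out-expresses its host.

    Per sample, among junctions with a nonzero back-spliced count, computes
    the fraction with CLR > 1 and its two sub-bands — (1, 5] (moderately
    higher than linear) and > 5 — then averages the per-sample fractions
    across samples.
    """
    fracs = {"clr_gt1": [], "clr_1_to_5": [], "clr_gt5": []}
    for _, grp in expression.groupby("sample_id"):
        expressed = grp[grp["count"] > 0]
        if expressed.empty:
            continue
        c = expressed["clr"]
        n = len(expressed)
        fracs["clr_gt1"].append((c > 1).sum() / n)
        fracs["clr_1_to_5"].append(((c > 1) & (c <= 5)).sum() / n)
        fracs["clr_gt5"].append((c > 5).sum() / n)
    if not fracs["clr_gt1"]:
        return {k: float("nan") for k in fracs}
    return {k: float(pd.Series(v).mean()) for k, v in fracs.items()}
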