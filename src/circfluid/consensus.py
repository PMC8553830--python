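"""Per-tool detection filters, six-tool intersection, and prevalence tiers.

The harmonization recipe: within each biofluid, a junction counts as
*detected* by a tool in a sample when that tool reports it with at least
``min_reads`` back-spliced reads there (default 2); a tool *retains* a
junction when it is detected in at least ``min_samples`` samples (default
5); and the *consensus catalog* is the intersection of the six tools'
retained sets.  Independent per-tool false positives rarely recur in five
samples for all six tools at once, which is what makes the strict
intersection a high-confidence catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SampleMeta, ToolCall
from .junctions import TOOLS

__all__ = [
    "FilterConfig",
    "DetectionMatrix",
    "detect",
    "retain_tool_junctions",
    "intersect_tools",
    "consensus_detection",
    "prevalence_table",
    "biofluid_overlap",
    "sample_qc",
    "prevalence_filter",
]


@dataclass
class FilterConfig:
    """Detection-filter thresholds.

    min_reads
        Minimum back-spliced reads for a junction to count as detected in a
        sample (default 2).
    min_samples
        Minimum number of samples (within a biofluid) a tool must detect a
        junction in for the tool to retain it (default 5).
    junction_overlap_nt
        Read overlap required on either side of the junction by the
        upstream callers.  Provenance metadata only: it parametrizes the
        callers, not anything recomputable from their outputs.
    strand_aware
        Whether junction keys used for cross-tool matching carry strand.
    min_circ_per_sample / min_prevalence
        The two expression-analysis pre-filters: samples must detect at
        least ``min_circ_per_sample`` junctions (default 300), junctions
        expressed in fewer than ``min_prevalence`` of samples (default 0.5)
        are excluded.
    detection_mode
        How a consensus junction counts as detected in a sample for
        prevalence purposes: "any" tool reporting >= min_reads (default) or
        "all" six tools.
    """

    min_reads: int = 2
    min_samples: int = 5
    junction_overlap_nt: int = 18
    strand_aware: bool = False
    min_circ_per_sample: int = 300
    min_prevalence: float = 0.5
    detection_mode: str = "any"

    def __post_init__(self) -> None:
        if self.min_reads < 1 or self.min_samples < 1:
            raise ValueError("min_reads and min_samples must be >= 1")
        if not 0 <= self.min_prevalence <= 1:
            raise ValueError("min_prevalence must be in [0, 1]")
        if self.detection_mode not in ("any", "all"):
            raise ValueError("detection_mode must be 'any' or 'all'")


@dataclass
class DetectionMatrix:
    """Raw counts and detection flags for one tool in one biofluid."""

    tool: str
    biofluid: str
    counts: pd.DataFrame    # junction_key x sample_id, int
    detected: pd.DataFrame  # junction_key x sample_id, bool
    config: FilterConfig = field(default_factory=FilterConfig)


def detect(
    calls: Iterable[ToolCall],
    samples: Sequence[SampleMeta],
    config: FilterConfig | None = None,
) -> DetectionMatrix:
    """Build the per-tool count/detection matrix over a biofluid's samples.

    All calls must come from one tool, and every referenced sample must be
    present in ``samples`` (all of one biofluid).  Duplicate reports of a
    junction within a sample (e.g. per-mate runs combined downstream) are
    summed.
    """
    config = config or FilterConfig()
    calls = list(calls)
    sample_ids = [s.sample_id for s in samples]
    biofluids = {s.biofluid for s in samples}
    if len(biofluids) > 1:
        raise ValueError(f"samples span multiple biofluids: {sorted(biofluids)}")
    biofluid = biofluids.pop() if biofluids else ""
    tools = {c.tool for c in calls}
    if len(tools) > 1:
        raise ValueError(f"calls span multiple tools: {sorted(tools)}")
    tool = tools.pop() if tools else ""

    known = set(sample_ids)
    unknown = {c.sample_id for c in calls} - known
    if unknown:
        raise ValueError(f"calls reference samples not in table: {sorted(unknown)}")

    cells: dict[tuple[str, str], int] = {}
    for c in calls:
        k = (c.junction.key_for(config.strand_aware), c.sample_id)
        cells[k] = cells.get(k, 0) + c.count
    keys = sorted({k for k, _ in cells})
    counts = pd.DataFrame(0, index=keys, columns=sample_ids, dtype=int)
    for (key, sid), n in cells.items():
        counts.at[key, sid] = n
    return DetectionMatrix(
        tool=tool,
        biofluid=biofluid,
        counts=counts,
        detected=counts >= config.min_reads,
        config=config,
    )


def retain_tool_junctions(
    matrix: DetectionMatrix, config: FilterConfig | None = None
) -> tuple[set[str], dict]:
    """Apply the per-tool sample-recurrence filter.

    Returns the retained junction set (detected in >= ``min_samples``
    samples) and a summary with the tool's total retained circRNA and the
    mean number of retained junctions detected per sample.
    """
    config = config or matrix.config
    n_detected = matrix.detected.sum(axis=1)
    retained = set(n_detected.index[n_detected >= config.min_samples])
    if retained:
        per_sample = matrix.detected.loc[sorted(retained)].sum(axis=0)
        mean_per_sample = float(per_sample.mean())
    else:
        mean_per_sample = 0.0
    summary = {
        "tool": matrix.tool,
        "biofluid": matrix.biofluid,
        "total_circRNA": len(retained),
        "mean_circRNA_per_sample": mean_per_sample,
    }
    return retained, summary


def intersect_tools(
    retained: Mapping[str, set[str]], min_tools: int = 6
) -> tuple[set[str], pd.DataFrame]:
    """Intersect the six per-tool retained sets.

    Returns the consensus set (junctions in at least ``min_tools`` sets;
    the default 6 is the strict all-tools intersection) and the exclusive
    intersection-pattern table with UpSet semantics: each junction of the
    union counted exactly once under its exact tool-membership pattern.
    """
    missing = [t for t in TOOLS if t not in retained]
    if missing:
        raise ValueError(f"retained sets missing for tools: {missing}")
    if not 1 <= min_tools <= 6:
        raise ValueError("min_tools must be in 1..6")

    union: set[str] = set().union(*retained.values())
    patterns: dict[tuple[bool, ...], int] = {}
    n_tools_per_key: dict[str, int] = {}
    for key in union:
        pat = tuple(key in retained[t] for t in TOOLS)
        patterns[pat] = patterns.get(pat, 0) + 1
        n_tools_per_key[key] = sum(pat)
    consensus = {k for k, n in n_tools_per_key.items() if n >= min_tools}

    rows = []
    for r in range(6, 0, -1):
        for combo in combinations(range(6), r):
            pat = tuple(i in combo for i in range(6))
            count = patterns.get(pat, 0)
            row = {t: pat[i] for i, t in enumerate(TOOLS)}
            row["n_tools"] = r
            row["exclusive_count"] = count
            rows.append(row)
    table = pd.DataFrame(rows)
    return consensus, table


def consensus_detection(
    matrices: Mapping[str, DetectionMatrix],
    consensus: set[str],
    mode: str = "any",
) -> pd.DataFrame:
    """Per-sample detection flags for consensus junctions.

    ``mode="any"``: detected in a sample when at least one tool reports it
    with >= min_reads there; ``mode="all"``: all six tools must.
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    keys = sorted(consensus)
    mats = list(matrices.values())
    if not mats:
        raise ValueError("no detection matrices supplied")
    samples = list(mats[0].detected.columns)
    agg = None
    for m in mats:
        d = m.detected.reindex(index=keys, columns=samples, fill_value=False)
        agg = d if agg is None else (agg | d if mode == "any" else agg & d)
    return agg.astype(bool)


def prevalence_table(
    detection: pd.DataFrame,
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
) -> pd.DataFrame:
    """Count junctions detected in at least t of samples, per tier t.

    A junction meets tier t when its detected-sample count is >=
    ceil(t * n_samples); counts are non-increasing in t.
    """
    n_samples = detection.shape[1]
    n_det = detection.sum(axis=1)
    rows = []
    for t in thresholds:
        need = int(np.ceil(t * n_samples))
        rows.append(
            {"threshold": float(t), "min_samples": need,
             "n_junctions": int((n_det >= need).sum())}
        )
    return pd.DataFrame(rows)


def biofluid_overlap(
    set_a: set[str], set_b: set[str]
) -> tuple[set[str], int, float | None]:
    """Overlap of one biofluid's consensus with another's.

    Returns the shared set, its size, and the shared fraction of ``set_b``
    (e.g. the fraction of urine circRNA also found in plasma).  The
    fraction is ``None`` when ``set_b`` is empty.
    """
    shared = set_a & set_b
    frac = len(shared) / len(set_b) if set_b else None
    return shared, len(shared), frac


def sample_qc(
    detection: pd.DataFrame, min_circ: int = 300
) -> list[str]:
    """Keep samples detecting at least ``min_circ`` junctions."""
    per_sample = detection.sum(axis=0)
    kept = [s for s in detection.columns if per_sample[s] >= min_circ]
    if not kept:
        raise ValueError(
            f"all samples fell below the {min_circ} circRNA/sample threshold"
        )
    return kept


def prevalence_filter(
    detection: pd.DataFrame, min_frac: float = 0.5
) -> list[str]:
    """Drop junctions expressed in fewer than ``min_frac`` of samples.

    A junction detected in exactly ``min_frac`` of samples is kept (the
    exclusion applies strictly below the threshold).
    """
    n = detection.shape[1]
    frac = detection.sum(axis=1) / n
    return [k for k in detection.index if frac[k] >= min_frac]
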