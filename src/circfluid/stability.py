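"""Longitudinal stability, inter-tool correlation, and platform concordance.

Stability is measured as the coefficient of variation (CV = sample sd /
mean) of a junction's JRPM across samples, computed within each
longitudinally sampled participant and across the whole biofluid.  If
individuals maintain characteristic circRNA profiles over time, the
within-participant CV distribution sits below the global one; a two-sided
Mann-Whitney rank-sum test compares the pooled within-participant CVs
against the global CVs (the comparison is distribution-free, as CV
distributions are heavily right-skewed).

Inter-tool agreement is the Pearson correlation of per-junction mean JRPM
profiles between callers, and cross-platform concordance is Spearman rank
agreement between qRT-PCR (mean Ct, lower = more abundant) and RNA-Seq
(mean JRPM, higher = more abundant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMeta

__all__ = [
    "StabilityResult",
    "cv",
    "participant_stability",
    "tool_correlation",
    "rank_concordance",
]


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean.

    Requires at least two values and a positive mean; scale-invariant.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean)


@dataclass
class StabilityResult:
    """Within-participant vs global CV comparison for one biofluid."""

    participant_cvs: dict[str, pd.Series]   # participant -> per-junction CV
    global_cvs: pd.Series                   # per-junction CV over all samples
    n_samples: dict[str, int]               # scope -> sample count
    statistic_name: str
    statistic: float
    pvalue: float
    per_participant_tests: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def pooled_participant_cvs(self) -> pd.Series:
        if not self.participant_cvs:
            return pd.Series(dtype=float)
        return pd.concat(list(self.participant_cvs.values()), ignore_index=True)

    @property
    def median_participant_cv(self) -> float:
        pooled = self.pooled_participant_cvs
        return float(pooled.median()) if not pooled.empty else float("nan")

    @property
    def median_global_cv(self) -> float:
        return float(self.global_cvs.median())

    def to_frame(self) -> pd.DataFrame:
        """Long table of (scope, junction_key, cv)."""
        rows = [("all", k, v) for k, v in self.global_cvs.items()]
        for pid, s in self.participant_cvs.items():
            rows.extend((pid, k, v) for k, v in s.items())
        return pd.DataFrame(rows, columns=["scope", "junction_key", "cv"])


def _cv_per_junction(matrix: pd.DataFrame) -> pd.Series:
    """Per-junction CV over the matrix columns, for junctions with mean > 0."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    keep = mean > 0
    sd = values.std(axis=1, ddof=1)
    out = pd.Series(sd[keep] / mean[keep], index=matrix.index[keep])
    return out


def participant_stability(
    jrpm: pd.DataFrame,
    samples: Sequence[SampleMeta],
    min_visits: int = 5,
) -> StabilityResult:
    """Compare within-participant to global expression variability.

    Parameters
    ----------
    jrpm
        junction x sample JRPM matrix, restricted to one biofluid's
        samples (typically the consensus catalog).
    samples
        Metadata for the matrix columns; used to group samples by
        participant.
    min_visits
        Only participants with at least this many samples in the matrix
        enter the within-participant arm (default 5, focusing on
        longitudinally sampled individuals).

    Per participant, the CV is computed per junction over that
    participant's samples (junctions with nonzero mean there); the global
    CVs use all matrix columns.  The pooled participant CVs are compared
    to the global CVs with a two-sided Mann-Whitney U test; per-participant
    tests against the global distribution are also reported.
    """
    meta = {s.sample_id: s for s in samples}
    cols = [c for c in jrpm.columns if c in meta]
    if len(cols) != jrpm.shape[1]:
        missing = set(jrpm.columns) - set(cols)
        raise ValueError(f"no metadata for samples: {sorted(missing)}")

    by_participant: dict[str, list[str]] = {}
    for c in cols:
        by_participant.setdefault(meta[c].participant_id, []).append(c)
    eligible = {p: cs for p, cs in by_participant.items() if len(cs) >= min_visits}
    if not eligible:
        raise ValueError(f"no participant has >= {min_visits} samples")

    global_cvs = _cv_per_junction(jrpm)
    participant_cvs: dict[str, pd.Series] = {}
    n_samples = {"all": len(cols)}
    per_tests = []
    for pid, cs in sorted(eligible.items()):
        pcv = _cv_per_junction(jrpm[cs])
        participant_cvs[pid] = pcv
        n_samples[pid] = len(cs)
        if pcv.size and global_cvs.size and (pcv.var() > 0 or global_cvs.var() > 0):
            u, p = stats.mannwhitneyu(pcv, global_cvs, alternative="two-sided")
        else:
            u, p = float("nan"), float("nan")
        per_tests.append(
            {"participant_id": pid, "n_samples": len(cs),
             "median_cv": float(pcv.median()) if pcv.size else float("nan"),
             "U": float(u), "pvalue": float(p)}
        )

    pooled = pd.concat(list(participant_cvs.values()), ignore_index=True)
    degenerate = (
        pooled.empty or global_cvs.empty
        or (pooled.var() == 0 and global_cvs.var() == 0
            and pooled.iloc[0] == global_cvs.iloc[0])
    )
    if degenerate:
        statistic, pvalue = float("nan"), float("nan")
    else:
        statistic, pvalue = stats.mannwhitneyu(
            pooled, global_cvs, alternative="two-sided"
        )
    return StabilityResult(
        participant_cvs=participant_cvs,
        global_cvs=global_cvs,
        n_samples=n_samples,
        statistic_name="mannwhitneyu",
        statistic=float(statistic),
        pvalue=float(pvalue),
        per_participant_tests=pd.DataFrame(per_tests),
    )


def tool_correlation(
    profiles: Mapping[str, pd.Series] | pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of per-junction mean JRPM between callers.

    ``profiles`` maps each tool to its per-junction mean JRPM; vectors are
    aligned on the union of junctions, zero-filled where a tool did not
    report a junction.  Pairs involving a zero-variance vector get NaN.
    """
    if not isinstance(profiles, pd.DataFrame):
        profiles = pd.DataFrame(profiles)
    profiles = profiles.fillna(0.0)
    tools = list(profiles.columns)
    mat = pd.DataFrame(np.nan, index=tools, columns=tools, dtype=float)
    for a in tools:
        for b in tools:
            x, y = profiles[a], profiles[b]
            if a == b:
                mat.loc[a, b] = 1.0 if x.std() >= 0 else np.nan
            elif x.std() == 0 or y.std() == 0:
                mat.loc[a, b] = np.nan
            else:
                mat.loc[a, b] = float(np.corrcoef(x, y)[0, 1])
    return mat


def rank_concordance(
    table: pd.DataFrame,
    value_a: str = "mean_ct",
    value_b: str = "mean_jrpm",
) -> tuple[pd.Series, pd.Series, float]:
    """Cross-platform abundance rank agreement.

    ``value_a`` ranks ascending (qRT-PCR: lowest mean Ct = most abundant =
    rank 1); ``value_b`` ranks descending (RNA-Seq: highest mean JRPM =
    rank 1).  Missing values on a platform are ranked last in input
    (insertion) order.  Spearman's rho is computed over items with both
    values present.
    """
    if len(table) < 3:
        raise ValueError("rank concordance needs at least 3 items")
    a = pd.to_numeric(table[value_a], errors="coerce")
    b = pd.to_numeric(table[value_b], errors="coerce")
    if a.isna().all() or b.isna().all():
        raise ValueError("one platform has no values")

    def _rank(values: pd.Series, ascending: bool) -> pd.Series:
        present = values.dropna()
        order = present.sort_values(ascending=ascending, kind="stable").index
        ranks = pd.Series(index=values.index, dtype=int)
        for r, idx in enumerate(order, start=1):
            ranks[idx] = r
        nxt = len(present) + 1
        for idx in values.index[values.isna()]:
            ranks[idx] = nxt
            nxt += 1
        return ranks

    rank_a = _rank(a, ascending=True)
    rank_b = _rank(b, ascending=False)
    complete = a.notna() & b.notna()
    rho = float(stats.spearmanr(rank_a[complete], rank_b[complete]).statistic)
    return rank_a, rank_b, rho
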