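"""End-to-end orchestration over an on-disk study directory.

Expects the layout written by :func:`circfluid.simulate.emit_files` (or an
equivalently arranged real study)::

    data_dir/
      samples.tsv
      annotation.bed
      tools/<tool>/<sample_id>.tsv
      sj/<sample_id>.SJ.out.tab

and writes, per biofluid, the consensus catalog (BED6), the exclusive
intersection-pattern table, prevalence tiers, the long expression table,
the JRPM matrix, feature annotations, CV/stability tables, the inter-tool
correlation matrix, and a JSON run report with record counts at every
filter step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_junctions
from .consensus import (
    FilterConfig,
    biofluid_overlap,
    consensus_detection,
    detect,
    intersect_tools,
    prevalence_filter,
    prevalence_table,
    retain_tool_junctions,
    sample_qc,
)
from .io import (
    read_bed12,
    read_sample_table,
    read_star_sj,
    read_tool_output,
    write_junction_bed,
    write_matrix,
)
from .junctions import TOOLS
from .quantify import build_expression_table, clr_summary, jrpm, jrpm_matrix
from .stability import participant_stability, tool_correlation

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline computed."""

    consensus: dict[str, set[str]]
    retained: dict[str, dict[str, set[str]]]          # biofluid -> tool -> set
    tool_summaries: list[dict]
    pattern_tables: dict[str, pd.DataFrame]
    prevalence: dict[str, pd.DataFrame]
    overlap: dict
    expression: dict[str, pd.DataFrame]
    jrpm: dict[str, pd.DataFrame]
    clr_fractions: dict[str, dict[str, float]]
    qc_samples: dict[str, list[str]]
    prevalent_junctions: dict[str, list[str]]
    annotations: dict[str, pd.DataFrame]
    stability: dict[str, object]
    correlations: dict[str, pd.DataFrame]
    report: dict = field(default_factory=dict)


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path | None = None,
    config: FilterConfig | None = None,
    min_visits: int = 5,
    run_stability: bool = True,
) -> PipelineResult:
    """Run harmonization, consensus, quantification, annotation, stability.

    ``config`` carries the detection filters (defaults: >= 2 reads,
    >= 5 samples, strand-unaware matching) and the expression pre-filters.
    Stages degrade gracefully: stability is skipped when no participant has
    ``min_visits`` samples and ``run_stability`` is False.
    """
    data = Path(data_dir)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    cfg = config or FilterConfig()

    samples = read_sample_table(data / "samples.tsv")
    by_fluid: dict[str, list] = {}
    for s in samples:
        by_fluid.setdefault(s.biofluid, []).append(s)
    transcripts = read_bed12(data / "annotation.bed")

    report: dict = {
        "version": __version__,
        "config": {k: v for k, v in vars(cfg).items()},
        "inputs": {
            "samples.tsv": _md5(data / "samples.tsv"),
            "annotation.bed": _md5(data / "annotation.bed"),
        },
        "n_samples": {f: len(v) for f, v in by_fluid.items()},
        "biofluids": {},
    }

    result = PipelineResult(
        consensus={}, retained={}, tool_summaries=[], pattern_tables={},
        prevalence={}, overlap={}, expression={}, jrpm={}, clr_fractions={},
        qc_samples={}, prevalent_junctions={}, annotations={}, stability={},
        correlations={},
    )

    for fluid, fluid_samples in sorted(by_fluid.items()):
        sids = [s.sample_id for s in fluid_samples]
        frep: dict = {"n_samples": len(sids)}
        matrices = {}
        retained: dict[str, set[str]] = {}
        for tool in TOOLS:
            calls = []
            for sid in sids:
                path = data / "tools" / tool / f"{sid}.tsv"
                if path.exists():
                    calls.extend(read_tool_output(path, tool, sid))
            matrix = detect(calls, fluid_samples, cfg)
            matrix.tool = tool
            matrices[tool] = matrix
            kept, summary = retain_tool_junctions(matrix, cfg)
            retained[tool] = kept
            result.tool_summaries.append(summary)
            frep.setdefault("per_tool", {})[tool] = {
                "n_calls": len(calls),
                "n_junctions_seen": int(matrix.counts.shape[0]),
                "n_retained": len(kept),
                "mean_per_sample": summary["mean_circRNA_per_sample"],
            }
            logger.info("%s/%s: %d calls, %d junctions, %d retained",
                        fluid, tool, len(calls), matrix.counts.shape[0], len(kept))

        consensus, pattern = intersect_tools(retained)
        detection = consensus_detection(matrices, consensus, cfg.detection_mode)
        tiers = prevalence_table(detection)
        frep["n_consensus"] = len(consensus)
        logger.info("%s: consensus catalog has %d junctions", fluid, len(consensus))

        # merged counts over consensus: a junction's count in a sample is the
        # maximum reported by any tool (the permissive detection analog)
        keys = sorted(consensus)
        merged = None
        for m in matrices.values():
            c = m.counts.reindex(index=keys, columns=sids, fill_value=0)
            merged = c if merged is None else merged.where(merged >= c, c)
        if merged is None:
            merged = pd.DataFrame(index=keys, columns=sids, dtype=int)

        linear_by_sample = {}
        for sid in sids:
            sj_path = data / "sj" / f"{sid}.SJ.out.tab"
            linear_by_sample[sid] = read_star_sj(sj_path) if sj_path.exists() else []
        expression = build_expression_table(merged, fluid_samples, linear_by_sample)
        jmat = jrpm_matrix(expression)
        clr_frac = clr_summary(expression)
        frep["clr_fractions"] = clr_frac

        try:
            qc = sample_qc(detection, cfg.min_circ_per_sample)
        except ValueError:
            qc = []
        prevalent = (
            prevalence_filter(detection[qc], cfg.min_prevalence) if qc else []
        )
        frep["n_samples_pass_qc"] = len(qc)
        frep["n_junctions_prevalent"] = len(prevalent)

        ann = annotate_junctions(keys, transcripts)
        ann_df = pd.DataFrame(
            [(a.junction_key, ",".join(a.genes), a.chosen_transcript or "",
              a.n_exons_spanned, ";".join(sorted(a.classes)), a.primary_class)
             for a in ann],
            columns=["junction_key", "genes", "chosen_transcript",
                     "n_exons_spanned", "classes", "primary_class"],
        )
        frep["feature_classes"] = (
            ann_df["primary_class"].value_counts().to_dict() if len(ann_df) else {}
        )

        # per-tool mean-JRPM profiles over the union of retained junctions
        union = sorted(set().union(*retained.values())) if retained else []
        totals = {s.sample_id: s.total_junction_reads for s in fluid_samples}
        profiles = {}
        for tool, m in matrices.items():
            c = m.counts.reindex(index=union, columns=sids, fill_value=0)
            jr = c.apply(lambda col: col.map(lambda n: jrpm(n, totals[col.name])))
            profiles[tool] = jr.mean(axis=1)
        corr = tool_correlation(profiles) if union else pd.DataFrame()

        stab = None
        if run_stability:
            try:
                stab = participant_stability(jmat, fluid_samples, min_visits)
                frep["stability"] = {
                    "median_participant_cv": stab.median_participant_cv,
                    "median_global_cv": stab.median_global_cv,
                    "statistic": stab.statistic,
                    "pvalue": stab.pvalue,
                }
            except ValueError as exc:
                logger.warning("%s: stability skipped (%s)", fluid, exc)

        result.consensus[fluid] = consensus
        result.retained[fluid] = retained
        result.pattern_tables[fluid] = pattern
        result.prevalence[fluid] = tiers
        result.expression[fluid] = expression
        result.jrpm[fluid] = jmat
        result.clr_fractions[fluid] = clr_frac
        result.qc_samples[fluid] = qc
        result.prevalent_junctions[fluid] = prevalent
        result.annotations[fluid] = ann_df
        result.stability[fluid] = stab
        result.correlations[fluid] = corr
        report["biofluids"][fluid] = frep

        if out is not None:
            write_junction_bed(consensus, out / f"consensus_{fluid}.bed")
            pattern.to_csv(out / f"intersection_patterns_{fluid}.tsv",
                           sep="\t", index=False)
            tiers.to_csv(out / f"prevalence_tiers_{fluid}.tsv",
                         sep="\t", index=False)
            expression.to_csv(out / f"expression_{fluid}.tsv",
                              sep="\t", index=False)
            write_matrix(jmat, out / f"jrpm_matrix_{fluid}.tsv")
            ann_df.to_csv(out / f"annotation_{fluid}.tsv", sep="\t", index=False)
            corr.to_csv(out / f"tool_correlation_{fluid}.tsv", sep="\t")
            if stab is not None:
                stab.to_frame().to_csv(out / f"cv_{fluid}.tsv",
                                       sep="\t", index=False)
                stab.per_participant_tests.to_csv(
                    out / f"stability_tests_{fluid}.tsv", sep="\t", index=False)

    if {"plasma", "urine"} <= set(result.consensus):
        shared, n_shared, frac = biofluid_overlap(
            result.consensus["plasma"], result.consensus["urine"]
        )
        result.overlap = {
            "shared": shared, "n_shared": n_shared,
            "fraction_of_urine": frac,
            "fraction_of_urine_pct": round(frac * 100, 1) if frac is not None else None,
        }
        report["overlap"] = {
            "n_shared": n_shared,
            "fraction_of_urine_pct": result.overlap["fraction_of_urine_pct"],
        }

    result.report = report
    if out is not None:
        with (out / "run_report.json").open("w") as fh:
            json.dump(report, fh, indent=1, default=str)
    return result
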