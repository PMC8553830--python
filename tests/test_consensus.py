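import numpy as np
import pandas as pd
import pytest

from circfluid.consensus import (
    FilterConfig,
    biofluid_overlap,
    detect,
    intersect_tools,
    prevalence_filter,
    prevalence_table,
    retain_tool_junctions,
    sample_qc,
)
from circfluid.io import SampleMeta, ToolCall
from circfluid.junctions import TOOLS, BackspliceJunction

from conftest import retained_sets


def _meta(sid, pid="P01", fluid="plasma"):
    return SampleMeta(sid, pid, fluid, 1, 100_000, 100)


def _call(tool, sid, start, count):
    return ToolCall(tool, sid, BackspliceJunction("chr1", start, start + 100), count)


class TestDetect:
    samples = [_meta(f"s{i}") for i in range(6)]

    @pytest.mark.parametrize("count,expected", [(2, True), (1, False), (0, False)])
    def test_min_reads_boundary(self, count, expected):
        calls = [_call("ciri2", "s0", 100, count)] if count else []
        m = detect(calls, self.samples, FilterConfig())
        if count:
            assert bool(m.detected.loc["chr1:100-200", "s0"]) is expected
        else:
            assert m.detected.empty or not m.detected.any().any()

    def test_duplicate_reports_are_summed(self):
        calls = [_call("ciri2", "s0", 100, 1), _call("ciri2", "s0", 100, 1)]
        m = detect(calls, self.samples)
        assert m.counts.loc["chr1:100-200", "s0"] == 2
        assert m.detected.loc["chr1:100-200", "s0"]

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError):
            detect([_call("ciri2", "zz", 100, 3)], self.samples)

    def test_mixed_tools_rejected(self):
        calls = [_call("ciri2", "s0", 100, 3), _call("dcc", "s0", 100, 3)]
        with pytest.raises(ValueError):
            detect(calls, self.samples)


class TestRetain:
    def test_min_samples_boundary(self):
        samples = [_meta(f"s{i}") for i in range(8)]
        calls = [_call("knife", f"s{i}", 100, 5) for i in range(5)]
        calls += [_call("knife", f"s{i}", 900, 5) for i in range(4)]
        retained, summary = retain_tool_junctions(detect(calls, samples))
        assert retained == {"chr1:100-200"}  # 5 samples kept, 4 dropped
        assert summary["total_circRNA"] == 1

    def test_noiseless_retained_equals_truth(self, noiseless_manifest):
        """With dropout and FP off, every tool retains exactly the planted
        truth set."""
        for fluid in ("plasma", "urine"):
            truth = noiseless_manifest.truth_keys(fluid)
            for tool, kept in retained_sets(noiseless_manifest, fluid).items():
                assert kept == truth, tool


class TestIntersect:
    def test_identical_sets(self):
        sets = {t: {"a", "b", "c"} for t in TOOLS}
        consensus, table = intersect_tools(sets)
        assert consensus == {"a", "b", "c"}
        full = table[table["n_tools"] == 6]
        assert full["exclusive_count"].sum() == 3

    def test_one_empty_set_empties_consensus(self):
        sets = {t: {"a"} for t in TOOLS}
        sets["mapsplice"] = set()
        consensus, _ = intersect_tools(sets)
        assert consensus == set()

    def test_exclusive_pattern_semantics(self):
        sets = {t: {"A", "B"} for t in TOOLS}
        sets["mapsplice"] = {"A"}
        consensus, table = intersect_tools(sets)
        assert consensus == {"A"}
        five = table[(table["n_tools"] == 5) & (~table["mapsplice"])]
        assert five["exclusive_count"].sum() == 1  # B sits in the 5-tool pattern
        assert table["exclusive_count"].sum() == 2  # each junction counted once

    def test_missing_tool_rejected_but_min_tools_relaxes(self):
        sets = {t: {"a"} for t in TOOLS[:5]}
        with pytest.raises(ValueError):
            intersect_tools(sets)
        sets[TOOLS[5]] = set()
        consensus, _ = intersect_tools(sets, min_tools=5)
        assert consensus == {"a"}

    def test_consensus_bounded_by_smallest_retained_set(self, default_manifest):
        for fluid in ("plasma", "urine"):
            sets = retained_sets(default_manifest, fluid)
            consensus, _ = intersect_tools(sets)
            assert len(consensus) <= min(len(s) for s in sets.values())

    def test_dropout_only_shrinks_consensus(self, noiseless_manifest,
                                            default_manifest):
        """Adding per-tool dropout can only shrink the consensus."""
        clean, _ = intersect_tools(retained_sets(noiseless_manifest, "plasma"))
        noisy_sets = retained_sets(default_manifest, "plasma")
        noisy_truth_only = {
            t: s & noiseless_manifest.truth_keys("plasma")
            for t, s in noisy_sets.items()
        }
        # not the same simulation draw, but the subset property holds per tool
        for t in TOOLS:
            sub = {u: noisy_truth_only[u] for u in TOOLS}
            sub[t] = set(list(sub[t])[: len(sub[t]) // 2])
            smaller, _ = intersect_tools(sub)
            bigger, _ = intersect_tools(noisy_truth_only)
            assert smaller <= bigger


class TestPrevalence:
    def test_tiers_non_increasing_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_j, n_s = rng.integers(1, 40), rng.integers(1, 30)
            det = pd.DataFrame(rng.random((n_j, n_s)) < rng.random())
            tiers = prevalence_table(det)
            counts = tiers["n_junctions"].to_numpy()
            assert (np.diff(counts) <= 0).all()

    def test_planted_prevalences(self):
        """Junctions present in 100%, 55% and 15% of 20 samples land in the
        tiers direct enumeration predicts."""
        det = pd.DataFrame(False, index=["j100", "j55", "j15"],
                           columns=[f"s{i}" for i in range(20)])
        det.loc["j100"] = True
        det.loc["j55", det.columns[:11]] = True
        det.loc["j15", det.columns[:3]] = True
        tiers = prevalence_table(det).set_index("threshold")["n_junctions"]
        assert tiers[0.1] == 3   # 3/20 = 15% >= 10%
        assert tiers[0.2] == 2   # j15 drops out
        assert tiers[0.5] == 2   # 11/20 = 55%
        assert tiers[0.6] == 1
        assert tiers[1.0] == 1

    def test_always_detected_junction_counts_in_every_tier(self):
        det = pd.DataFrame(True, index=["j"], columns=["a", "b", "c"])
        tiers = prevalence_table(det)
        assert (tiers["n_junctions"] == 1).all()


class TestBiofluidOverlap:
    def test_identical_and_disjoint(self):
        assert biofluid_overlap({"a"}, {"a"})[2] == 1.0
        assert biofluid_overlap({"a"}, {"b"})[2] == 0.0

    def test_published_worked_example(self):
        """61 of 72 urine junctions shared with plasma reports as 84.7%."""
        urine = {f"u{i}" for i in range(72)}
        plasma = {f"u{i}" for i in range(61)} | {f"p{i}" for i in range(900)}
        shared, n, frac = biofluid_overlap(plasma, urine)
        assert n == 61
        assert round(frac * 100, 1) == 84.7

    def test_empty_reference_set_is_not_applicable(self):
        assert biofluid_overlap({"a"}, set())[2] is None


class TestExpressionPrefilters:
    def test_sample_qc_boundary(self):
        det = pd.DataFrame(False, index=[f"j{i}" for i in range(300)],
                           columns=["keep", "drop"])
        det["keep"] = True
        det.loc[: "j298", "drop"] = True  # 299 detected
        assert sample_qc(det, min_circ=300) == ["keep"]

    def test_sample_qc_all_removed_is_hard_error(self):
        det = pd.DataFrame(False, index=["j"], columns=["a"])
        with pytest.raises(ValueError):
            sample_qc(det, min_circ=1)

    def test_prevalence_filter_keeps_exact_half(self):
        det = pd.DataFrame(
            [[True, True, False, False], [True, False, False, False]],
            index=["half", "quarter"], columns=list("abcd"),
        )
        assert prevalence_filter(det, 0.5) == ["half"]

    def test_prefilters_match_enumeration(self, default_manifest):
        counts = default_manifest.true_counts["plasma"]
        det = counts >= 2
        kept = sample_qc(det, min_circ=50)
        brute = [s for s in det.columns if sum(det[s]) >= 50]
        assert kept == brute
        prev = prevalence_filter(det[kept], 0.5)
        brute_prev = [
            j for j in det.index
            if sum(det.loc[j, kept]) / len(kept) >= 0.5
        ]
        assert prev == brute_prev
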