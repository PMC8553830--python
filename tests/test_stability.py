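import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circfluid.datasets import validation_panel
from circfluid.io import SampleMeta
from circfluid.junctions import TOOLS
from circfluid.simulate import GeneratorConfig, simulate_truth
from circfluid.stability import (
    cv,
    participant_stability,
    rank_concordance,
    tool_correlation,
)


def _jrpm_from_manifest(manifest, fluid):
    counts = manifest.true_counts[fluid]
    totals = pd.Series({s.sample_id: s.total_junction_reads
                        for s in manifest.samples_of(fluid)})
    return counts / totals[counts.columns] * 1e6


class TestCv:
    def test_constant_vector(self):
        assert cv([5, 5, 5]) == 0.0

    def test_two_point_closed_form(self):
        # sd of [1, 3] with n-1 denominator is sqrt(2); mean is 2
        assert cv([1, 3]) == pytest.approx(math.sqrt(2) / 2, abs=1e-9)
        assert cv([1, 3]) == pytest.approx(0.7071, abs=1e-4)

    @settings(derandomize=True, max_examples=60)
    @given(values=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=20),
           c=st.floats(0.1, 100))
    def test_scale_invariance(self, values, c):
        if sum(values) / len(values) <= 0:
            return
        assert cv([c * v for v in values]) == pytest.approx(cv(values), rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cv([5.0])
        with pytest.raises(ValueError):
            cv([0.0, 0.0])


class TestParticipantStability:
    def test_participant_effects_lower_within_cv(self, default_manifest):
        """Participant-specific offsets with shared sampling noise give
        lower within-participant than global variability."""
        jm = _jrpm_from_manifest(default_manifest, "plasma")
        res = participant_stability(jm, default_manifest.samples_of("plasma"),
                                    min_visits=5)
        assert res.median_participant_cv < res.median_global_cv
        assert res.pvalue < 1e-4
        assert set(res.n_samples) > {"all"}
        assert not res.per_participant_tests.empty

    def test_null_model_is_not_degenerately_significant(self):
        """Without participant effects the test statistic must not be
        systematically extreme."""
        pvals = []
        for seed in range(6):
            m = simulate_truth(
                GeneratorConfig(participant_effect_sd=0.0), seed=200 + seed)
            jm = _jrpm_from_manifest(m, "plasma")
            res = participant_stability(jm, m.samples_of("plasma"))
            pvals.append(res.pvalue)
        assert max(pvals) > 1e-4  # at least some seeds are unremarkable

    def test_identical_samples_are_degenerate(self):
        samples = [SampleMeta(f"s{i}", "P01", "plasma", i + 1, 10**6, 0)
                   for i in range(5)]
        jm = pd.DataFrame(3.0, index=["chr1:1-100", "chr1:200-300"],
                          columns=[s.sample_id for s in samples])
        res = participant_stability(jm, samples, min_visits=5)
        assert (res.global_cvs == 0).all()
        assert math.isnan(res.pvalue)

    def test_no_eligible_participant_is_hard_error(self):
        samples = [SampleMeta("s1", "P01", "plasma", 1, 10**6, 0)]
        jm = pd.DataFrame(1.0, index=["chr1:1-100"], columns=["s1"])
        with pytest.raises(ValueError):
            participant_stability(jm, samples, min_visits=5)


class TestToolCorrelation:
    def test_identical_profiles_and_unit_diagonal(self):
        base = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        mat = tool_correlation({"ciri2": base, "knife": base.copy()})
        assert mat.loc["ciri2", "knife"] == pytest.approx(1.0)
        assert (np.diag(mat.to_numpy()) == 1.0).all()

    def test_zero_variance_pair_is_not_applicable(self):
        mat = tool_correlation({
            "ciri2": pd.Series([1.0, 2.0]),
            "knife": pd.Series([3.0, 3.0]),
        })
        assert math.isnan(mat.loc["ciri2", "knife"])

    def test_correlation_decreases_with_dropout(self):
        """All tools see the same truth counts; independent dropout pushes
        pairwise correlations below 1, monotonically in the rate."""
        mean_r = []
        for rate in (0.0, 0.15, 0.4):
            cfg = GeneratorConfig(dropout={t: rate for t in TOOLS},
                                  fp_rate={t: 0.0 for t in TOOLS})
            m = simulate_truth(cfg, seed=77)
            totals = {s.sample_id: s.total_junction_reads
                      for s in m.samples_of("plasma")}
            profiles = {}
            for tool, counts in m.tool_counts["plasma"].items():
                jr = counts.div(pd.Series(totals)[counts.columns], axis=1) * 1e6
                profiles[tool] = jr.mean(axis=1)
            mat = tool_correlation(profiles)
            off = mat.to_numpy()[~np.eye(6, dtype=bool)]
            mean_r.append(off.mean())
        assert mean_r[0] == pytest.approx(1.0, abs=1e-12)
        assert mean_r[0] > mean_r[1] > mean_r[2]


class TestRankConcordance:
    def _table(self, a, b):
        return pd.DataFrame({"mean_ct": a, "mean_jrpm": b})

    def test_identical_orderings(self):
        # lowest Ct = most abundant = highest JRPM
        _, _, rho = rank_concordance(self._table([20, 25, 30], [100, 10, 1]))
        assert rho == pytest.approx(1.0)

    def test_reversed_orderings(self):
        _, _, rho = rank_concordance(self._table([20, 25, 30], [1, 10, 100]))
        assert rho == pytest.approx(-1.0)

    def test_rho_equals_pearson_on_ranks(self):
        t = self._table([20, 31, 25, 28, 22], [5, 80, 2, 9, 40])
        ra, rb, rho = rank_concordance(t)
        assert rho == pytest.approx(float(np.corrcoef(ra, rb)[0, 1]))
        assert sorted(ra) == sorted(rb) == [1, 2, 3, 4, 5]

    def test_missing_values_ranked_last_in_order(self):
        t = self._table([20, math.nan, math.nan], [1, 2, 3])
        ra, _, _ = rank_concordance(t)
        assert list(ra) == [1, 2, 3]

    def test_all_missing_platform_rejected(self):
        with pytest.raises(ValueError):
            rank_concordance(self._table([math.nan] * 3, [1, 2, 3]))

    @pytest.mark.parametrize("fluid", ["plasma", "urine"])
    def test_published_panel_ranks_reproduced(self, fluid):
        """Re-ranking the published mean Ct and mean JRPM values reproduces
        the published per-platform ranks; the top plasma circRNA by JRPM is
        circMCU, followed by circFIP1L1-1 and circSIAE."""
        panel = validation_panel(fluid)
        ra, rb, rho = rank_concordance(panel)
        assert list(ra) == list(panel["qpcr_rank"])
        assert list(rb) == list(panel["rnaseq_rank"])
        if fluid == "plasma":
            top3 = panel.set_index("circRNA")["rnaseq_rank"]
            assert top3["circMCU"] == 1
            assert top3["circFIP1L1-1"] == 2
            assert top3["circSIAE"] == 3
        # the two platforms rank the panel discordantly
        assert abs(rho) < 0.5
        complete = panel.dropna(subset=["mean_ct"])
        ref = stats.spearmanr(complete["mean_ct"].rank(),
                              (-complete["mean_jrpm"]).rank()).statistic
        assert rho == pytest.approx(float(ref), abs=1e-12)
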