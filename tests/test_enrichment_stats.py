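"""Box summaries, rank tests and ANOVA against hand-computed values
and a permutation oracle."""


import numpy as np
import pytest

from chromaggr.enrichment_stats import (
    dunn_posthoc,
    enrichment_by_state,
    kruskal_wallis,
    one_way_anova,
    students_t,
    tukey_box_summary,
)
from chromaggr.intervals import GenomicInterval, StateSegmentation, ValidationError
from chromaggr.signal import counts_track


class TestTukeyBox:
    def test_odd_symmetric_data(self):
        s = tukey_box_summary([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)
        assert (s.lo_whisker, s.hi_whisker) == (1, 5)
        assert s.outliers == ()

    def test_constant_data(self):
        s = tukey_box_summary([5, 5, 5])
        assert s.median == s.q1 == s.q3 == s.lo_whisker == s.hi_whisker == 5
        assert s.outliers == ()

    def test_upper_outlier_pulls_whisker_to_data(self):
        s = tukey_box_summary([1, 2, 3, 4, 100])
        assert (s.q1, s.q3) == (2, 4)
        # fence at q3 + 1.5*IQR = 7; whisker is the extreme value inside
        assert s.hi_whisker == 4
        assert s.outliers == (100,)

    def test_whiskers_are_attained_values(self, rng):
        x = rng.standard_normal(100)
        s = tukey_box_summary(x)
        assert s.lo_whisker in x and s.hi_whisker in x
        assert s.lo_whisker <= s.q1 <= s.median <= s.q3 <= s.hi_whisker

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            tukey_box_summary([])


class TestKruskalWallis:
    def test_hand_value_without_ties(self):
        r = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert r.statistic == pytest.approx(7.2)
        assert r.df == 2

    def test_symmetric_groups_give_zero(self):
        r = kruskal_wallis([[1, 2, 3]] * 3)
        assert r.statistic == pytest.approx(0.0)

    def test_rank_invariance_under_monotone_map(self, rng):
        groups = [rng.standard_normal(6) for _ in range(3)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_all_identical_defined_as_null(self):
        r = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_agrees_with_permutation_oracle(self, rng):
        """Chi-square p approximates the permutation p on small N.

        The oracle computes H directly from the rank-sum formula
        (no ties in this instance) on random relabelings.
        """

        def h_stat(values):  # 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), n_i=3, N=9
            ranks = np.argsort(np.argsort(values)) + 1.0
            rsums = ranks.reshape(3, 3).sum(axis=1)
            return 12 / (9 * 10) * (rsums**2 / 3).sum() - 3 * 10

        groups = [[0.3, 1.7, 2.2], [0.9, 2.8, 3.5], [1.1, 4.0, 4.4]]
        pooled = np.concatenate(groups)
        obs = kruskal_wallis(groups)
        assert h_stat(pooled) == pytest.approx(obs.statistic)
        n_perm = 20_000
        count = sum(
            h_stat(rng.permutation(pooled)) >= obs.statistic - 1e-12
            for _ in range(n_perm)
        )
        p_perm = count / n_perm
        # chi-square approximation error dominates the MC error here
        assert obs.p_value == pytest.approx(p_perm, abs=0.06)


class TestDunn:
    def test_hand_z_extreme_pair(self):
        r = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        row = r.pairwise[r.pairwise["comparison"] == "group1 vs group3"].iloc[0]
        # mean ranks 2 and 8, N=9, var = 7.5*(2/3) = 5
        assert abs(row["z"]) == pytest.approx(6 / np.sqrt(5.0))

    def test_identical_groups_null(self):
        r = dunn_posthoc([[1, 2, 3]] * 3)
        assert np.allclose(r.pairwise["z"], 0)
        assert np.allclose(r.pairwise["p_adjusted"], 1)

    @pytest.mark.parametrize("adjustment", ["bonferroni", "sidak", "holm", "none"])
    def test_adjusted_p_never_below_raw(self, rng, adjustment):
        groups = [rng.standard_normal(8) + mu for mu in (0, 0.5, 1.2, 0.1)]
        r = dunn_posthoc(groups, adjustment=adjustment)
        assert (r.pairwise["p_adjusted"] >= r.pairwise["p"] - 1e-12).all()


class TestAnova:
    def test_equal_means_f_zero(self):
        r = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert r.statistic == pytest.approx(0.0)

    def test_hand_value(self):
        r = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert r.statistic == pytest.approx(1.5)
        assert r.df == (1, 4)

    def test_location_invariance(self, rng):
        groups = [rng.standard_normal(5) + mu for mu in (0, 1, 2)]
        a = one_way_anova(groups)
        b = one_way_anova([g + 100 for g in groups])
        assert a.statistic == pytest.approx(b.statistic)

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValidationError):
            one_way_anova([[1, 1], [2, 2]])

    def test_control_comparisons_table(self):
        r = one_way_anova(
            [[1, 2, 3], [4, 5, 6], [1.1, 2.1, 3.1]],
            control_index=0,
            labels=["ctrl", "kd1", "kd2"],
        )
        assert len(r.pairwise) == 2
        assert (r.pairwise["p_adjusted"] >= r.pairwise["p"] - 1e-12).all()


class TestStudentT:
    def test_identical_groups(self):
        r = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_hand_value(self):
        r = students_t([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3 / np.sqrt(2 / 3))

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(7) + 1
        assert students_t(a, b).statistic == pytest.approx(-students_t(b, a).statistic)

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(ValidationError):
            students_t([1, 1], [2, 2])


class TestEnrichmentByState:
    def make_seg(self):
        return StateSegmentation(
            [
                GenomicInterval("chr1", 0, 1000, name="active promoter"),
                GenomicInterval("chr1", 2000, 3000, name="active promoter"),
                GenomicInterval("chr1", 4000, 5000, name="weak promoter"),
            ],
            state_catalog={"active promoter", "weak promoter", "inactive promoter"},
        )

    def test_identical_tracks_give_unit_enrichment(self, rng):
        vals = rng.poisson(5, 50).astype(float)
        t = counts_track({"chr1": vals}, 100)
        table = enrichment_by_state(t, t, self.make_seg())
        for label in ("active promoter", "weak promoter"):
            np.testing.assert_allclose(table.groups[label], 1.0)

    def test_empty_states_present_with_empty_vectors(self, rng):
        t = counts_track({"chr1": rng.poisson(5, 50).astype(float)}, 100)
        table = enrichment_by_state(t, t, self.make_seg())
        assert table.groups["inactive promoter"].size == 0

    def test_single_state_single_segment(self):
        t = counts_track({"chr1": np.full(10, 3.0)}, 100)
        seg = StateSegmentation([GenomicInterval("chr1", 0, 1000, name="active promoter")])
        table = enrichment_by_state(t, t, seg)
        assert list(table.groups) == ["active promoter"]
        assert table.groups["active promoter"].size == 1


def test_null_calibration_small(rng):
    """Type-I error of the rank test near nominal alpha (small batch;
    the full 1000-simulation calibration runs in the acceptance suite)."""
    rejections = sum(
        kruskal_wallis([rng.standard_normal(10) for _ in range(3)]).p_value < 0.05
        for _ in range(200)
    )
    assert 2 <= rejections <= 22  # wide binomial band for n=200
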