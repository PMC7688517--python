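"""Mann-Whitney comparisons and their wrappers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from tcrep import (
    Clonotype,
    Group,
    Repertoire,
    RepertoireSet,
    ValidationError,
    compare_diversity,
    compare_tracked_frequency,
    mann_whitney,
)

from helpers import enumerated_mannwhitney_p

TRACKED = "CASGETGTNERLFF"


def cohort_from_freqs(resp_freqs, nonresp_freqs, depth=1000):
    """Cohort where each animal has the tracked clone at a given frequency."""
    reps = {}
    for i, f in enumerate(resp_freqs):
        aid = f"r{i}"
        clones = []
        tracked_count = round(f * depth)
        if tracked_count:
            clones.append(Clonotype(TRACKED, tracked_count))
        if depth - tracked_count:
            clones.append(Clonotype("CASSLGQAYEQYF", depth - tracked_count))
        reps[aid] = Repertoire(aid, clones, group=Group.RESPONDER)
    for i, f in enumerate(nonresp_freqs):
        aid = f"n{i}"
        clones = []
        tracked_count = round(f * depth)
        if tracked_count:
            clones.append(Clonotype(TRACKED, tracked_count))
        if depth - tracked_count:
            clones.append(Clonotype("CASSLGQAYEQYF", depth - tracked_count))
        reps[aid] = Repertoire(aid, clones, group=Group.NON_RESPONDER)
    return RepertoireSet(reps, tracked_clones=[TRACKED])


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        cmp = mann_whitney([1, 2, 3], [1, 2, 3], mode="exact")
        assert cmp.p_value == 1.0

    def test_complete_separation_small_sample(self):
        cmp = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert cmp.u_statistic == 0.0
        assert cmp.p_value == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)

    def test_two_sided_p_symmetric_under_group_swap(self):
        a, b = [0.1, 0.9, 2.2, 3.3], [1.5, 2.8, 4.1]
        assert mann_whitney(a, b).p_value == pytest.approx(
            mann_whitney(b, a).p_value
        )

    def test_exact_agrees_with_normal_approx_at_moderate_shift(self):
        rng = np.random.default_rng(5)
        a = list(rng.normal(0.7, 0.2, size=8))
        b = list(rng.normal(0.4, 0.2, size=5))
        p_exact = mann_whitney(a, b, mode="exact").p_value
        p_approx = mann_whitney(a, b, mode="normal_approx").p_value
        assert abs(p_exact - p_approx) < 0.02

    def test_auto_switches_to_approximation_with_ties(self):
        cmp = mann_whitney([1, 1, 2], [2, 3, 4], mode="auto")
        assert cmp.method == "asymptotic"
        cmp2 = mann_whitney([1.5, 2.5], [3.5, 4.5], mode="auto")
        assert cmp2.method == "exact"

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=6),
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_u_statistics_of_both_orientations_sum_to_product(self, a, b):
        u_a = mann_whitney(a, b).u_statistic
        u_b = mann_whitney(b, a).u_statistic
        assert u_a + u_b == pytest.approx(len(a) * len(b))
        assert 0 <= u_a <= len(a) * len(b)

    def test_exact_matches_enumeration_on_8_vs_5_shape(self):
        rng = np.random.default_rng(17)
        a = list(rng.normal(0.8, 0.2, size=8))
        b = list(rng.normal(0.3, 0.3, size=5))
        cmp = mann_whitney(a, b, mode="exact")
        assert cmp.p_value == pytest.approx(enumerated_mannwhitney_p(a, b), abs=1e-12)

    def test_upward_shift_never_raises_one_sided_evidence(self):
        # monotonicity of the one-sided 'a greater' p under location shift,
        # checked through the two-sided p of increasingly separated samples
        rng = np.random.default_rng(3)
        a = list(rng.normal(0, 1, size=6))
        b = list(rng.normal(0, 1, size=6))
        from scipy.stats import mannwhitneyu

        prev = 1.0
        for shift in (0.0, 1.0, 2.0, 4.0, 8.0):
            p = mannwhitneyu(
                [x + shift for x in a], b, alternative="greater", method="exact"
            ).pvalue
            assert p <= prev + 1e-12
            prev = p


class TestCompareTrackedFrequency:
    def test_reports_percentage_scale_means(self):
        rset = cohort_from_freqs([0.8, 0.9], [0.2, 0.3])
        cmp = compare_tracked_frequency(rset)
        assert cmp.group_means[0] == pytest.approx(85.0)
        assert cmp.group_means[1] == pytest.approx(25.0)

    def test_identical_constant_groups_give_p_one(self):
        rset = cohort_from_freqs([0.5, 0.5], [0.5, 0.5])
        cmp = compare_tracked_frequency(rset)
        assert cmp.p_value == 1.0
        assert cmp.group_means[0] == cmp.group_means[1]

    def test_complete_separation_gives_smallest_achievable_p(self):
        rset = cohort_from_freqs([1.0] * 8, [0.0] * 5)
        # all-tied-within-groups values force the approximation; use exact
        # on jittered ranks instead: frequencies 1.0 vs 0.0 are tied within
        # groups but fully separated between, so U is extremal
        cmp = compare_tracked_frequency(rset)
        assert cmp.u_statistic in (0.0, 40.0)
        rset2 = cohort_from_freqs(
            [0.9, 0.91, 0.92, 0.93, 0.94, 0.95, 0.96, 0.97],
            [0.1, 0.11, 0.12, 0.13, 0.14],
        )
        cmp2 = compare_tracked_frequency(rset2, mode="exact")
        assert cmp2.p_value == pytest.approx(2 / comb(13, 5), abs=1e-12)

    def test_missing_group_rejected(self):
        rset = cohort_from_freqs([0.5], [])
        with pytest.raises(ValidationError):
            compare_tracked_frequency(rset)


class TestCompareDiversity:
    def test_separated_entropies_give_extreme_u(self):
        reps = {}
        for i in range(3):
            aid = f"r{i}"
            reps[aid] = Repertoire(
                aid, [Clonotype("CASSLGQAYEQYF", 100)], group=Group.RESPONDER
            )
        for i in range(3):
            aid = f"n{i}"
            clones = [
                Clonotype(f"CASS{a}{b}GELFF", 1)
                for a in "ACDEFGHIKL"
                for b in "ACDEFGHIKL"
            ]
            reps[aid] = Repertoire(aid, clones, group=Group.NON_RESPONDER)
        rset = RepertoireSet(reps, tracked_clones=[TRACKED])
        cmp = compare_diversity(rset, alpha=1.0)
        assert cmp.group_means[0] == pytest.approx(0.0)
        assert cmp.group_means[1] == pytest.approx(math.log(100))
        assert cmp.u_statistic == 0.0

    def test_alpha_zero_compares_log_richness(self, small_cohort):
        rset = small_cohort.repertoire_set
        cmp = compare_diversity(rset, alpha=0.0)
        richness_a = [math.log(len(r)) for r in rset.by_group(Group.RESPONDER)]
        assert sorted(cmp.group_a_values) == pytest.approx(sorted(richness_a))

    def test_label_permutation_null_is_roughly_uniform(self):
        # on a null cohort (both groups from one distribution) the p-values
        # across label shuffles should not pile up near 0
        rng = np.random.default_rng(11)
        values = list(rng.normal(1.0, 0.3, size=13))
        pvals = []
        for _ in range(300):
            perm = rng.permutation(values)
            pvals.append(mann_whitney(list(perm[:8]), list(perm[8:])).p_value)
        assert np.mean(pvals) > 0.3
        assert np.mean(np.array(pvals) <= 0.05) < 0.15
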