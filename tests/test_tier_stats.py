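"""Enrichment statistics: presence filter, ratios, Significance A, Welch,
Benjamini-Hochberg, and the nested tier assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from lfqtier.errors import DegeneracyError, ValidationError
from lfqtier.tier_stats import (
    assign_tiers,
    benjamini_hochberg,
    classify_tiers,
    compute_ratios,
    presence_filter,
    signa_params,
    significance_a,
    welch_stage,
)

from conftest import make_design, make_matrix


def bh_stepup_oracle(p):
    """Independent BH by direct enumeration of the step-up definition:
    q_i = min over j with p_j >= p_i of m * p_j / rank_j, clipped at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    ranks = [0] * m
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    q = []
    for i in range(m):
        candidates = [
            m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]
        ]
        q.append(min(1.0, min(candidates)))
    return q


class TestPresenceFilter:
    def _matrix(self, bait_present, n_bait=6, n_control=6):
        row = [10.0 if b else None for b in bait_present]
        row += [10.0] * n_control
        names = [f"b{i + 1}" for i in range(n_bait)] + [
            f"c{i + 1}" for i in range(n_control)
        ]
        return make_matrix([row], sample_names=names)

    @pytest.mark.parametrize(
        "n_present,expected",
        [(6, True), (5, True), (4, True), (3, False), (0, False)],
    )
    def test_two_thirds_of_six_is_four(self, n_present, expected,
                                       six_rep_design):
        """With 6 bait replicates the 2/3 threshold is exactly 4 present."""
        present = [i < n_present for i in range(6)]
        m = self._matrix(present)
        assert presence_filter(m, six_rep_design)[0] == expected

    def test_control_samples_never_counted(self, six_rep_design):
        # present in all controls, only 1 bait sample: must fail
        m = self._matrix([True] + [False] * 5)
        assert not presence_filter(m, six_rep_design)[0]

    @pytest.mark.parametrize(
        "fraction,n_bait,threshold",
        [(2 / 3, 6, 4), (2 / 3, 3, 2), (0.5, 6, 3), (1.0, 4, 4),
         (0.66, 6, 4)],
    )
    def test_ceiling_thresholds(self, fraction, n_bait, threshold):
        """Threshold = ceil(fraction * n_bait) across replicate counts."""
        design = make_design(n_bait, 2)
        at = self._matrix([i < threshold for i in range(n_bait)],
                          n_bait=n_bait, n_control=2)
        below = self._matrix([i < threshold - 1 for i in range(n_bait)],
                             n_bait=n_bait, n_control=2)
        assert presence_filter(at, design, fraction)[0]
        assert not presence_filter(below, design, fraction)[0]

    def test_empty_matrix_rejected(self, six_rep_design):
        from lfqtier.io import LfqMatrix

        names = [f"b{i}" for i in range(1, 7)] + [
            f"c{i}" for i in range(1, 7)
        ]
        m = LfqMatrix(
            protein_ids=[], gene_symbols=[],
            intensities=np.empty((0, 12)), sample_names=names,
        )
        with pytest.raises(ValidationError):
            presence_filter(m, six_rep_design)


class TestComputeRatios:
    def _setup(self, bait, control):
        names = [f"b{i + 1}" for i in range(len(bait))] + [
            f"c{i + 1}" for i in range(len(control))
        ]
        m = make_matrix([list(bait) + list(control)], sample_names=names)
        return m, make_design(len(bait), len(control))

    def test_by_index_pairing(self):
        m, d = self._setup([8, 8, 8], [2, 2, 2])
        r = compute_ratios(m, d, pairing="by_index")
        np.testing.assert_allclose(r.replicate_log2_ratios[0], [2, 2, 2])
        assert r.summary_ratio[0] == pytest.approx(2.0)

    def test_missing_pair_dropped_without_imputation(self):
        m, d = self._setup([8, None, 8], [2, 2, 2])
        r = compute_ratios(m, d, pairing="by_index", imputation="none")
        assert np.isnan(r.replicate_log2_ratios[0][1])
        assert r.summary_ratio[0] == pytest.approx(2.0)
        assert r.n_present_bait[0] == 2

    def test_ratio_of_means(self):
        # log2 bait (4,2), control (2,4): means cancel
        m, d = self._setup([16, 4], [4, 16])
        r = compute_ratios(m, d, pairing="ratio_of_means")
        assert r.summary_ratio[0] == pytest.approx(0.0)

    def test_no_computable_ratio_is_missing(self):
        m, d = self._setup([None, None], [4, 4])
        r = compute_ratios(m, d)
        assert np.isnan(r.summary_ratio[0])

    def test_min_shift_imputation_fills_missing(self):
        names = ["b1", "b2", "c1", "c2"]
        m = make_matrix([[8, 8, 2, 2], [None, 4, 2, 2]],
                        sample_names=names)
        d = make_design(2, 2)
        r = compute_ratios(m, d, imputation="global_min_shift")
        # imputed bait value = min log2 of column b1 (=3) - 1 = 2
        assert r.replicate_log2_ratios[1][0] == pytest.approx(2 - 1)
        assert not np.isnan(r.summary_ratio[1])

    def test_design_sample_missing_from_matrix(self):
        m = make_matrix([[1, 2]], sample_names=["b1", "x"])
        d = make_design(1, 1)
        with pytest.raises(ValidationError, match="absent"):
            compute_ratios(m, d)


class TestSignAParams:
    def test_median_of_symmetric_triple(self):
        p = signa_params(np.array([-1.0, 0.0, 1.0]))
        assert p.r0 == 0.0

    def test_uniform_grid_percentiles(self):
        """Linear-interpolation percentiles on an explicit uniform grid."""
        grid = -5.0 + 0.001 * np.arange(10001)
        p = signa_params(grid)
        assert p.r1 == pytest.approx(-5.0 + 0.001 * 8413, abs=1e-9)
        assert p.r_minus1 == pytest.approx(-5.0 + 0.001 * 1587, abs=1e-9)
        assert p.r0 == pytest.approx(0.0, abs=1e-12)

    def test_constant_ratios_give_degenerate_anchors(self):
        p = signa_params(np.full(5, 3.25))
        assert p.r_minus1 == p.r0 == p.r1 == 3.25

    def test_fewer_than_three_finite_rejected(self):
        with pytest.raises(ValidationError, match="3"):
            signa_params(np.array([1.0, 2.0, np.nan]))


class TestSignificanceA:
    PARAMS = None

    def setup_method(self):
        from lfqtier.tier_stats import SignAParams
        self.params = SignAParams(r_minus1=-1.0, r0=0.0, r1=1.0)

    def test_at_median_p_is_half(self):
        p = significance_a(np.array([0.0]), self.params)
        assert p[0] == pytest.approx(0.5, abs=1e-12)

    def test_at_upper_anchor_p_is_normal_tail_at_one(self):
        expected = 0.5 * math.erfc(1 / math.sqrt(2))
        p = significance_a(np.array([1.0]), self.params)
        assert p[0] == pytest.approx(expected, abs=1e-9)
        assert p[0] == pytest.approx(0.158655, abs=1e-6)

    def test_below_median_clamped_to_one(self):
        p = significance_a(np.array([-10.0, -0.001]), self.params)
        assert p.tolist() == [1.0, 1.0]

    def test_missing_ratio_gives_nan(self):
        p = significance_a(np.array([np.nan, 2.0]), self.params)
        assert np.isnan(p[0]) and not np.isnan(p[1])

    def test_degenerate_spread_raises(self):
        degenerate = signa_params(np.full(5, 1.0))
        with pytest.raises(DegeneracyError, match="spread"):
            significance_a(np.array([1.0]), degenerate)

    @given(st.lists(st.floats(0.01, 50.0), min_size=2, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_nonincreasing_above_median(self, values):
        r = np.sort(np.array(values))
        p = significance_a(r, self.params)
        assert np.all(np.diff(p) <= 1e-15)


class TestWelchStage:
    def _ratios(self, replicate_rows, bait=None, control=None):
        from lfqtier.tier_stats import RatioTable
        replicate = np.array(replicate_rows, dtype=float)
        n = replicate.shape[0]
        if bait is None:
            bait = np.zeros((n, 2))
            control = np.zeros((n, 2))
        return RatioTable(
            protein_ids=[f"P{i}" for i in range(n)],
            replicate_log2_ratios=replicate,
            summary_ratio=np.nanmean(replicate, axis=1),
            n_present_bait=np.sum(~np.isnan(replicate), axis=1),
            bait_log2=np.asarray(bait, dtype=float),
            control_log2=np.asarray(control, dtype=float),
        )

    def test_one_sample_upper_tail_matches_integration_oracle(self):
        """t = 5.422 on df 3: compare with numeric integration of the
        t-density rather than the closed-form CDF."""
        r = self._ratios([[1.0, 2.0, 1.5, 2.5]])
        p = welch_stage(r, mode="one_sample_on_ratios")
        x = np.array([1.0, 2.0, 1.5, 2.5])
        t = x.mean() / (x.std(ddof=1) / 2.0)
        assert t == pytest.approx(5.4222, abs=1e-3)
        df = 3
        pdf = lambda u: (
            math.gamma((df + 1) / 2)
            / (math.sqrt(df * math.pi) * math.gamma(df / 2))
            * (1 + u * u / df) ** (-(df + 1) / 2)
        )
        oracle, _ = integrate.quad(pdf, t, np.inf)
        assert p[0] == pytest.approx(oracle, abs=1e-8)
        assert p[0] == pytest.approx(0.0062, abs=5e-4)

    def test_zero_variance_zero_mean_gives_one(self):
        r = self._ratios([[0.0, 0.0, 0.0, 0.0]])
        assert welch_stage(r)[0] == 1.0

    def test_zero_variance_positive_mean_gives_zero(self):
        r = self._ratios([[2.0, 2.0, 2.0]])
        assert welch_stage(r)[0] == 0.0

    def test_single_replicate_is_undefined(self):
        r = self._ratios([[1.5, np.nan, np.nan]])
        assert np.isnan(welch_stage(r)[0])

    def test_two_sample_identical_groups_gives_one(self):
        r = self._ratios(
            [[0.0, 0.0, 0.0]],
            bait=[[5.0, 5.0, 5.0]],
            control=[[5.0, 5.0, 5.0]],
        )
        assert welch_stage(r, mode="two_sample_welch")[0] == 1.0

    def test_two_sample_matches_scipy_welch(self):
        rng = np.random.default_rng(3)
        bait = rng.normal(1, 1, size=(1, 6))
        control = rng.normal(0, 2, size=(1, 6))
        r = self._ratios([[0.0] * 6], bait=bait, control=control)
        p = welch_stage(r, mode="two_sample_welch")
        expected = stats.ttest_ind(
            bait[0], control[0], equal_var=False, alternative="greater"
        ).pvalue
        assert p[0] == pytest.approx(expected, rel=1e-12)


class TestBenjaminiHochberg:
    def test_classic_stepup_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1, 1, 1]), 1.0)

    def test_nan_excluded_and_returned_nan(self):
        q = benjamini_hochberg([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        # m = 2 defined tests only
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_stepup_oracle(self, pvals):
        q = benjamini_hochberg(pvals)
        np.testing.assert_allclose(q, bh_stepup_oracle(pvals), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestAssignTiers:
    def test_all_gates_pass_is_tier1(self):
        t = assign_tiers([True], [0.01], [0.01])
        assert t[0] == "tier1"

    def test_welch_fail_is_tier2(self):
        t = assign_tiers([True], [0.01], [0.20])
        assert t[0] == "tier2"

    def test_signa_fail_is_tier3(self):
        t = assign_tiers([True], [0.20], [0.01])
        assert t[0] == "tier3"

    def test_presence_fail_is_none_regardless(self):
        t = assign_tiers([False], [0.001], [0.001])
        assert t[0] == "none"

    def test_undefined_q_never_qualifies(self):
        t = assign_tiers([True, True], [np.nan, 0.01], [0.01, np.nan])
        assert t.tolist() == ["tier3", "tier2"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            assign_tiers([True, False], [0.1], [0.1])

    @given(
        st.lists(
            st.tuples(
                st.booleans(),
                st.floats(0, 1),
                st.floats(0, 1),
            ),
            min_size=1,
            max_size=60,
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_nesting_property(self, rows):
        presence = [r[0] for r in rows]
        sq = [r[1] for r in rows]
        wq = [r[2] for r in rows]
        tier = assign_tiers(presence, sq, wq)
        for t, pres, s, w in zip(tier, presence, sq, wq):
            if t != "none":
                assert pres
            if t in ("tier1", "tier2"):
                assert s <= 0.05
            if t == "tier1":
                assert w <= 0.05


class TestClassifyTiers:
    def test_null_calibration_of_signa(self):
        """On pure-noise ratios the SignA p <= 0.05 fraction sits near 5%."""
        rng = np.random.default_rng(11)
        ratios = rng.standard_normal(10_000)
        params = signa_params(ratios)
        p = significance_a(ratios, params)
        frac = float(np.mean(p <= 0.05))
        assert 0.03 <= frac <= 0.07

    def test_pipeline_recovers_planted_signal(self, small_simulated):
        matrix, design, truth = small_simulated
        table = classify_tiers(matrix, design)
        tier1 = set(table.tier_ids("tier1"))
        recall = len(tier1 & truth.enriched_ids) / len(truth.enriched_ids)
        assert recall >= 0.8
        fdp = len(tier1 - truth.enriched_ids) / max(len(tier1), 1)
        assert fdp <= 0.15

    def test_stage_counts_are_nested(self, small_simulated):
        matrix, design, _ = small_simulated
        table = classify_tiers(matrix, design)
        counts = table.counts()
        n_presence = int(np.sum(table.presence_pass))
        assert matrix.n_proteins >= n_presence
        assert n_presence >= counts["tier1"] + counts["tier2"]
        assert (
            counts["tier1"] + counts["tier2"] + counts["tier3"] == n_presence
        )
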