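"""Agreement engine: RS, variance components, ICC, SDC, LoA, labels."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wqagree import (
    Thresholds,
    VarianceComponents,
    bland_altman_points,
    classify,
    evaluate_measure,
    icc_agreement,
    limits_of_agreement,
    sdc,
    spearman_rs,
    variance_components,
)
from wqagree.errors import InsufficientDataError, UndefinedStatisticError

from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def midranks(values):
    """Average-assigned ranks by direct enumeration."""
    values = np.asarray(values, dtype=float)
    ranks = np.empty(len(values))
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of midranks, via the raw covariance formula."""
    rx, ry = midranks(x), midranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def anova_oracle(data):
    """Explicit sums-of-squares decomposition of an n x k table."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (
        max((ss_rows / (n - 1) - ms_err) / k, 0.0),
        max((ss_cols / (k - 1) - ms_err) / n, 0.0),
        max(ms_err, 0.0),
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone_agreement(self):
        assert spearman_rs([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert spearman_rs([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_tied_values_use_midranks(self):
        # frozen from the rank-enumeration oracle
        value = spearman_rs([1, 2, 2, 4], [1, 3, 2, 4])
        assert value == pytest.approx(0.9486832980505139, abs=1e-12)
        assert value == pytest.approx(spearman_oracle([1, 2, 2, 4], [1, 3, 2, 4]))

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rs([1.0, 1.0, 1.0], [1, 2, 3])

    @given(
        x=st.lists(st.integers(0, 5), min_size=4, max_size=12),
        ymap=st.permutations(range(6)),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_oracle_and_bounds(self, x, ymap):
        y = [ymap[v] for v in x]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        rs = spearman_rs(np.array(x, float), np.array(y, float))
        assert -1.0 - 1e-12 <= rs <= 1.0 + 1e-12
        assert rs == pytest.approx(spearman_oracle(x, y), abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert spearman_rs(np.exp(x), y**3) == pytest.approx(
            spearman_rs(x, y), abs=1e-12
        )


# ---------------------------------------------------------------------------
# variance components and ICC
# ---------------------------------------------------------------------------

class TestVarianceComponents:
    def test_duplicate_columns_leave_only_object_variance(self):
        v = [0.1, 0.3, 0.5, 0.2]
        c = variance_components(make_table(v, v))
        assert c.sigma2_observers == pytest.approx(0.0, abs=1e-15)
        assert c.sigma2_residual == pytest.approx(0.0, abs=1e-15)
        assert c.sigma2_objects > 0

    def test_constant_table_has_no_variance(self):
        c = variance_components(make_table([0.2] * 4, [0.2] * 4))
        assert c.sigma2_objects == c.sigma2_observers == c.sigma2_residual == 0

    def test_three_visit_table_against_explicit_sums_of_squares(self):
        # frozen from the ANOVA-decomposition oracle:
        # SS_rows=427, SS_cols=1.5, SS_err=7 -> MS_err=3.5,
        # sigma2_objects=105, sigma2_observers=(1.5-3.5)/3 -> truncated to 0
        c = variance_components(
            make_table([10, 20, 30], [12, 18, 33], kind="score")
        )
        assert c.sigma2_objects == pytest.approx(105.0)
        assert c.sigma2_observers == 0.0
        assert c.sigma2_residual == pytest.approx(3.5)

    def test_exhaustive_oracle_equivalence_small_tables(self):
        """All 3x2 tables with entries in {0, 1, 2} match the brute-force
        sums-of-squares oracle exactly."""
        for cells in itertools.product(range(3), repeat=6):
            data = np.array(cells, float).reshape(3, 2)
            table = make_table(data[:, 0] / 2, data[:, 1] / 2)
            c = variance_components(table)
            expect = anova_oracle(np.column_stack([data[:, 0], data[:, 1]]) / 2)
            assert c.sigma2_objects == pytest.approx(expect[0], abs=1e-12)
            assert c.sigma2_observers == pytest.approx(expect[1], abs=1e-12)
            assert c.sigma2_residual == pytest.approx(expect[2], abs=1e-12)

    def test_too_few_visits_raise(self):
        with pytest.raises(InsufficientDataError):
            variance_components(make_table([0.1, 0.2], [0.1, 0.3]))


class TestICC:
    def test_direct_ratio(self):
        c = VarianceComponents(4, 1, 1, n_objects=10)
        assert icc_agreement(c) == pytest.approx(2 / 3, abs=1e-4)

    def test_perfect_reliability(self):
        assert icc_agreement(VarianceComponents(5, 0, 0, n_objects=10)) == 1.0

    def test_total_lack_of_reliability(self):
        assert icc_agreement(VarianceComponents(0, 2, 3, n_objects=10)) == 0.0

    def test_all_zero_components_not_computable(self):
        with pytest.raises(UndefinedStatisticError):
            icc_agreement(VarianceComponents(0, 0, 0, n_objects=10))

    @given(
        s_obj=st.floats(0.01, 10),
        s_obs=st.floats(0, 5),
        s_res=st.floats(0.01, 5),
        bump=st.floats(0.01, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_residual_variance(self, s_obj, s_obs, s_res, bump):
        """More residual noise strictly lowers ICC and raises SDC."""
        lo = VarianceComponents(s_obj, s_obs, s_res, n_objects=10)
        hi = VarianceComponents(s_obj, s_obs, s_res + bump, n_objects=10)
        assert icc_agreement(hi) < icc_agreement(lo)
        assert sdc(hi) > sdc(lo)


class TestSDC:
    def test_closed_form(self):
        c = VarianceComponents(1.0, 0.5, 1.5, n_objects=5)
        assert sdc(c) == pytest.approx(1.96 * np.sqrt(2) * np.sqrt(2.0))

    def test_zero_measurement_error(self):
        assert sdc(VarianceComponents(1.0, 0.0, 0.0, n_objects=5)) == 0.0

    def test_chained_from_component_oracle(self):
        table = make_table([10, 20, 30], [12, 18, 33], kind="score")
        c = variance_components(table)
        assert sdc(c) == pytest.approx(5.185672569686598, abs=1e-12)

    def test_literal_printed_variant_skips_the_square_root(self):
        c = VarianceComponents(1.0, 0.5, 1.5, n_objects=5)
        assert sdc(c, literal_formula=True) == pytest.approx(
            1.96 * np.sqrt(2) * 2.0
        )


# ---------------------------------------------------------------------------
# limits of agreement
# ---------------------------------------------------------------------------

class TestLimitsOfAgreement:
    def test_constant_difference_collapses_the_interval(self):
        a = np.array([0.10, 0.30, 0.50, 0.20])
        mean_d, lo, hi = limits_of_agreement(make_table(a, a - 0.05))
        assert (mean_d, lo, hi) == pytest.approx((0.05, 0.05, 0.05))

    def test_identical_observers(self):
        a = [0.1, 0.4, 0.3]
        assert limits_of_agreement(make_table(a, a)) == pytest.approx((0, 0, 0))

    def test_hand_computed_interval(self):
        # differences (-0.02, 0.00, 0.05, 0.01): mean 0.01, sd 0.0294392...
        a = np.array([0.10, 0.20, 0.30, 0.40])
        table = make_table(a, a - np.array([-0.02, 0.00, 0.05, 0.01]))
        mean_d, lo, hi = limits_of_agreement(table)
        assert mean_d == pytest.approx(0.01)
        assert lo == pytest.approx(-0.04770083766000859, abs=1e-12)
        assert hi == pytest.approx(0.06770083766000859, abs=1e-12)

    def test_sign_convention_observer_a_higher_is_positive(self):
        table = make_table([0.5, 0.6, 0.7], [0.4, 0.5, 0.6])
        mean_d, _, _ = limits_of_agreement(table)
        assert mean_d == pytest.approx(0.1)

    def test_halfwidth_matches_error_components_without_bias(self):
        """On a balanced zero-bias table the direct LoA half-width agrees
        with the components route 1.96*sqrt(2*(s2_obs + s2_res)): the
        observer component only absorbs the (here absent) mean shift."""
        rng = np.random.default_rng(11)
        truth = rng.normal(0.5, 0.15, size=400)
        a = truth + rng.normal(0, 0.05, 400)
        b = truth + rng.normal(0, 0.05, 400)
        table = make_table(a, b, kind="score")
        _, lo, hi = limits_of_agreement(table)
        c = variance_components(table)
        components_halfwidth = 1.96 * np.sqrt(
            2 * (c.sigma2_observers + c.sigma2_residual)
        )
        assert (hi - lo) / 2 == pytest.approx(components_halfwidth, rel=0.02)

    def test_bland_altman_points(self):
        table = make_table([0.4, 0.3], [0.6, 0.3])
        assert bland_altman_points(table) == [
            pytest.approx((0.5, -0.2)),
            pytest.approx((0.3, 0.0)),
        ]


# ---------------------------------------------------------------------------
# classification and composition
# ---------------------------------------------------------------------------

class TestClassify:
    def test_inclusive_boundaries(self):
        labels = classify(0.4, 0.4, 0.1, (-0.1, 0.1))
        assert labels == {
            "rs": "acceptable", "icc": "acceptable",
            "sdc": "acceptable", "loa": "acceptable",
        }

    def test_good_boundaries(self):
        labels = classify(0.7, 0.7, 0.0, (0.0, 0.0))
        assert labels["rs"] == "good" and labels["icc"] == "good"

    def test_rs_good_above_threshold(self):
        assert classify(0.75, 0.5, 0.05, (0, 0))["rs"] == "good"

    def test_loa_exceeding_either_bound_fails(self):
        assert classify(0.5, 0.5, 0.05, (-0.11, 0.09))["loa"] == "not acceptable"
        assert classify(0.5, 0.5, 0.05, (-0.09, 0.11))["loa"] == "not acceptable"

    def test_score_measures_threshold_on_the_normalised_scale(self):
        """A QBA-score SDC of 1.2 units over a 24.2-unit theoretical range
        is about 5 % and therefore acceptable."""
        labels = classify(0.5, 0.5, 1.2, (-1.0, 1.1), scale_divisor=24.2)
        assert labels["sdc"] == "acceptable"
        assert labels["loa"] == "acceptable"
        labels = classify(0.5, 0.5, 3.0, (-3.0, 1.0), scale_divisor=24.2)
        assert labels["sdc"] == "not acceptable"
        assert labels["loa"] == "not acceptable"


class TestEvaluateMeasure:
    def test_duplicate_column_table_is_perfect_end_to_end(self):
        v = [0.1, 0.3, 0.5, 0.2, 0.4]
        r = evaluate_measure(make_table(v, v))
        assert r.rs == pytest.approx(1.0)
        assert r.icc == pytest.approx(1.0)
        assert r.sdc == pytest.approx(0.0, abs=1e-12)
        assert (r.loa_lower, r.loa_upper) == pytest.approx((0.0, 0.0))
        assert r.labels == {
            "rs": "good", "icc": "good",
            "sdc": "acceptable", "loa": "acceptable",
        }

    def test_row_order_is_irrelevant(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(12), rng.random(12)
        r1 = evaluate_measure(make_table(a, b))
        perm = rng.permutation(12)
        r2 = evaluate_measure(make_table(a[perm], b[perm]))
        for attr in ("rs", "icc", "sdc", "loa_lower", "loa_upper"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr))

    def test_statistics_chain_the_component_oracles(self):
        table = make_table([10, 20, 30], [12, 18, 33], kind="score")
        r = evaluate_measure(table)
        assert r.icc == pytest.approx(105.0 / 108.5)
        assert r.sdc == pytest.approx(5.185672569686598)
        assert r.rs == pytest.approx(spearman_oracle([10, 20, 30], [12, 18, 33]))

    def test_affine_transform_of_both_columns(self):
        """a + b*x applied to both observers leaves RS and ICC unchanged
        and scales SDC and the LoA width by |b|."""
        rng = np.random.default_rng(9)
        truth = rng.normal(0, 1, 15)
        a = truth + rng.normal(0, 0.3, 15)
        b = truth + rng.normal(0, 0.3, 15)
        r1 = evaluate_measure(make_table(a, b, kind="score"))
        r2 = evaluate_measure(make_table(3 + 2 * a, 3 + 2 * b, kind="score"))
        assert r2.rs == pytest.approx(r1.rs)
        assert r2.icc == pytest.approx(r1.icc)
        assert r2.sdc == pytest.approx(2 * r1.sdc)
        assert r2.loa_upper - r2.loa_lower == pytest.approx(
            2 * (r1.loa_upper - r1.loa_lower)
        )
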