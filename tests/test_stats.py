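"""Statistics against independent closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.stats import t as t_dist

import perimem as pm
from perimem.errors import ParameterError
from perimem.measure import QC_OK


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t, written from the formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    sp2 /= na + nb - 2
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def pearson_oracle(x, y):
    """Direct covariance-formula Pearson r with its two-tailed t-based p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xd, yd = x - x.mean(), y - y.mean()
    r = (xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum())
    n = x.size
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, 2 * t_dist.sf(abs(t), n - 2)


def quartile_oracle(x, q):
    """Sort-and-linearly-interpolate quantile."""
    s = np.sort(np.asarray(x, float))
    pos = q * (s.size - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, s.size - 1)
    return s[lo] + (pos - lo) * (s[hi] - s[lo])


finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestSummarizeGroup:
    def test_hand_computable_five_values(self):
        s = pm.summarize_group([1, 2, 3, 4, 5], "g")
        assert (s.median_nm, s.q1_nm, s.q3_nm) == (3.0, 2.0, 4.0)
        assert (s.whisker_low_nm, s.whisker_high_nm) == (1.0, 5.0)
        assert s.n_points == 5

    def test_single_value_degenerate(self):
        s = pm.summarize_group([7.5], "g")
        assert s.median_nm == s.q1_nm == s.q3_nm == s.mean_nm == 7.5
        assert s.sd_nm == 0.0

    def test_translation_equivariance(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0]
        a = pm.summarize_group(x, "g")
        b = pm.summarize_group([v + 10.0 for v in x], "g")
        for f in ("mean_nm", "median_nm", "q1_nm", "q3_nm",
                  "whisker_low_nm", "whisker_high_nm"):
            assert getattr(b, f) == pytest.approx(getattr(a, f) + 10.0)
        assert b.sd_nm == pytest.approx(a.sd_nm)

    def test_whiskers_clip_to_most_extreme_inlier(self):
        x = [10.0, 11.0, 12.0, 13.0, 14.0, 100.0]  # one far outlier
        s = pm.summarize_group(x, "g")
        assert s.whisker_high_nm == 14.0
        assert s.q1_nm <= s.median_nm <= s.q3_nm

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(finite_floats, min_size=2, max_size=40))
    def test_quartiles_match_sort_interpolate_oracle(self, x):
        s = pm.summarize_group(x, "g")
        assert s.q1_nm == pytest.approx(quartile_oracle(x, 0.25), rel=1e-12, abs=1e-9)
        assert s.median_nm == pytest.approx(quartile_oracle(x, 0.5), rel=1e-12, abs=1e-9)
        assert s.q3_nm == pytest.approx(quartile_oracle(x, 0.75), rel=1e-12, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            pm.summarize_group([], "g")


class TestStudentT:
    def test_frozen_textbook_case(self):
        res = pm.student_t_two_tailed([1, 2, 3], [2, 3, 4])
        assert res.t_stat == pytest.approx(-1.224744871391589, abs=1e-9)
        assert res.df == 4
        assert res.p_two_tailed == pytest.approx(0.28786413472669053, abs=1e-9)
        assert res.method == "student_pooled"

    def test_identical_groups(self):
        res = pm.student_t_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0
        assert res.p_two_tailed == 1.0

    def test_swap_negates_t_preserves_p(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 3.0, 4.0, 6.0]
        r1 = pm.student_t_two_tailed(a, b)
        r2 = pm.student_t_two_tailed(b, a)
        assert r2.t_stat == pytest.approx(-r1.t_stat)
        assert r2.p_two_tailed == pytest.approx(r1.p_two_tailed)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(finite_floats, min_size=2, max_size=20),
        st.lists(finite_floats, min_size=2, max_size=20),
    )
    def test_matches_closed_form_oracle(self, a, b):
        assume(np.std(a) + np.std(b) > 1e-6)
        t, df, p = pooled_t_oracle(a, b)
        assume(np.isfinite(t))
        res = pm.student_t_two_tailed(a, b)
        assert res.t_stat == pytest.approx(t, rel=1e-9, abs=1e-9)
        assert res.df == df
        assert res.p_two_tailed == pytest.approx(p, rel=1e-9, abs=1e-9)

    def test_welch_differs_under_unequal_variances(self):
        a = [1.0, 1.1, 0.9, 1.05, 0.95]
        b = [2.0, 8.0, -3.0, 11.0, -6.0]
        pooled = pm.student_t_two_tailed(a, b, method="student_pooled")
        welch = pm.student_t_two_tailed(a, b, method="welch")
        assert welch.df < pooled.df

    def test_too_few_values_rejected(self):
        with pytest.raises(ParameterError):
            pm.student_t_two_tailed([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_positive_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pm.pearson_r(x, [2 * v + 1 for v in x])
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pm.pearson_r(x, [-v for v in x])
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_frozen_direct_formula_case(self):
        res = pm.pearson_r([1, 2, 3, 4], [1, 3, 2, 5])
        assert res.r == pytest.approx(0.8315218406202999, abs=1e-9)
        assert res.p_two_tailed == pytest.approx(0.16847815937970018, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(finite_floats, finite_floats), min_size=3, max_size=30))
    def test_matches_covariance_oracle(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        assume(np.std(x) > 1e-6 and np.std(y) > 1e-6)
        r, p = pearson_oracle(x, y)
        assume(np.isfinite(r) and abs(r) < 1 - 1e-12)
        res = pm.pearson_r(x, y)
        assert res.r == pytest.approx(r, rel=1e-9, abs=1e-9)
        assert res.p_two_tailed == pytest.approx(p, rel=1e-9, abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1 = pm.pearson_r(x, y).r
        r2 = pm.pearson_r(3.0 * x + 2.0, 0.5 * y - 7.0).r
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            pm.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def synthetic_table(distances, cell_ids, group="g"):
    rows = []
    per_cell_count = {}
    for d, cid in zip(distances, cell_ids):
        i = per_cell_count.get(cid, 0)
        per_cell_count[cid] = i + 1
        rows.append(
            {
                "source_id": cid, "group_label": group, "cell_id": cid,
                "segment_index": i, "arc_start_nm": 50.0 * i,
                "arc_end_nm": 50.0 * (i + 1), "distance_nm": d,
                "peak_im_nm": -d / 2, "peak_om_nm": d / 2,
                "prominence_im": 0.8, "prominence_om": 0.8,
                "qc_pass": True, "qc_reason": QC_OK,
            }
        )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def _tables(self, seed=0):
        rng = np.random.default_rng(seed)
        da = rng.normal(24.0, 1.0, size=120)
        db = rng.normal(21.0, 1.0, size=120)
        cells = [f"c{i//10}" for i in range(120)]
        return synthetic_table(da, cells, "wt"), synthetic_table(db, cells, "mut")

    def test_recovers_mean_difference_and_significance(self):
        ta, tb = self._tables()
        sa, sb, test, diff = pm.compare_groups(ta, tb, "wt", "mut")
        assert diff == pytest.approx(3.0, abs=0.5)
        assert test.p_two_tailed < 1e-6
        assert sa.n_points == sb.n_points == 120
        assert sa.n_cells == 12

    def test_identical_tables_give_zero_difference(self):
        ta, _ = self._tables()
        sa, sb, test, diff = pm.compare_groups(ta, ta.copy())
        assert diff == 0.0
        assert test.t_stat == 0.0
        assert test.p_two_tailed == 1.0

    def test_difference_antisymmetric_under_swap(self):
        ta, tb = self._tables()
        _, _, t1, d1 = pm.compare_groups(ta, tb)
        _, _, t2, d2 = pm.compare_groups(tb, ta)
        assert d2 == pytest.approx(-d1)
        assert t2.t_stat == pytest.approx(-t1.t_stat)

    def test_cell_pooling_collapses_to_cell_means(self):
        ta, tb = self._tables()
        sa, sb, _, _ = pm.compare_groups(ta, tb, pooling="cells")
        assert sa.n_points == 12  # one observation per cell

    def test_qc_failures_are_dropped_before_pooling(self):
        ta, tb = self._tables()
        ta.loc[:20, "qc_pass"] = False
        sa, _, _, _ = pm.compare_groups(ta, tb)
        assert sa.n_points == 120 - 21

    def test_empty_group_after_qc_rejected(self):
        ta, tb = self._tables()
        ta["qc_pass"] = False
        with pytest.raises(ParameterError):
            pm.compare_groups(ta, tb)


class TestEndToEndUnbiasedness:
    def test_difference_estimate_unbiased_over_seeds(self):
        """Small cohorts over many seeds: the mean of the pipeline's
        group-difference estimates stays within 0.2 nm of the constructed
        3-nm truth."""
        base = pm.EnvelopeSpec(length_nm=300.0, noise_sd=0.15)
        diffs = []
        for seed in range(10):
            _, _, report = pm.simulate_and_compare(
                4, 24.0, 21.0, 0.3, seed=seed, spec_base=base
            )
            diffs.append(report["mean_difference_nm"])
        assert abs(np.mean(diffs) - 3.0) <= 0.2
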