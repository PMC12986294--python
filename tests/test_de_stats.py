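import math

import numpy as np
import pandas as pd
import pytest

from mirquant.de_stats import (ALPHA_MIN, DEConfig, DesignSpec,
                               DifferentialExpression, bh_adjust,
                               classify_change, estimate_dispersion,
                               fit_nb_glm, power_two_sample_t, run_de,
                               size_factors_median_of_ratios, variance_filter,
                               wald_test)
from printed_tables import (CONCORDANCE_ROWS, CONTROL_ROWS, DISCREPANT_ROWS)


def oracle_bh(p):
    """Literal step-up: q_(i) = min_{j>=i} p_(j) m / j, clipped, input order."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


# ---------------------------------------------------------------------------
# Variance filter
# ---------------------------------------------------------------------------

class TestVarianceFilter:
    def test_uniform_variance_removes_nothing(self):
        counts = pd.DataFrame(
            {"s1": [1, 5, 9], "s2": [3, 7, 11]}, index=["a", "b", "c"])
        kept, removed = variance_filter(counts, 1.0)
        assert removed == [] and len(kept) == 3

    def test_constant_feature_removed(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(101, 4)))
        counts.iloc[7] = 33  # zero variance among positive variances
        _, removed = variance_filter(counts, 1.0)
        assert removed == [7]

    def test_matches_percentile_oracle(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(30, size=(200, 6)))
        kept, removed = variance_filter(counts, 1.0)
        variances = counts.var(axis=1, ddof=1).to_numpy()
        cutoff = np.percentile(variances, 1.0)
        expected = set(counts.index[variances < cutoff])
        assert set(removed) == expected
        assert len(kept) + len(removed) == 200

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            variance_filter(pd.DataFrame({"s1": [1, 2]}), 1.0)


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 30, 50], "s2": [10, 30, 50]})
        assert (size_factors_median_of_ratios(counts) == 1.0).all()

    def test_hand_computed_example(self):
        counts = pd.DataFrame({"s1": [10, 30, 50], "s2": [20, 60, 100]})
        factors = size_factors_median_of_ratios(counts)
        np.testing.assert_allclose(
            factors.to_numpy(), [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12)

    def test_scale_equivariance_exact(self):
        # multiplying one column by c multiplies its factor relative to the
        # others by exactly c; in absolute terms the column's own factor
        # picks up c^(1 - 1/m) and the rest c^(-1/m), because the per-feature
        # geometric means absorb c^(1/m) (cf. [[10,20],[30,60],[50,100]]
        # -> [1/sqrt2, sqrt2], where the doubled column gets sqrt2, not 2)
        rng = np.random.default_rng(2)
        m = 4
        counts = pd.DataFrame(rng.poisson(40, size=(50, m)) + 1)
        base = size_factors_median_of_ratios(counts)
        scaled = counts.copy()
        scaled[2] = scaled[2] * 3
        factors = size_factors_median_of_ratios(scaled)
        ratio = factors / base
        np.testing.assert_allclose(ratio[2] / ratio[0], 3.0, rtol=1e-12)
        np.testing.assert_allclose(factors[2], base[2] * 3 ** (1 - 1 / m),
                                   rtol=1e-12)
        np.testing.assert_allclose(factors.drop(2), base.drop(2) * 3 ** (-1 / m),
                                   rtol=1e-12)

    def test_no_everywhere_positive_feature_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="positive"):
            size_factors_median_of_ratios(counts)


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

class TestDispersion:
    groups20 = np.array(["a"] * 10 + ["b"] * 10)

    def test_poisson_counts_near_zero_dispersion(self):
        rng = np.random.default_rng(3)
        for mean in (50, 200):
            y = rng.poisson(mean, size=20).astype(float)
            alpha = estimate_dispersion(y, np.ones(20), self.groups20)
            assert alpha <= 0.01

    def test_nb_dispersion_recovery(self):
        # alpha = 0.5, mean 100, n = 50: estimate within [0.25, 0.9]
        # in at least 90% of replicates
        rng = np.random.default_rng(4)
        r, mu = 2.0, 100.0
        groups = np.array(["a"] * 50)
        inside = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.negative_binomial(r, r / (r + mu), size=50).astype(float)
            alpha = estimate_dispersion(y, np.ones(50), groups)
            inside += 0.25 <= alpha <= 0.9
        assert inside / n_rep >= 0.90

    def test_constant_counts_land_on_floor(self):
        y = np.full(8, 33.0)
        alpha = estimate_dispersion(y, np.ones(8),
                                    np.array(["a"] * 4 + ["b"] * 4))
        assert alpha == ALPHA_MIN

    def test_all_zero_feature_rejected(self):
        with pytest.raises(ValueError):
            estimate_dispersion(np.zeros(8), np.ones(8),
                                np.array(["a"] * 4 + ["b"] * 4))


# ---------------------------------------------------------------------------
# NB GLM and Wald test
# ---------------------------------------------------------------------------

X_TWO_GROUP = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])


class TestNbGlm:
    def test_closed_form_poisson_limit(self):
        y = np.array([10, 10, 10, 20, 20, 20], dtype=float)
        log2fc, se, flag = fit_nb_glm(y, X_TWO_GROUP, 1, np.ones(6), ALPHA_MIN)
        assert flag == ""
        assert log2fc == pytest.approx(1.0, abs=1e-6)

    def test_identical_groups_zero_effect(self):
        y = np.array([15, 15, 15, 15, 15, 15], dtype=float)
        log2fc, se, _ = fit_nb_glm(y, X_TWO_GROUP, 1, np.ones(6), ALPHA_MIN)
        stat, p = wald_test(log2fc, se)
        assert log2fc == pytest.approx(0.0, abs=1e-8)
        assert stat == pytest.approx(0.0, abs=1e-6) and p == pytest.approx(1.0)

    def test_offset_invariance(self):
        y = np.array([12, 8, 15, 30, 22, 28], dtype=float)
        a, _, _ = fit_nb_glm(y, X_TWO_GROUP, 1, np.ones(6), 0.1)
        b, _, _ = fit_nb_glm(y * 4, X_TWO_GROUP, 1, np.full(6, 4.0), 0.1)
        assert a == pytest.approx(b, rel=1e-6)

    def test_complete_separation_capped_and_flagged(self):
        y = np.array([0, 0, 0, 20, 25, 30], dtype=float)
        log2fc, _, flag = fit_nb_glm(y, X_TWO_GROUP, 1, np.ones(6), 0.1)
        assert flag == "separation" and log2fc == 30.0
        log2fc, _, flag = fit_nb_glm(y[::-1].copy(), X_TWO_GROUP, 1,
                                     np.ones(6), 0.1)
        assert flag == "separation" and log2fc == -30.0


class TestWald:
    def test_critical_value(self):
        _, p = wald_test(1.959964, 1.0)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_zero_effect_p_one(self):
        assert wald_test(0.0, 0.5)[1] == 1.0

    def test_zero_se_flagged_nan(self):
        stat, p = wald_test(1.0, 0.0)
        assert math.isnan(stat) and math.isnan(p)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.037]), [0.037])

    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_oracle_on_1000_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 51))
            np.testing.assert_allclose(bh_adjust(p), oracle_bh(p),
                                       rtol=1e-12, atol=1e-15)

    def test_output_bounds_and_order(self):
        rng = np.random.default_rng(6)
        p = np.sort(rng.uniform(size=30))
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        assert (np.diff(q) >= -1e-15).all()  # order-preserving on sorted input

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# Classification against the published tables
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mirna,log2fc,p,label",
                         CONCORDANCE_ROWS + CONTROL_ROWS,
                         ids=lambda v: str(v))
def test_classification_reproduces_published_labels(mirna, log2fc, p, label):
    assert classify_change(log2fc, p) == label


@pytest.mark.parametrize("group,mirna,log2fc,p,printed,under_rule",
                         DISCREPANT_ROWS, ids=lambda v: str(v))
def test_documented_discrepant_rows_follow_stated_rule(group, mirna, log2fc,
                                                       p, printed,
                                                       under_rule):
    """Rows whose printed label contradicts the |log2FC| > 0.6, p < 0.05
    rule: the implementation follows the stated rule, not the label."""
    assert classify_change(log2fc, p) == under_rule != printed


def test_classification_threshold_is_strict():
    assert classify_change(0.6, 0.01) == "no"
    assert classify_change(0.601, 0.05) == "no"   # p not below threshold
    assert classify_change(0.601, 0.049) == "up"


# ---------------------------------------------------------------------------
# run_de / model-results interface
# ---------------------------------------------------------------------------

def _two_group_design(samples, n_ref):
    return pd.DataFrame(
        {"condition": ["reference"] * n_ref
         + ["treatment"] * (len(samples) - n_ref)}, index=samples)


class TestRunDe:
    def test_identical_columns_nothing_classified(self):
        rng = np.random.default_rng(7)
        col = rng.poisson(60, size=40)
        counts = pd.DataFrame({f"s{i}": col for i in range(6)})
        res = run_de(counts, _two_group_design(counts.columns, 3))
        assert np.allclose(res.table["log2fc"], 0.0, atol=1e-8)
        assert (res.table["change"] == "no").all()

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.poisson(50, size=(60, 6)),
                              columns=[f"s{i}" for i in range(6)])
        design = _two_group_design(counts.columns, 3)
        res_a = run_de(counts, design)
        perm = ["s4", "s1", "s5", "s0", "s2", "s3"]
        res_b = run_de(counts[perm], design.loc[perm])
        pd.testing.assert_frame_equal(res_a.table, res_b.table)

    def test_paired_design_recovers_within_subject_effect(self):
        # 60 features, 10 with true log2FC = 1 post vs pre, strong
        # feature-specific subject baselines handled by subject fixed effects
        rng = np.random.default_rng(9)
        n_subj, n_feat, n_de = 6, 60, 10
        lam = rng.lognormal(np.log(80), 0.6, size=(n_feat, n_subj))
        lfc = np.zeros(n_feat)
        lfc[:n_de] = 1.0
        pre = rng.poisson(lam)
        post = rng.poisson(lam * 2.0 ** lfc[:, None])
        counts = pd.DataFrame(
            np.hstack([pre, post]),
            columns=[f"pre{i}" for i in range(n_subj)]
            + [f"post{i}" for i in range(n_subj)])
        design = pd.DataFrame({
            "condition": ["reference"] * n_subj + ["treatment"] * n_subj,
            "subject": [f"p{i}" for i in range(n_subj)] * 2,
        }, index=counts.columns)
        spec = DesignSpec(design, paired_col="subject")
        res = DifferentialExpression(counts, spec).fit()
        de_lfc = res.table.loc[[i for i in range(n_de)
                                if i in res.table.index], "log2fc"]
        null_lfc = res.table.loc[[i for i in range(n_de, n_feat)
                                  if i in res.table.index], "log2fc"]
        assert de_lfc.median() == pytest.approx(1.0, abs=0.25)
        assert abs(null_lfc.median()) < 0.25

    def test_interaction_contrast_isolates_group_time_effect(self):
        # only the treatment group's later time point shifts, and only for
        # the first 10 of 50 features; the interaction term isolates that
        # shift (the factor's baseline is its lexicographically first level)
        rng = np.random.default_rng(10)
        n, n_feat, n_de = 4, 50, 10
        base = rng.lognormal(np.log(100), 0.4, size=n_feat)
        lfc = np.zeros(n_feat)
        lfc[:n_de] = 1.5
        cols, cond, time = {}, [], []
        for grp in ("reference", "treatment"):
            for t in ("t0", "t1"):
                mult = 2.0 ** lfc if (grp, t) == ("treatment", "t1") \
                    else np.ones(n_feat)
                for i in range(n):
                    cols[f"{grp[:3]}_{t}{i}"] = rng.poisson(base * mult)
                    cond.append(grp)
                    time.append(t)
        counts = pd.DataFrame(cols)
        design = pd.DataFrame({"condition": cond, "time": time},
                              index=counts.columns)
        spec = DesignSpec(design, interaction_col="time")
        res = DifferentialExpression(counts, spec).fit()
        de_lfc = res.table.loc[[i for i in range(n_de)
                                if i in res.table.index], "log2fc"]
        assert de_lfc.median() == pytest.approx(1.5, abs=0.3)

    def test_results_surface(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.poisson(50, size=(30, 6)),
                              columns=[f"s{i}" for i in range(6)])
        res = run_de(counts, _two_group_design(counts.columns, 3))
        assert set(res.table.columns) >= {"base_mean", "log2fc", "lfc_se",
                                          "wald_stat", "p_unadj", "p_adj",
                                          "change"}
        assert (res.table["p_adj"] >= res.table["p_unadj"] - 1e-15).all()
        assert "median-of-ratios" in res.metadata
        summary = res.summary()
        assert "features tested" in summary and "log2fc" in summary
        volcano = res.volcano_table()
        assert list(volcano.columns) == ["log2fc", "neg_log10_p", "change"]


# ---------------------------------------------------------------------------
# Post-hoc power
# ---------------------------------------------------------------------------

class TestPower:
    def test_null_effect_equals_size(self):
        assert power_two_sample_t(6, 9, 0.0, 0.05) == pytest.approx(0.05)

    def test_published_pilot_value(self):
        assert round(power_two_sample_t(6, 9, 0.8, 0.05), 2) == 0.29

    def test_large_sample_limit(self):
        assert power_two_sample_t(1000, 1000, 0.8, 0.05) > 0.999

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_two_sample_t(1, 9, 0.8)
        with pytest.raises(ValueError):
            power_two_sample_t(6, 9, -0.1)
        with pytest.raises(ValueError):
            power_two_sample_t(6, 9, 0.8, alpha=0.0)
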