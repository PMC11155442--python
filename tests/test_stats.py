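"""Cohort statistics: t-tests, AUC/DeLong, cutoff metrics, accounting."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cervelast import (delong_ci, empirical_auc, filter_analysis_set,
                       generate_cohort, pooled_t_test, sens_spec_at_cutoff,
                       summarize_characteristics)
from cervelast.cohortgen import CohortConfig
from cervelast.stats import StatsError, CHARACTERISTICS_ROWS


def auc_by_pair_enumeration(scores, labels):
    """Independent oracle: exhaustive Mann-Whitney pair counting."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


class TestPooledTTest:
    @pytest.mark.parametrize("m1,s1,n1,m2,s2,n2", [
        (0.70, 0.26, 8, 1.63, 0.65, 119),   # average elasticity rows
        (82.7, 13.8, 8, 81.1, 17.9, 119),   # weight rows
        (4.2, 1.1, 5, 3.9, 0.8, 17),
    ])
    def test_matches_closed_form(self, m1, s1, n1, m2, s2, n2):
        """Pooled-variance Student t reproduced to near machine precision."""
        res = pooled_t_test(m1, s1, n1, m2, s2, n2)
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        t_ref = (m2 - m1) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_ref = 2.0 * sps.t.sf(abs(t_ref), n1 + n2 - 2)
        assert abs(abs(res.t_statistic) - abs(t_ref)) < 1e-10
        assert abs(res.p_value - p_ref) < 1e-12
        assert res.degrees_of_freedom == n1 + n2 - 2

    def test_identical_groups_give_t0_p1(self):
        res = pooled_t_test(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_cases(self):
        assert pooled_t_test(2.0, 0.0, 5, 2.0, 0.0, 5).p_value == 1.0
        with pytest.raises(StatsError):
            pooled_t_test(2.0, 0.0, 5, 3.0, 0.0, 5)

    def test_welch_variant_uses_satterthwaite_df(self):
        res = pooled_t_test(0.70, 0.26, 8, 1.63, 0.65, 119, method="welch")
        assert res.method == "welch"
        assert res.degrees_of_freedom < 125  # unequal variances shrink the df


class TestEmpiricalAuc:
    def test_worked_example_five_sixths(self):
        # positives' elasticities {0.5, 0.9}, negatives' {0.8, 1.2, 1.5}
        elast = np.array([0.5, 0.9, 0.8, 1.2, 1.5])
        labels = np.array([1, 1, 0, 0, 0], bool)
        assert empirical_auc(-elast, labels) == pytest.approx(5.0 / 6.0)

    def test_perfect_separation(self):
        assert empirical_auc([3, 4, 0, 1], [True, True, False, False]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert empirical_auc([1, 1, 1, 1], [True, False, True, False]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            empirical_auc([1.0, 2.0], [True, True])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0, 2.5]),
                              st.booleans()),
                    min_size=4, max_size=50))
    def test_equals_pair_enumeration_oracle_hypothesis(self, pairs):
        scores = np.array([s for s, _ in pairs])
        labels = np.array([l for _, l in pairs], bool)
        if labels.all() or not labels.any():
            return
        assert empirical_auc(scores, labels) == pytest.approx(
            auc_by_pair_enumeration(scores, labels), abs=1e-12)

    def test_equals_pair_enumeration_oracle(self):
        """Exact agreement with brute-force pair counting on random small sets."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(4, 51))
            scores = rng.choice(np.arange(10) / 3.0, size=n)  # forces ties
            labels = np.zeros(n, bool)
            labels[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = True
            assert empirical_auc(scores, labels) == pytest.approx(
                auc_by_pair_enumeration(scores, labels), abs=1e-12)


class TestDeLong:
    def test_se_agrees_with_bootstrap_oracle(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(1.0, 1.0, 12), rng.normal(0.0, 1.0, 18)])
        labels = np.repeat([True, False], [12, 18])
        res = delong_ci(scores, labels)
        pos, neg = scores[:12], scores[12:]
        boot = rng.integers(0, 12, (10_000, 12)), rng.integers(0, 18, (10_000, 18))
        aucs = (pos[boot[0]][:, :, None] > neg[boot[1]][:, None, :]).mean(axis=(1, 2))
        assert res.se == pytest.approx(aucs.std(ddof=1), rel=0.15)

    def test_duplicating_data_shrinks_se_not_auc(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2, 0.9, 0.5])
        labels = np.array([0, 0, 1, 1, 1, 0, 1, 0], bool)
        base = delong_ci(scores, labels)
        doubled = delong_ci(np.tile(scores, 2), np.tile(labels, 2))
        assert doubled.auc == pytest.approx(base.auc)
        assert doubled.se < base.se

    def test_perfect_separation_clips_and_flags(self):
        res = delong_ci([3.0, 4.0, 5.0, 0.0, 1.0, 2.0], [1, 1, 1, 0, 0, 0])
        assert res.auc == 1.0
        assert res.ci_high == 1.0
        assert res.degenerate

    def test_ci_ordering_and_clipping(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.uniform(size=40) < 0.4
        res = delong_ci(scores, labels)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0


class TestCutoffMetrics:
    def test_worked_example_two_thirds_sensitivity(self):
        elast = np.array([0.5, 0.9, 1.2, 2.0, 1.8, 1.4])
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        res = sens_spec_at_cutoff(elast, labels, cutoff=1.0)
        assert res.sensitivity == pytest.approx(2.0 / 3.0)
        assert res.specificity == 1.0

    def test_cutoff_below_all_values_gives_zero_sensitivity(self):
        res = sens_spec_at_cutoff([1.0, 2.0, 3.0], [True, True, False], cutoff=0.5)
        assert res.sensitivity == 0.0

    def test_tie_at_cutoff_counts_negative(self):
        res = sens_spec_at_cutoff([1.0, 0.5, 2.0], [True, True, False], cutoff=1.0)
        assert res.sensitivity == pytest.approx(0.5)  # the 1.0 tie is not predicted sPTB

    def test_clopper_pearson_seven_of_eight(self):
        """Exact binomial lower bound for 7/8 sensitivity is 0.473."""
        elast = np.concatenate([np.full(7, 0.5), [1.5], np.full(4, 2.0)])
        labels = np.repeat([True, False], [8, 4])
        res = sens_spec_at_cutoff(elast, labels, cutoff=1.0)
        assert res.sensitivity == pytest.approx(7 / 8)
        assert res.sens_ci[0] == pytest.approx(0.4735, abs=5e-4)

    def test_sensitivity_monotone_specificity_antitone_in_cutoff(self):
        rng = np.random.default_rng(5)
        elast = rng.uniform(0.2, 3.0, 60)
        labels = rng.uniform(size=60) < 0.3
        cuts = np.linspace(0.1, 3.5, 25)
        sens = [sens_spec_at_cutoff(elast, labels, c).sensitivity for c in cuts]
        spec = [sens_spec_at_cutoff(elast, labels, c).specificity for c in cuts]
        assert np.all(np.diff(sens) >= 0)
        assert np.all(np.diff(spec) <= 0)

    def test_large_cohort_sensitivity_matches_normal_model(self):
        """Sensitivity at 1.0 kPa/mm converges to the truncated-normal CDF value."""
        from cervelast.cohortgen import PRETERM_ELASTICITY as PE
        rng = np.random.default_rng(9)
        preterm = PE.sample_average(100_000, rng)
        term = np.full(100_000, 2.0)
        elast = np.concatenate([preterm, term])
        labels = np.repeat([True, False], 100_000)
        res = sens_spec_at_cutoff(elast, labels, cutoff=1.0)
        a = (PE.floor - PE.avg_mean) / PE.avg_sd
        expected = ((sps.norm.cdf((1.0 - PE.avg_mean) / PE.avg_sd) - sps.norm.cdf(a))
                    / (1.0 - sps.norm.cdf(a)))
        assert res.sensitivity == pytest.approx(expected, abs=0.005)


class TestAnalysisSetAndTable:
    def test_default_cohort_filters_to_127(self):
        cohort = generate_cohort(CohortConfig(), seed=0)
        analysis, accounting = filter_analysis_set(cohort)
        assert accounting["analyzed"] == 127
        assert len(analysis) == 127
        assert accounting["sptb"] / accounting["analyzed"] == pytest.approx(0.063, abs=0.001)

    def test_validation_only_cohort_132_minus_5(self):
        config = CohortConfig(n_development=0, n_no_show=0, n_lost_followup=0,
                              n_operator_error=0)
        _, accounting = filter_analysis_set(generate_cohort(config, seed=0))
        assert accounting["enrolled"] == 132
        assert accounting["analyzed"] == 127

    def test_cohort_without_exclusions_unchanged(self):
        config = CohortConfig(n_indicated=0, n_development=0, n_no_show=0,
                              n_lost_followup=0, n_operator_error=0)
        analysis, _ = filter_analysis_set(generate_cohort(config, seed=0))
        assert len(analysis) == 127

    def test_unknown_group_label_rejected(self):
        df = pd.DataFrame({"group": ["sptb", "mystery"]})
        with pytest.raises(StatsError):
            filter_analysis_set(df)

    def test_table_rows_match_printed_characteristics(self):
        cohort = generate_cohort(CohortConfig(), seed=0)
        analysis, _ = filter_analysis_set(cohort)
        # use the ground-truth columns as stand-ins for measured ones
        for stem in ("elasticity_anterior_kpa_mm", "elasticity_posterior_kpa_mm",
                     "elasticity_avg_kpa_mm", "length_anterior_mm",
                     "length_posterior_mm", "length_avg_mm"):
            analysis[stem] = analysis[f"true_{stem}"]
        table = summarize_characteristics(analysis)
        assert list(table["characteristic"]) == [label for label, *_ in CHARACTERISTICS_ROWS]
        ga_birth = table[table["characteristic"].str.startswith("Gestational age at birth")]
        assert float(ga_birth["p_value"].iloc[0]) < 1e-10

    def test_identical_groups_give_unit_pvalues(self):
        row = {"group": "sptb", "maternal_age_years": 30.0, "height_cm": 160.0,
               "weight_kg": 70.0, "parity": 1, "prior_ptb": False,
               "ga_exam_days": 180.0, "ga_birth_days": 250.0}
        rows = [dict(row), dict(row)]
        rows += [dict(row, group="term", ga_birth_days=250.0) for _ in range(2)]
        df = pd.DataFrame(rows)
        table = summarize_characteristics(df)
        cont = table.dropna(subset=["p_value"])
        assert (cont["p_value"] == 1.0).all()
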