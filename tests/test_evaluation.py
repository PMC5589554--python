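"""C-statistics, paired AUC comparison, calibration, risk-model fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from lungrisk.evaluation import (
    auc,
    compare_auc,
    evaluate_models,
    fit_risk_models,
    hosmer_lemeshow,
)
from lungrisk.grs import ScoreVector

from conftest import make_cohort


def brute_force_auc(scores, status):
    cases = scores[status == 1]
    ctrls = scores[status == 0]
    total = 0.0
    for c in cases:
        for d in ctrls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


def permutation_compare(scores_a, scores_b, status, reps=20_000, seed=0):
    """Sign-flip permutation null for the paired AUC difference."""
    rng = np.random.default_rng(seed)
    def d(sa, sb):
        a1, _, _ = auc(sa, status)
        a2, _, _ = auc(sb, status)
        return a1 - a2
    obs = abs(d(scores_a, scores_b))
    n = len(status)
    hits = 0
    for _ in range(reps):
        swap = rng.random(n) < 0.5
        sa = np.where(swap, scores_b, scores_a)
        sb = np.where(swap, scores_a, scores_b)
        if abs(d(sa, sb)) >= obs - 1e-12:
            hits += 1
    return hits / reps


class TestAuc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        status = np.r_[np.zeros(5, int), np.ones(5, int)]
        a, lo, hi = auc(scores, status)
        assert a == 1.0 and hi == 1.0

    def test_small_example_by_pair_enumeration(self):
        scores = np.array([0.9, 0.4, 0.5, 0.3])
        status = np.array([1, 1, 0, 0])
        a, _, _ = auc(scores, status)
        assert a == pytest.approx(0.75)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(21)
        scores = rng.integers(0, 20, 300).astype(float)  # heavy ties
        status = rng.integers(0, 2, 300)
        a, _, _ = auc(scores, status)
        assert a == pytest.approx(brute_force_auc(scores, status), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(22)
        scores = rng.random(200)
        status = rng.integers(0, 2, 200)
        a1, _, _ = auc(scores, status)
        a2, _, _ = auc(np.exp(5 * scores), status)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_is_error(self):
        with pytest.raises(ValueError):
            auc(np.arange(5.0), np.ones(5, int))


class TestCompareAuc:
    def test_self_comparison_degenerate(self):
        rng = np.random.default_rng(23)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        diff, p = compare_auc(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_monotone_transform_gives_zero_difference(self):
        rng = np.random.default_rng(24)
        s = rng.random(80)
        y = rng.integers(0, 2, 80)
        diff, p = compare_auc(np.log(s + 1.0), s, y)
        assert diff == 0.0 and p == 1.0

    def test_agrees_with_permutation_oracle_small_n(self):
        """n=30 paired instances: the asymptotic p tracks the exact
        sign-flip permutation p across 30 draws (the two can differ on a
        single draw, since one is asymptotic and one exact)."""
        from scipy.stats import spearmanr

        deltas, pd_all, pp_all = [], [], []
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            y = np.r_[np.ones(15, int), np.zeros(15, int)]
            lin = 0.8 * y + rng.normal(size=30)
            sa = expit(lin + 0.4 * rng.normal(size=30))
            sb = expit(0.7 * lin + 0.4 * rng.normal(size=30))
            _, p_delong = compare_auc(sa, sb, y)
            p_perm = permutation_compare(sa, sb, y, reps=4000, seed=s)
            deltas.append(abs(p_delong - p_perm))
            pd_all.append(p_delong)
            pp_all.append(p_perm)
        assert np.mean(deltas) < 0.06
        assert spearmanr(pd_all, pp_all).statistic > 0.9

    def test_added_noise_predictor_rarely_rejected(self):
        """B = A + pure noise: the paired test keeps its size."""
        rng = np.random.default_rng(26)
        rejections = 0
        for _ in range(200):
            y = rng.integers(0, 2, 150)
            base = y + rng.normal(size=150)
            noisy = base + 0.3 * rng.normal(size=150)
            _, p = compare_auc(base, noisy, y)
            if p < 0.05:
                rejections += 1
        assert rejections / 200 <= 0.10


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups_statistic_zero(self):
        # 4 groups, predicted prob equals group event rate exactly
        p = np.repeat([0.2, 0.4, 0.6, 0.8], 10)
        y = np.concatenate([
            np.r_[np.ones(2), np.zeros(8)],
            np.r_[np.ones(4), np.zeros(6)],
            np.r_[np.ones(6), np.zeros(4)],
            np.r_[np.ones(8), np.zeros(2)],
        ]).astype(int)
        stat, pval, groups = hosmer_lemeshow(p, y, groups=4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_hand_computed_two_group_statistic(self):
        p = np.r_[np.full(10, 0.3), np.full(10, 0.7)]
        y = np.r_[np.ones(5), np.zeros(5), np.ones(4), np.zeros(6)].astype(int)
        stat, _, groups = hosmer_lemeshow(p, y, groups=2)
        # group 1: O=5, E=3, n=10 ; group 2: O=4, E=7, n=10
        expected = (5 - 3) ** 2 / (3 * (1 - 0.3)) + (4 - 7) ** 2 / (7 * (1 - 0.7))
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_type_i_error_calibrated(self):
        """Well-specified logistic model: HL rejects ~5% of the time."""
        import statsmodels.api as sm

        rng = np.random.default_rng(27)
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(size=1000)
            y = (rng.random(1000) < expit(-0.5 + 0.8 * x)).astype(int)
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            _, pval, _ = hosmer_lemeshow(np.asarray(fit.predict()), y)
            if pval < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([0.0, 0.5]), np.array([0, 1]))


class TestRiskModels:
    def test_constant_smoking_is_degenerate_error(self):
        rng = np.random.default_rng(28)
        g = rng.binomial(2, 0.3, 60).astype(float)
        cohort = make_cohort(g[:, None], rng.integers(0, 2, 60),
                             smoking=np.ones(60, int))
        sv = ScoreVector(scores=pd.Series(g, index=cohort.genotypes.sample_ids),
                         weight_source="t", k=1, mode="weighted_sum")
        with pytest.raises(ValueError, match="smoking"):
            fit_risk_models(cohort, sv)

    def test_null_grs_coefficient_size_calibrated(self):
        """GRS independent of status: the extended model's GRS term is
        significant at 5% about 5% of the time."""
        rng = np.random.default_rng(29)
        hits = 0
        reps = 100
        for _ in range(reps):
            n = 400
            smoke = rng.integers(0, 2, n)
            y = (rng.random(n) < expit(-0.5 + 0.7 * smoke)).astype(int)
            g = rng.normal(size=n)
            cohort = make_cohort(
                np.clip(rng.binomial(2, 0.3, n)[:, None].astype(float), 0, 2),
                y, smoking=smoke)
            sv = ScoreVector(scores=pd.Series(g, index=cohort.genotypes.sample_ids),
                             weight_source="t", k=1, mode="weighted_sum")
            fits = fit_risk_models(cohort, sv)
            if abs(fits["extended"].tvalues[2]) > 1.96:
                hits += 1
        assert 0.02 <= hits / reps <= 0.10

    def test_smoking_or_recovered_within_ci(self):
        """Generator smoking OR 3: the epidemiologic model's CI covers it
        in most replicates."""
        from lungrisk.simulate import SimSpec, SimVariant, simulate_cohort

        covered = 0
        reps = 30
        for s in range(reps):
            spec = SimSpec(n_cases=500, n_controls=700,
                           variants=[SimVariant("rs1", "1", 100, 0.3, 1.2)],
                           smoking_or=3.0, prevalence=0.02, seed=4000 + s)
            bundle, _ = simulate_cohort(spec)
            sv = ScoreVector(
                scores=pd.Series(bundle.genotypes.dosages[:, 0],
                                 index=bundle.genotypes.sample_ids),
                weight_source="t", k=1, mode="weighted_sum")
            fits = fit_risk_models(bundle, sv)
            b = fits["epidemiologic"].params[1]
            se = fits["epidemiologic"].bse[1]
            if b - 1.96 * se <= np.log(3.0) <= b + 1.96 * se:
                covered += 1
        assert covered >= 26  # ~95% nominal coverage

    def test_evaluate_models_report_shape(self, table1_cohort):
        from lungrisk.grs import compute_grs
        from lungrisk.io_core import packaged_weight_table

        bundle, _ = table1_cohort
        sv = compute_grs(bundle.genotypes, packaged_weight_table(),
                         control_mask=bundle.control_mask)
        rep = evaluate_models(bundle, sv)
        t = rep.table.set_index("model")
        assert list(t.index) == ["epidemiologic", "genetic", "extended"]
        for _, row in t.iterrows():
            assert 0 <= row["ci_low"] <= row["auc"] <= row["ci_high"] <= 1
        # the combined model discriminates better than smoking alone
        assert t.loc["extended", "auc"] > t.loc["epidemiologic", "auc"]
        assert t.loc["extended", "p_vs_epidemiologic"] < 0.01
        assert rep.hl_stat >= 0
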