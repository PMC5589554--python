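"""HWE exact test, control MAF, LD r^2 and the filter/prune sequence."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from lungrisk.io_core import VariantRecord
from lungrisk.qc import (
    QcThresholds,
    apply_qc,
    compute_control_maf,
    genotype_counts,
    hwe_chisq_test,
    hwe_exact_test,
    ld_r2,
)
from lungrisk.simulate import SimSpec, SimVariant, simulate_genotypes

from conftest import make_cohort


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Direct-formula enumeration of the conditional heterozygote law."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n - n_a
    # P(h) = n! / (r! h! c!) * 2^h * n_a! n_A! / (2n)!
    logc = gammaln(n + 1) + gammaln(n_a + 1) + gammaln(n_A + 1) - gammaln(2 * n + 1)
    probs = {}
    for h in range(n_a % 2, min(n_a, n_A) + 1, 2):
        r = (n_a - h) // 2
        c = n - h - r
        lp = logc + h * np.log(2.0) - gammaln(r + 1) - gammaln(h + 1) - gammaln(c + 1)
        probs[h] = np.exp(lp)
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    p_obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHweExact:
    def test_mode_configuration_gives_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        assert hwe_exact_test(3, 5, 12) == pytest.approx(
            hwe_enumeration_oracle(3, 5, 12), abs=1e-12
        )

    def test_total_het_deficiency_is_extreme(self):
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_exhaustive_small_tables_match_oracle(self):
        for n in (7, 19, 30):
            for n_AA, n_Aa in itertools.product(range(n + 1), repeat=2):
                n_aa = n - n_AA - n_Aa
                if n_aa < 0:
                    continue
                assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                    hwe_enumeration_oracle(n_AA, n_Aa, n_aa), abs=1e-12
                ), (n_AA, n_Aa, n_aa)

    def test_all_zero_counts_is_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_rejection_rate_calibrated_under_hwe(self):
        """1,000 HWE variants at MAF 0.3, n=2,000: ~5% rejected at 0.05."""
        rng = np.random.default_rng(42)
        rejections = 0
        g = rng.binomial(2, 0.3, size=(1000, 2000))
        for row in g:
            nAA, nAa, naa = (row == 2).sum(), (row == 1).sum(), (row == 0).sum()
            if hwe_exact_test(nAA, nAa, naa) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_chisq_agrees_at_large_balanced_counts(self):
        exact = hwe_exact_test(450, 420, 130)
        chisq = hwe_chisq_test(450, 420, 130)
        assert abs(exact - chisq) < 0.05


class TestControlMaf:
    def test_monomorphic_low_and_high(self):
        status = np.zeros(4, int)
        assert compute_control_maf(np.zeros(4), status) == 0.0
        assert compute_control_maf(np.full(4, 2.0), status) == 0.0

    def test_folding_to_minor_frequency(self):
        status = np.zeros(4, int)
        assert compute_control_maf(np.array([0.0, 1, 1, 2]), status) == pytest.approx(0.5)

    def test_cases_excluded(self):
        dos = np.array([2.0, 2, 0, 0])
        status = np.array([1, 1, 0, 0])
        assert compute_control_maf(dos, status) == 0.0

    def test_no_controls_is_error(self):
        with pytest.raises(ValueError):
            compute_control_maf(np.array([1.0]), np.array([1]))


class TestLdR2:
    def test_identical_columns(self):
        x = np.array([0.0, 1, 2, 0])
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        assert ld_r2(np.array([0.0, 1, 2, 0]), np.array([2.0, 1, 0, 2])) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        x = np.array([0.0, 1, 2, 1, 0])
        y = np.array([0.0, 0, 2, 1, 1])
        r = np.corrcoef(x, y)[0, 1]
        assert ld_r2(x, y) == pytest.approx(r * r, abs=1e-12)

    def test_monomorphic_returns_nan(self):
        assert np.isnan(ld_r2(np.zeros(5), np.array([0.0, 1, 2, 1, 0])))


def _hwe_column(n, p):
    """Deterministic column with genotype counts at exact HWE proportions."""
    nAA = int(round(n * p * p))
    nAa = int(round(n * 2 * p * (1 - p)))
    return np.array([2.0] * nAA + [1.0] * nAa + [0.0] * (n - nAA - nAa))


class TestApplyQc:
    def build_toy(self):
        n = 200  # 100 controls then 100 cases
        good = _hwe_column(100, 0.3)
        cols = {
            "bad_info": np.concatenate([good, good]),
            "bad_maf": np.concatenate([np.r_[np.ones(8), np.zeros(92)],
                                       np.r_[np.ones(8), np.zeros(92)]]),
            "bad_hwe": np.concatenate([np.r_[np.full(50, 2.0), np.zeros(50)]] * 2),
            "pair_a": np.concatenate([good, good]),
            "pair_b": np.concatenate([good, good]),
        }
        variants = [
            VariantRecord("bad_info", "1", 10_000, "A", "B", "B", 0.3, info=0.7),
            VariantRecord("bad_maf", "1", 20_000, "A", "B", "B", 0.04, info=0.9),
            VariantRecord("bad_hwe", "1", 30_000, "A", "B", "B", 0.5, info=0.9),
            VariantRecord("pair_a", "2", 50_000, "A", "B", "B", 0.3, info=0.9),
            VariantRecord("pair_b", "2", 50_100, "A", "B", "B", 0.3, info=0.9),
        ]
        dosages = np.column_stack([cols[v.rsid] for v in variants])
        status = np.r_[np.zeros(100, int), np.ones(100, int)]
        return make_cohort(dosages, status, variants=variants)

    def test_toy_panel_keeps_single_variant(self):
        cohort = self.build_toy()
        assoc_p = {"bad_info": 0.5, "bad_maf": 0.5, "bad_hwe": 0.5,
                   "pair_a": 0.01, "pair_b": 0.02}
        kept, report = apply_qc(cohort, QcThresholds(), assoc_p)
        assert [v.rsid for v in kept] == ["pair_a"]
        t = report.table.set_index("rsid")["first_fail_rule"]
        assert t["bad_info"] == "info"
        assert t["bad_maf"] == "maf"
        assert t["bad_hwe"] == "hwe"
        assert t["pair_b"] == "ld"

    def test_vacuous_thresholds_keep_everything(self):
        cohort = self.build_toy()
        thr = QcThresholds(min_info=0.0, min_maf=0.0, min_hwe_p=0.0,
                           ld_r2=1.0, ld_window_bp=0)
        assoc_p = dict.fromkeys(cohort.genotypes.rsids, 0.5)
        kept, report = apply_qc(cohort, thr, assoc_p)
        assert len(kept) == 5
        assert report.stage_counts["ld"] == 5

    def test_correlated_pair_outside_window_both_kept(self):
        cohort = self.build_toy()
        thr = QcThresholds(min_info=0.0, min_maf=0.0, min_hwe_p=0.0,
                           ld_window_bp=50)  # pair is 100 bp apart
        assoc_p = dict.fromkeys(cohort.genotypes.rsids, 0.5)
        kept, _ = apply_qc(cohort, thr, assoc_p)
        assert {"pair_a", "pair_b"} <= {v.rsid for v in kept}

    def test_stage_counts_non_increasing(self):
        cohort = self.build_toy()
        _, report = apply_qc(cohort, QcThresholds(),
                             dict.fromkeys(cohort.genotypes.rsids, 0.5))
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        assert report.table["pass"].sum() + (~report.table["pass"]).sum() == 5

    def test_missing_assoc_p_for_survivor_is_error(self):
        cohort = self.build_toy()
        with pytest.raises(ValueError, match="pair_a"):
            apply_qc(cohort, QcThresholds(), {"pair_b": 0.02})

    def test_prune_order_stable_under_permutation(self, small_cohort):
        bundle, _ = small_cohort
        rng = np.random.default_rng(0)
        assoc_p = {r: float(p) for r, p in
                   zip(bundle.genotypes.rsids, rng.random(10))}
        thr = QcThresholds(min_maf=0.0, min_hwe_p=0.0, ld_r2=0.02,
                           ld_window_bp=10_000_000)
        baseline = None
        for perm_seed in range(4):
            order = np.random.default_rng(perm_seed).permutation(10)
            gm = bundle.genotypes.subset([bundle.genotypes.rsids[j] for j in order])
            cohort = make_cohort(gm.dosages, bundle.phenotypes.status,
                                 variants=gm.variants)
            kept, _ = apply_qc(cohort, thr, assoc_p)
            ids = sorted(v.rsid for v in kept)
            if baseline is None:
                baseline = ids
            assert ids == baseline
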