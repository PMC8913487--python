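import numpy as np
import pytest
from scipy import stats

import imputeval as iv
from imputeval.study_design import DesignConfig, _cell_probabilities


class TestBuildContingency:
    def test_hwe_carriers_at_p03(self):
        G = iv.hwe_genotype_counts(0.3, 100)  # (49, 42, 9)
        table = iv.build_contingency(G, G)
        assert table[0, 0] == pytest.approx(51.0)  # 1 - 0.7^2 = 0.51
        assert table[0, 1] == pytest.approx(49.0)

    def test_identical_groups_give_proportional_rows(self):
        t = iv.build_contingency(iv.hwe_genotype_counts(0.2, 60),
                                 iv.hwe_genotype_counts(0.2, 180))
        np.testing.assert_allclose(t[0] / t[0].sum(), t[1] / t[1].sum())

    def test_matches_hand_aggregation(self, rng):
        gc = rng.uniform(0, 50, 3)
        gt = rng.uniform(0, 50, 3)
        t = iv.build_contingency(gc, gt)
        np.testing.assert_allclose(
            t, [[gc[1] + gc[2], gc[0]], [gt[1] + gt[2], gt[0]]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            iv.build_contingency([-1, 2, 3], [1, 2, 3])


class TestChisqTest:
    def test_proportional_rows_give_zero(self):
        stat, p = iv.chisq_test([[30, 70], [60, 140]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_sum(self):
        O = np.array([[30.0, 70.0], [10.0, 90.0]])
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        expected = ((O - E) ** 2 / E).sum()
        stat, p = iv.chisq_test(O)
        assert stat == pytest.approx(expected)
        assert p == pytest.approx(stats.chi2.sf(expected, 1))

    def test_statistic_linear_in_total_at_fixed_proportions(self):
        s1, _ = iv.chisq_test([[30, 70], [10, 90]])
        s2, _ = iv.chisq_test([[60, 140], [20, 180]])
        assert s2 == pytest.approx(2 * s1)

    def test_zero_marginal_flagged(self):
        with pytest.raises(ValueError, match="marginal"):
            iv.chisq_test([[0, 0], [10, 90]])


class TestCohensW:
    def test_null_equals_alt_gives_zero(self):
        p = [0.25, 0.25, 0.25, 0.25]
        assert iv.cohens_w(p, p) == 0.0

    def test_closed_form_hand_evaluation(self):
        # carrier freqs 0.51 vs 0.36 at a 1:1 ratio
        p_alt, p_null = _cell_probabilities(0.51, 0.36, 0.5)
        expected = np.sqrt((((p_alt - p_null) ** 2) / p_null).sum())
        assert iv.cohens_w(p_alt, p_null) == pytest.approx(expected)
        assert expected == pytest.approx(
            np.sqrt(0.25 * (0.51 - 0.36) ** 2 * (1 / 0.435 + 1 / 0.565)))

    def test_symmetric_under_label_swap_at_equal_ratio(self):
        a = iv.cohens_w(*_cell_probabilities(0.51, 0.36, 0.5))
        b = iv.cohens_w(*_cell_probabilities(0.36, 0.51, 0.5))
        assert a == pytest.approx(b)


class TestPowerChisq:
    def test_zero_effect_gives_alpha(self):
        assert iv.power_chisq(0.0, 500, alpha=0.05) == pytest.approx(0.05)
        assert iv.power_chisq(0.0, 500, alpha=5e-8) == pytest.approx(5e-8)

    def test_power_approaches_one_for_large_n(self):
        assert iv.power_chisq(0.1, 10_000_000, alpha=5e-8) > 1 - 1e-9

    def test_strictly_increasing_in_n_and_w(self):
        # grids chosen below power saturation so strictness is meaningful
        ns = np.arange(200, 5000, 200)
        p = iv.power_chisq(0.15, ns, alpha=5e-8)
        assert (np.diff(p) > 0).all()
        ws = np.linspace(0.05, 0.3, 15)
        p = np.array([iv.power_chisq(w, 1500, alpha=5e-8) for w in ws])
        assert (np.diff(p) > 0).all()


class TestRequiredSampleSize:
    def test_equal_mafs_not_achievable(self):
        res = iv.required_sample_size(DesignConfig(0.2, 0.2))
        assert res.w == pytest.approx(0.0)
        assert not res.achievable

    def test_matches_exhaustive_scan_oracle(self):
        cfg = DesignConfig(0.3, 0.2)
        res = iv.required_sample_size(cfg)
        # independent scan: effect size from first principles, power per N
        q1, q0 = 1 - 0.7 ** 2, 1 - 0.8 ** 2
        qbar = (q1 + q0) / 2
        w = np.sqrt(0.25 * (q1 - q0) ** 2 * (1 / qbar + 1 / (1 - qbar)))
        crit = stats.chi2.ppf(1 - cfg.alpha, 1)
        required = None
        for n in range(cfg.n_min, cfg.n_max + 1):
            if 1 - stats.ncx2.cdf(crit, 1, n * w * w) >= 0.8:
                required = n
                break
        assert res.w == pytest.approx(w)
        assert res.required_n == required

    def test_imputed_regime_needs_at_least_as_many_samples(self, rng):
        """Randomized battery: HWE genotype counts pushed through any
        diagonally dominant channel never reduce the required N."""
        from test_error_model import random_stochastic
        from imputeval._binning import N_MAF_BINS
        for _ in range(25):
            P = np.repeat(random_stochastic(rng, diag_min=0.6)[None],
                          N_MAF_BINS, axis=0)
            em = iv.ErrorModel(matrices={"unfiltered": P.copy(), "filtered": P.copy()})
            case = round(rng.uniform(0.1, 0.45), 3)
            ctrl = round(rng.uniform(0.05, case - 0.04), 3)
            ratio = [(1, 1), (1, 3), (3, 1)][rng.integers(0, 3)]
            true_n = iv.required_sample_size(
                DesignConfig(case, ctrl, ratio=ratio)).required_n
            imp_n = iv.required_sample_size(
                DesignConfig(case, ctrl, ratio=ratio, regime="imputed"), em).required_n
            if np.isnan(true_n):
                assert np.isnan(imp_n)
            else:
                assert np.isnan(imp_n) or imp_n >= true_n


@pytest.fixture(scope="module")
def grid():
    return iv.run_design_grid(iv.parametric_error_model())


class TestDesignGrid:
    def test_full_grid_has_189_rows(self, grid):
        assert len(grid) == 189  # 21 MAF pairs x 3 ratios x 3 regimes
        assert grid["regime"].nunique() == 3

    def test_true_regime_delta_n_is_zero(self, grid):
        true_rows = grid[grid["regime"] == "true"]
        assert (true_rows["delta_n"].dropna() == 0).all()

    def test_equal_maf_pair_all_sentinel(self):
        df = iv.run_design_grid(iv.parametric_error_model(),
                                maf_pairs=[(0.2, 0.2)], ratios=((1, 1),))
        assert df["required_n"].isna().all()

    def test_filtered_channel_requires_no_more_than_unfiltered(self, grid):
        piv = grid.pivot_table(index=["case_maf", "control_maf", "ratio"],
                               columns="regime", values="required_n")
        both = piv.dropna(subset=["imputed", "filtered-imputed"])
        assert (both["filtered-imputed"] <= both["imputed"]).all()
        assert (both["imputed"] >= both["true"]).all()

    def test_balanced_ratio_is_most_efficient(self, grid):
        piv = grid.pivot_table(index=["case_maf", "control_maf", "regime"],
                               columns="ratio", values="required_n")
        for col in ("1:3", "3:1"):
            both = piv.dropna(subset=["1:1", col])
            assert (both[col] >= both["1:1"]).all()
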