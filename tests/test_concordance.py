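import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import imputeval as iv
from imputeval.concordance import ConfusionTable


def table(counts):
    return ConfusionTable(np.asarray(counts, dtype=float))


def kappa_oracle(counts):
    """Independent chance-corrected-agreement oracle: expand the table to
    label vectors and score with sklearn's Cohen's kappa."""
    from sklearn.metrics import cohen_kappa_score
    counts = np.asarray(counts, dtype=int)
    y_true, y_pred = [], []
    for g in range(3):
        for i in range(3):
            y_true += [g] * counts[g, i]
            y_pred += [i] * counts[g, i]
    return cohen_kappa_score(y_true, y_pred, labels=[0, 1, 2])


class TestConfusionTable:
    def test_diagonal_and_single_cell_placement(self):
        sites = [iv.VariantKey("1", 1, "A", "G")]
        t = iv.GenotypeMatrix(sites=sites, samples=list("abc"), calls=[[0, 1, 2]])
        i = iv.GenotypeMatrix(sites=sites, samples=list("abc"), calls=[[0, 1, 2]])
        mt = iv.MafTable(keys=sites, maf=[0.2], source="truth")
        [ct] = iv.confusion_table(t, i, mt)
        np.testing.assert_array_equal(ct.counts, np.eye(3))
        i2 = iv.GenotypeMatrix(sites=sites, samples=list("abc"), calls=[[0, 0, 2]])
        [ct2] = iv.confusion_table(t, i2, mt)
        assert ct2.counts[1, 0] == 1  # truth het imputed hom-ref

    def test_cells_match_brute_force_tally(self, rng):
        n_sites, n_samples = 400, 25
        sites = [iv.VariantKey("1", k + 1, "A", "G") for k in range(n_sites)]
        tc = rng.choice([-1, 0, 1, 2], p=[0.05, 0.6, 0.25, 0.1], size=(n_sites, n_samples))
        ic = rng.choice([-1, 0, 1, 2], p=[0.05, 0.6, 0.25, 0.1], size=(n_sites, n_samples))
        maf = rng.uniform(0, 0.5, n_sites)
        t = iv.GenotypeMatrix(sites=sites, samples=[f"s{j}" for j in range(n_samples)], calls=tc)
        i = iv.GenotypeMatrix(sites=sites, samples=t.samples, calls=ic)
        mt = iv.MafTable(keys=sites, maf=maf, source="truth")
        tables = {ct.maf_bin: ct.counts for ct in iv.confusion_table(t, i, mt)}
        from imputeval._binning import maf_bin_index
        expected = {}
        for s in range(n_sites):
            k = int(maf_bin_index(maf[s]))
            if k < 0:
                continue
            for j in range(n_samples):
                if tc[s, j] < 0 or ic[s, j] < 0:
                    continue
                expected.setdefault(k, np.zeros((3, 3)))[tc[s, j], ic[s, j]] += 1
        assert set(tables) == set(expected)
        for k in expected:
            np.testing.assert_array_equal(tables[k], expected[k])

    def test_mismatched_sites_instruct_to_intersect(self):
        s1 = [iv.VariantKey("1", 1, "A", "G")]
        s2 = [iv.VariantKey("1", 2, "A", "G")]
        t = iv.GenotypeMatrix(sites=s1, samples=["a"], calls=[[0]])
        i = iv.GenotypeMatrix(sites=s2, samples=["a"], calls=[[0]])
        mt = iv.MafTable(keys=s1, maf=[0.2], source="truth")
        with pytest.raises(ValueError, match="intersect"):
            iv.confusion_table(t, i, mt)


class TestIqs:
    def test_perfect_agreement_is_one(self):
        assert iv.iqs(table(np.diag([10, 10, 10]))).iqs == pytest.approx(1.0)

    def test_independent_margins_force_chance_level(self):
        s = iv.iqs(table([[8, 1, 1]] * 3))
        assert s.p_o == pytest.approx(1 / 3)
        assert s.p_c == pytest.approx(1 / 3)
        assert s.iqs == pytest.approx(0.0)

    def test_matches_kappa_oracle_on_reference_table(self):
        counts = [[90, 5, 5], [10, 80, 10], [2, 3, 45]]
        assert iv.iqs(table(counts)).iqs == pytest.approx(kappa_oracle(counts), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 200), min_size=9, max_size=9))
    def test_equals_kappa_oracle_on_random_tables(self, cells):
        counts = np.array(cells).reshape(3, 3)
        n = counts.sum()
        if n == 0:
            with pytest.raises(ValueError):
                iv.iqs(table(counts))
            return
        s = iv.iqs(table(counts))
        if s.iqs is None:  # single-cell table: chance explains everything
            assert s.p_c == pytest.approx(1.0)
        else:
            assert s.iqs == pytest.approx(kappa_oracle(counts), abs=1e-9)

    def test_iqs_one_iff_diagonal(self):
        assert iv.iqs(table([[5, 0, 0], [0, 3, 0], [0, 0, 2]])).iqs == pytest.approx(1)
        assert iv.iqs(table([[5, 1, 0], [0, 3, 0], [0, 0, 2]])).iqs < 1

    def test_independence_drives_iqs_to_zero(self, rng):
        n = 100_000
        pt = np.array([0.6, 0.3, 0.1])
        pi = np.array([0.55, 0.35, 0.1])
        t = rng.choice(3, size=n, p=pt)
        i = rng.choice(3, size=n, p=pi)
        counts = np.zeros((3, 3))
        np.add.at(counts, (t, i), 1)
        assert abs(iv.iqs(table(counts)).iqs) < 0.02


class TestGenotypeConcordance:
    def test_het_row_rate_normalization(self):
        counts = np.zeros((3, 3))
        counts[1] = [72, 908, 20]
        rates = iv.genotype_concordance(table(counts))
        np.testing.assert_allclose(rates.loc["het"], [0.072, 0.908, 0.020])

    def test_rows_sum_to_one_and_match_direct_division(self, rng):
        counts = rng.integers(1, 100, size=(3, 3)).astype(float)
        rates = iv.genotype_concordance(table(counts)).to_numpy()
        np.testing.assert_allclose(rates.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(rates, counts / counts.sum(axis=1, keepdims=True))

    def test_zero_row_flagged_nan(self):
        counts = np.zeros((3, 3))
        counts[0, 0] = 5
        rates = iv.genotype_concordance(table(counts))
        assert rates.loc["het"].isna().all()


class TestNonrefConcordance:
    def test_extremes(self):
        assert iv.nonref_concordance(table(np.diag([0, 50, 50]))) == pytest.approx(1.0)
        only_err = np.zeros((3, 3))
        only_err[1, 0] = 10
        assert iv.nonref_concordance(table(only_err)) == 0.0

    def test_both_denominator_conventions(self, rng):
        c = rng.integers(0, 50, size=(3, 3)).astype(float)
        ct = table(c)
        num = c[1, 1] + c[2, 2]
        assert iv.nonref_concordance(ct, "either") == pytest.approx(num / (c.sum() - c[0, 0]))
        assert iv.nonref_concordance(ct, "truth") == pytest.approx(num / c[1:].sum())


class TestMeanR2:
    def _pair(self, tc, ic, maf):
        n_sites, n_samples = np.shape(tc)
        sites = [iv.VariantKey("1", k + 1, "A", "G") for k in range(n_sites)]
        t = iv.GenotypeMatrix(sites=sites, samples=[f"s{j}" for j in range(n_samples)], calls=tc)
        i = iv.GenotypeMatrix(sites=sites, samples=t.samples, calls=ic)
        return t, i, iv.MafTable(keys=sites, maf=maf, source="truth")

    def test_identical_dosages_give_r2_one_and_constant_excluded(self):
        tc = np.array([[0, 1, 2, 1], [0, 0, 0, 0]], dtype=np.int8)
        t, i, mt = self._pair(tc, tc.copy(), [0.25, 0.25])
        df = iv.mean_r2(t, i, mt)
        assert df["mean_r2"].iloc[0] == pytest.approx(1.0)
        assert df["n_sites"].iloc[0] == 1
        assert df["n_excluded"].iloc[0] == 1

    def test_matches_per_site_corrcoef_oracle(self, rng):
        tc = rng.choice([-1, 0, 1, 2], p=[0.1, 0.5, 0.3, 0.1], size=(200, 40))
        ic = np.where(rng.random((200, 40)) < 0.8, tc, rng.integers(0, 3, (200, 40)))
        maf = rng.uniform(0.1, 0.2, 200)  # all in bins 10..19
        t, i, mt = self._pair(tc, ic, maf)
        df = iv.mean_r2(t, i, mt)
        from imputeval._binning import maf_bin_index
        per_bin = {}
        for s in range(200):
            mask = (tc[s] >= 0) & (ic[s] >= 0)
            if mask.sum() < 2 or tc[s][mask].std() == 0 or ic[s][mask].std() == 0:
                continue
            r = np.corrcoef(tc[s][mask], ic[s][mask])[0, 1]
            per_bin.setdefault(int(maf_bin_index(maf[s])), []).append(r ** 2)
        for _, row in df.iterrows():
            if row["n_sites"]:
                assert row["mean_r2"] == pytest.approx(
                    np.mean(per_bin[row["maf_bin"]]), abs=1e-10)


class TestAccuracyByGroup:
    @staticmethod
    def welch_oracle(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        return t, df

    def _frame(self, a, b):
        import pandas as pd
        rows = [{"maf_range": "(0,0.5]", "in_reference_panel": True,
                 "nonref_concordance": x} for x in a]
        rows += [{"maf_range": "(0,0.5]", "in_reference_panel": False,
                  "nonref_concordance": x} for x in b]
        return pd.DataFrame(rows)

    def test_identical_groups_t_zero_p_one(self):
        out = iv.accuracy_by_group(self._frame([1, 2, 3], [1, 2, 3]))
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_closed_form_welch_statistic(self):
        a, b = [0.95, 0.96, 0.94], [0.90, 0.91, 0.89]
        out = iv.accuracy_by_group(self._frame(a, b))
        t, df = self.welch_oracle(a, b)
        assert out["t"].iloc[0] == pytest.approx(t)
        assert out["df"].iloc[0] == pytest.approx(df)
        assert out["p_value"].iloc[0] < 0.05
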