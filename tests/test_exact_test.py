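import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from germscreen import SampleRole, ScreenConfig, bh_fdr, conditional_exact_test, nb_pmf
from germscreen.exact_test import run_contrast

from conftest import make_count_matrix
from oracles import bh_oracle, conditional_exact_oracle, nb_pmf_oracle


class TestNbPmf:
    def test_poisson_limit_at_zero_dispersion(self):
        assert nb_pmf(0, 1.0, 0.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_mass_sums_to_one(self):
        total = nb_pmf(np.arange(0, 4000), 20.0, 0.16).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_closed_form_nb(self):
        # size 1/phi = 6.25, mean 2: value frozen from an independent
        # lgamma-based evaluation of the NB mass function
        assert nb_pmf(2, 2.0, 0.16) == pytest.approx(0.23482971576636133, abs=1e-12)
        assert nb_pmf(2, 2.0, 0.16) == pytest.approx(nb_pmf_oracle(2, 2.0, 0.16), abs=1e-14)

    def test_variance_is_mean_plus_phi_mean_squared(self):
        y = np.arange(0, 20000)
        pm = nb_pmf(y, 50.0, 0.16)
        mean = (y * pm).sum()
        var = ((y - mean) ** 2 * pm).sum()
        assert mean == pytest.approx(50.0, rel=1e-9)
        assert var == pytest.approx(50.0 + 0.16 * 50.0**2, rel=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            nb_pmf(-1, 1.0, 0.16)


class TestConditionalExactTest:
    def test_balanced_mode_gives_p_one(self):
        assert conditional_exact_test(5, 5, 1e6, 1e6, 0.4) == pytest.approx(1.0)

    def test_zero_total_is_uninformative(self):
        assert conditional_exact_test(0, 0, 1e6, 1e6, 0.4) == 1.0

    def test_matches_enumeration_oracle_spot(self):
        p = conditional_exact_test(12, 0, 1e6, 1e6, 0.4)
        assert p == pytest.approx(conditional_exact_oracle(12, 0, 1e6, 1e6, 0.4), abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(1e6, 1e6), (1e6, 3e6)])
    @pytest.mark.parametrize("bcv", [0.0, 0.4])
    def test_matches_enumeration_oracle_small_grid(self, n1, n2, bcv):
        for s in range(0, 26):
            for y1 in range(s + 1):
                expected = conditional_exact_oracle(y1, s - y1, n1, n2, bcv)
                got = conditional_exact_test(y1, s - y1, n1, n2, bcv)
                assert got == pytest.approx(expected, abs=1e-10)

    @given(
        y1=st.integers(0, 30), y2=st.integers(0, 30),
        n1=st.integers(10**5, 5 * 10**6), n2=st.integers(10**5, 5 * 10**6),
        bcv=st.sampled_from([0.0, 0.2, 0.4]),
    )
    def test_symmetry_under_group_swap(self, y1, y2, n1, n2, bcv):
        a = conditional_exact_test(y1, y2, n1, n2, bcv)
        b = conditional_exact_test(y2, y1, n2, n1, bcv)
        assert a == pytest.approx(b, abs=1e-12)

    def test_more_extreme_observation_is_more_significant(self):
        ps = [conditional_exact_test(y1, 20 - y1, 1e6, 1e6, 0.4) for y1 in range(10, 21)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestBhFdr:
    def test_identical_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_hand_step_up_example(self):
        # q_i = min over j>=i of p_(j)*m/j: all collapse to 0.04
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_pvalue_identity(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_direct_definition_and_is_monotone(self, pvals):
        got = bh_fdr(pvals)
        expected = bh_oracle(pvals)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(np.asarray(got)[order]) >= -1e-12).all()
        assert (np.asarray(got) >= np.asarray(pvals) - 1e-12).all()


class TestRunContrast:
    def test_identical_columns_are_null(self):
        counts = [10, 200, 0, 55]
        cm = make_count_matrix({SampleRole.ovary_1_2: counts, SampleRole.larvae: counts})
        res = run_contrast(cm, SampleRole.ovary_1_2, SampleRole.larvae, ScreenConfig())
        assert (res.table["p_value"] == 1.0).all()
        assert (res.table["fdr"] == 1.0).all()

    def test_extreme_gene_attains_minimum_fdr(self):
        rng = np.random.default_rng(5)
        null = rng.integers(0, 30, size=1000)
        a = np.append(null, 1000)
        b = np.append(null, 0)
        cm = make_count_matrix({SampleRole.ovary_1_2: a.tolist(), SampleRole.larvae: b.tolist()})
        res = run_contrast(cm, SampleRole.ovary_1_2, SampleRole.larvae, ScreenConfig())
        assert res.table["fdr"].iloc[-1] == res.table["fdr"].min()
        assert res.table["logfc"].iloc[-1] > 0

    def test_logfc_sign_and_finiteness(self):
        cm = make_count_matrix(
            {SampleRole.ovary_1_2: [100, 0, 10], SampleRole.larvae: [0, 100, 10]}
        )
        res = run_contrast(cm, SampleRole.ovary_1_2, SampleRole.larvae, ScreenConfig())
        logfc = res.table["logfc"]
        assert np.isfinite(logfc).all()
        assert logfc.iloc[0] > 0 and logfc.iloc[1] < 0

    def test_planted_hundredfold_genes_reach_strict_fdr(self):
        """50 planted 100-fold ovary genes among 2000 at ~1e6 depth: at least
        48 must reach FDR < 0.001 in a single contrast."""
        rng = np.random.default_rng(42)
        n_null, n_planted = 1950, 50
        phi = 0.16
        base = rng.uniform(20, 200, size=n_null)
        def nb(mean):
            return rng.poisson(rng.gamma(1 / phi, mean * phi))
        y1 = np.concatenate([nb(base), nb(np.full(n_planted, 100 * 30.0))])
        y2 = np.concatenate([nb(base), nb(np.full(n_planted, 30.0))])
        cm = make_count_matrix(
            {SampleRole.ovary_1_2: y1.tolist(), SampleRole.larvae: y2.tolist()}
        )
        res = run_contrast(cm, SampleRole.ovary_1_2, SampleRole.larvae, ScreenConfig())
        planted_fdr = res.table["fdr"].iloc[n_null:]
        assert (planted_fdr < 0.001).sum() >= 48
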