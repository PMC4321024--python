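import numpy as np
import pandas as pd
import pytest

from germscreen import (
    CANONICAL_ROLE_ORDER,
    ConfigError,
    DataError,
    SampleRole,
    ScreenConfig,
    bloodmeal_class,
    follicle_cell_flag,
    intersect_contrasts,
    mean_profile,
    ovary_ratio,
    zygotic_flag,
)
from germscreen.exact_test import ContrastResult
from germscreen.screen import run_screen

from conftest import full_profile, make_count_matrix, make_expression_matrix

CFG = ScreenConfig()


def contrast_from(fdr, logfc, name="c"):
    genes = pd.Index([f"g{i}" for i in range(len(fdr))], name="gene_id")
    table = pd.DataFrame(
        {
            "count_ovary": 0, "count_other": 0,
            "logfc": logfc, "p_value": fdr, "fdr": fdr,
        },
        index=genes,
    )
    return ContrastResult(name, "ov", "other", 1e6, 1e6, table)


class TestIntersectContrasts:
    def test_requires_all_four_contrasts(self):
        # g0 significant everywhere; g1 misses one contrast
        res = [
            contrast_from([1e-5, 1e-5], [1.0, 1.0], "a"),
            contrast_from([1e-5, 1e-5], [1.0, 1.0], "b"),
            contrast_from([1e-5, 1e-5], [1.0, 1.0], "c"),
            contrast_from([1e-5, 0.5], [1.0, 1.0], "d"),
        ]
        assert list(intersect_contrasts(res, 0.001)) == ["g0"]

    def test_boundary_fdr_is_included(self):
        res = [contrast_from([0.001], [1.0]) for _ in range(4)]
        assert list(intersect_contrasts(res, 0.001)) == ["g0"]

    def test_downregulated_gene_excluded_unless_direction_disabled(self):
        res = [contrast_from([1e-6], [-2.0]) for _ in range(4)]
        assert len(intersect_contrasts(res, 0.001)) == 0
        assert list(intersect_contrasts(res, 0.001, require_ovary_up=False)) == ["g0"]

    def test_mismatched_universes_rejected(self):
        a = contrast_from([1e-5], [1.0])
        b = contrast_from([1e-5, 1e-5], [1.0, 1.0])
        with pytest.raises(ConfigError):
            intersect_contrasts([a, b], 0.001)


class TestOvaryRatio:
    def test_all_zero_offtargets_use_pseudocount(self):
        # ovary RPKM 738 with silent off-targets: 738 / 0.1 = 7380
        expr = make_expression_matrix(full_profile(ovary_1_2=[738.0]))
        assert ovary_ratio(expr, CFG).iloc[0] == pytest.approx(7380.0)

    def test_threshold_is_strictly_greater(self):
        expr = make_expression_matrix(
            full_profile(
                ovary_1_2=[10.0], larvae=[0.1], pupae=[0.1], male_1_5=[0.1],
                carcass_24pbm=[0.1],
            )
        )
        ratio = ovary_ratio(expr, CFG).iloc[0]
        assert ratio == pytest.approx(100.0)
        assert not (ratio > CFG.fold_threshold)

    def test_silent_gene_has_ratio_one(self):
        expr = make_expression_matrix(full_profile(ovary_1_2=[0.0]))
        assert ovary_ratio(expr, CFG).iloc[0] == pytest.approx(1.0)

    def test_substitution_not_addition(self):
        # small nonzero values are NOT bumped by the pseudocount
        expr = make_expression_matrix(
            full_profile(
                ovary_1_2=[100.0], larvae=[0.02], pupae=[0.02], male_1_5=[0.02],
                carcass_24pbm=[0.02],
            )
        )
        assert ovary_ratio(expr, CFG).iloc[0] == pytest.approx(100.0 / 0.02)

    def test_ignores_unrelated_samples(self):
        lo = make_expression_matrix(full_profile(ovary_1_2=[50.0], embryo_0_1=[0.0]))
        hi = make_expression_matrix(full_profile(ovary_1_2=[50.0], embryo_0_1=[999.0]))
        assert ovary_ratio(lo, CFG).iloc[0] == ovary_ratio(hi, CFG).iloc[0]


class TestRefinementFlags:
    def test_no_embryo_signal_flags_follicle_cell(self):
        expr = make_expression_matrix(full_profile(ovary_1_2=[500.0], embryo_0_1=[0.0]))
        assert follicle_cell_flag(expr, CFG).iloc[0]

    def test_deposited_transcript_not_flagged(self):
        expr = make_expression_matrix(full_profile(ovary_1_2=[500.0], embryo_0_1=[80.0]))
        assert not follicle_cell_flag(expr, CFG).iloc[0]

    def test_follicle_threshold_boundary_not_flagged(self):
        expr = make_expression_matrix(
            full_profile(ovary_1_2=[500.0], embryo_0_1=[CFG.embryo_min_rpkm])
        )
        assert not follicle_cell_flag(expr, CFG).iloc[0]

    def test_zygotic_rise_flagged_with_first_interval(self):
        expr = make_expression_matrix(
            full_profile(embryo_0_1=[5.0], embryo_2_4=[20.0], embryo_4_8=[18.0],
                         embryo_8_12=[15.0])
        )
        out = zygotic_flag(expr, CFG)
        assert out["zygotic_flag"].iloc[0]
        assert out["zygotic_interval"].iloc[0] == "embryo_0_1:embryo_2_4"

    def test_monotone_maternal_decay_not_flagged(self):
        expr = make_expression_matrix(
            full_profile(embryo_0_1=[40.0], embryo_2_4=[20.0], embryo_4_8=[10.0],
                         embryo_8_12=[5.0])
        )
        assert not zygotic_flag(expr, CFG)["zygotic_flag"].iloc[0]

    def test_zero_predecessor_is_substituted(self):
        expr = make_expression_matrix(
            full_profile(embryo_0_1=[0.0], embryo_2_4=[1.0], embryo_4_8=[0.5],
                         embryo_8_12=[0.2])
        )
        out = zygotic_flag(expr, CFG)
        assert out["zygotic_flag"].iloc[0]  # 1.0 > 2 * 0.1
        assert out["zygotic_interval"].iloc[0] == "embryo_0_1:embryo_2_4"

    @pytest.mark.parametrize(
        "pre,pbm,expected",
        [(10.0, 10.0, "same"), (10.0, 100.0, "up"), (100.0, 10.0, "down")],
    )
    def test_bloodmeal_classification(self, pre, pbm, expected):
        expr = make_expression_matrix(full_profile(ovary_1_2=[pre], ovary_24pbm=[pbm]))
        assert bloodmeal_class(expr, CFG).iloc[0] == expected


class TestMeanProfile:
    def test_singleton_set_returns_own_profile(self):
        expr = make_expression_matrix(full_profile(ovary_1_2=[5.0, 100.0]))
        prof = mean_profile(expr, ["g1"])
        assert prof["ovary_1_2"] == 100.0

    def test_mean_of_two_genes_and_order_invariance(self):
        expr = make_expression_matrix(full_profile(ovary_1_2=[10.0, 30.0], larvae=[2.0, 4.0]))
        a = mean_profile(expr, ["g0", "g1"])
        b = mean_profile(expr, ["g1", "g0"])
        assert a["ovary_1_2"] == 20.0 and a["larvae"] == 3.0
        pd.testing.assert_series_equal(a, b)

    def test_canonical_sample_order(self):
        expr = make_expression_matrix(full_profile(ovary_1_2=[1.0]))
        assert list(mean_profile(expr, ["g0"]).index) == [r.value for r in CANONICAL_ROLE_ORDER]

    def test_empty_set_rejected(self):
        expr = make_expression_matrix(full_profile(ovary_1_2=[1.0]))
        with pytest.raises(DataError):
            mean_profile(expr, [])


class TestRunScreen:
    def test_all_null_matrix_yields_empty_sets(self):
        rng = np.random.default_rng(2)
        base = rng.integers(50, 500, size=60)
        data = {role: base.tolist() for role in CANONICAL_ROLE_ORDER}
        cm = make_count_matrix(data)
        lengths = pd.Series(rng.integers(500, 5000, 60), index=cm.gene_ids)
        table, summary, _ = run_screen(cm, lengths, CFG)
        assert summary["n_fdr_strict"] == 0
        assert summary["n_fdr_relaxed"] == 0
        assert summary["n_germline_final"] == 0

    def test_strict_set_nested_in_relaxed(self, default_screen):
        table, summary, _, _ = default_screen
        assert (table["in_fdr_strict"] <= table["in_fdr_relaxed"]).all()
        assert summary["n_fdr_strict"] <= summary["n_fdr_relaxed"]

    def test_invariants_of_result_table(self, default_screen):
        table, _, _, _ = default_screen
        assert (table["passes_ratio"] == (table["ovary_ratio"] > CFG.fold_threshold)).all()
        assert (~table["germline_call"] | table["in_fdr_strict"]).all()
        assert (~table["germline_call"] | ~table["follicle_flag"]).all()

    def test_determinism_byte_identical_tables(self, default_dataset, tmp_path):
        from germscreen.core_io import write_screen_table

        counts, lengths, _ = default_dataset
        sub_genes = counts.gene_ids[::25]
        sub = type(counts)(counts.counts.loc[sub_genes], dict(counts.roles))
        t1, _, _ = run_screen(sub, lengths.loc[sub_genes], CFG)
        t2, _, _ = run_screen(sub, lengths.loc[sub_genes], CFG)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_screen_table(t1, p1)
        write_screen_table(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()
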