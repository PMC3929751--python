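import io

import numpy as np
import pandas as pd
import pytest

from cooccur_tfbs import (
    DegenerateInputError,
    ExpressionMatrix,
    bh_qvalues,
    filter_present,
    merge_probes,
    paired_test,
    paired_tests,
    pca_scores,
    sam_statistic,
    select_top_variance,
    template_match,
    variance_fraction,
)
from cooccur_tfbs.deg_selection import dendrogram_newick, gene_variance


def make_design(n_pairs):
    pairs = [f"P{i}" for i in range(1, n_pairs + 1)]
    cols = [f"{p}_c" for p in pairs] + [f"{p}_w" for p in pairs]
    return pd.DataFrame(
        {"group": ["control"] * n_pairs + ["wounded"] * n_pairs, "pair": pairs * 2},
        index=pd.Index(cols, name="sample"),
    )


def make_matrix(values, n_pairs=3, index=None):
    design = make_design(n_pairs)
    df = pd.DataFrame(values, columns=design.index, index=index)
    return ExpressionMatrix(df, design)


class TestFilterPresent:
    def test_present_in_one_group_is_enough(self):
        # 3 present calls in control only, none in wounded: retained (OR rule)
        em = make_matrix([[8.0, 8.0, 8.0, 4.0, 4.0, 4.0]], index=["p1"])
        out = filter_present(em, k=3)
        assert list(out.values.index) == ["p1"]
        assert filter_present(em, k=3, rule="and").values.empty

    def test_absent_everywhere_dropped(self):
        em = make_matrix([[4.0] * 6], index=["p1"])
        assert filter_present(em, k=3).values.empty

    def test_explicit_call_table_matches_brute_force(self):
        rng = np.random.default_rng(0)
        n = 200
        design = make_design(3)
        values = pd.DataFrame(
            rng.normal(8, 1, size=(n, 6)), columns=design.index,
            index=[f"p{i}" for i in range(n)],
        )
        calls = pd.DataFrame(
            rng.choice(["P", "M", "A"], size=(n, 6)), columns=design.index, index=values.index
        )
        em = ExpressionMatrix(values, design)
        out = filter_present(em, calls=calls, k=2)
        ctrl = design.index[design["group"] == "control"]
        wnd = design.index[design["group"] == "wounded"]
        expected = {
            p
            for p in values.index
            if (calls.loc[p, ctrl] == "P").sum() >= 2 or (calls.loc[p, wnd] == "P").sum() >= 2
        }
        assert set(out.values.index) == expected

    def test_non_annotated_probes_dropped(self):
        em = make_matrix([[8.0] * 6, [8.0] * 6], index=["p1", "p2"])
        out = filter_present(em, k=3, annotation={"p1": "G1", "p2": None})
        assert list(out.values.index) == ["p1"]

    def test_k_larger_than_group_rejected(self):
        em = make_matrix([[8.0] * 6], index=["p1"])
        with pytest.raises(ValueError, match="exceeds"):
            filter_present(em, k=4)


class TestMergeProbes:
    def test_mean_of_two_probes(self):
        em = make_matrix([[4.0] * 6, [6.0] * 6], index=["p1", "p2"])
        out = merge_probes(em, {"p1": "G1", "p2": "G1"})
        assert list(out.values.index) == ["G1"]
        np.testing.assert_allclose(out.values.loc["G1"], 5.0)

    def test_single_probe_gene_unchanged(self):
        em = make_matrix([[4.0, 5.0, 6.0, 7.0, 8.0, 9.0]], index=["p1"])
        out = merge_probes(em, {"p1": "G1"})
        np.testing.assert_array_equal(out.values.loc["G1"], em.values.loc["p1"])

    def test_random_toy_equals_groupby_oracle(self):
        rng = np.random.default_rng(1)
        design = make_design(3)
        probes = [f"p{i}" for i in range(50)]
        genes = {p: f"G{rng.integers(0, 20)}" for p in probes}
        values = pd.DataFrame(rng.normal(8, 2, (50, 6)), index=probes, columns=design.index)
        out = merge_probes(ExpressionMatrix(values, design), genes)
        oracle = values.groupby(values.index.map(genes.get)).mean()
        pd.testing.assert_frame_equal(out.values.sort_index(), oracle.sort_index(), check_names=False)


class TestPairedTest:
    def test_hand_computed_p_value(self):
        # differences (1,2,3): t = 2 / (1/sqrt(3)) = 3.464, df=2, p ~ 0.0742
        em = make_matrix([[0.0, 0.0, 0.0, 1.0, 2.0, 3.0]], index=["g"])
        p = paired_test(em.values.loc["g"], em.design)
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_zero_variance_differences_rejected(self):
        em = make_matrix([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]], index=["g"])
        with pytest.raises(DegenerateInputError):
            paired_test(em.values.loc["g"], em.design)

    def test_group_swap_leaves_p_unchanged(self):
        em = make_matrix([[0.1, 0.4, 0.2, 1.0, 2.0, 3.0]], index=["g"])
        swapped = em.design.copy()
        swapped["group"] = swapped["group"].map({"control": "wounded", "wounded": "control"})
        p1 = paired_test(em.values.loc["g"], em.design)
        p2 = paired_test(em.values.loc["g"], swapped)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(2)
        design = make_design(4)
        values = pd.DataFrame(rng.normal(8, 1, (20, 8)), columns=design.index,
                              index=[f"g{i}" for i in range(20)])
        em = ExpressionMatrix(values, design)
        ps = paired_tests(em)
        for g in values.index[:5]:
            assert ps[g] == pytest.approx(paired_test(values.loc[g], design), rel=1e-12)

    def test_sample_order_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        design = make_design(3)
        values = pd.DataFrame(rng.normal(8, 1, (10, 6)), columns=design.index,
                              index=[f"g{i}" for i in range(10)])
        perm = rng.permutation(list(design.index))
        a = paired_tests(ExpressionMatrix(values, design))
        b = paired_tests(ExpressionMatrix(values[perm], design.loc[perm]))
        pd.testing.assert_series_equal(a, b)


class TestBHQvalues:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal_p_fixed_point(self):
        np.testing.assert_allclose(bh_qvalues([0.3] * 7), [0.3] * 7)

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_qvalues([0.123]), [0.123])

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        q = bh_qvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])


class TestSelection:
    def _planted(self, planted_expression):
        em, truth = planted_expression
        p = paired_tests(em)
        q = pd.Series(bh_qvalues(p.to_numpy()), index=p.index)
        return em, truth, p, q

    def test_top_equals_qpass_when_n_matches(self, planted_expression):
        em, truth, p, q = self._planted(planted_expression)
        res = select_top_variance(em, q, q_max=0.05, n=len(em.values))
        # n exceeds the q-passing count: warning and everything returned
        assert set(res.top_genes) == res.q_pass

    def test_planted_genes_dominate_top_list(self, planted_expression):
        em, truth, p, q = self._planted(planted_expression)
        res = select_top_variance(em, q, q_max=0.05, n=40, p_values=p)
        overlap = len(set(res.top_genes) & truth.de_genes)
        assert overlap >= 36  # >= 90% of the top-40 are planted
        assert res.max_p_in_top <= 0.05

    def test_equal_variance_breaks_ties_lexicographically(self):
        em = make_matrix(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]],
            index=["GB", "GA"],
        )
        q = pd.Series([0.01, 0.01], index=["GB", "GA"])
        res = select_top_variance(em, q, n=1)
        assert res.top_genes == ["GA"]

    def test_variance_is_descending_along_top(self, planted_expression):
        em, _, p, q = self._planted(planted_expression)
        res = select_top_variance(em, q, n=30)
        v = res.variance.loc[res.top_genes].to_numpy()
        assert (np.diff(v) <= 1e-12).all()

    def test_underfull_selection_warns(self):
        em = make_matrix([[1, 2, 3, 7, 8, 9.0], [1, 1.1, 0.9, 1, 1.2, 0.8]], index=["GA", "GB"])
        q = pd.Series([0.01, 0.9], index=["GA", "GB"])
        with pytest.warns(UserWarning, match="pass"):
            res = select_top_variance(em, q, n=5)
        assert res.top_genes == ["GA"]


class TestVarianceFraction:
    def test_all_and_none(self, planted_expression):
        em, *_ = planted_expression
        assert variance_fraction(list(em.values.index), em) == pytest.approx(1.0)
        assert variance_fraction([], em) == 0.0

    def test_arithmetic_oracle(self):
        # genes with variances 1..10; top 2 carry (10+9)/55 of the total
        rng = np.random.default_rng(5)
        design = make_design(3)
        base = rng.normal(0, 1, 6)
        base = (base - base.mean()) / base.std(ddof=1)  # unit sample variance
        rows = [base * np.sqrt(v) + 8 for v in range(1, 11)]
        em = ExpressionMatrix(
            pd.DataFrame(rows, index=[f"g{i}" for i in range(1, 11)], columns=design.index),
            design,
        )
        got = variance_fraction(["g10", "g9"], em)
        assert got == pytest.approx(19 / 55, rel=1e-9)


class TestPCA:
    def test_single_varying_gene_explains_everything(self):
        em = make_matrix([[1, 2, 3, 4, 5, 6.0], [5, 5, 5, 5, 5, 5.0]], index=["g1", "g2"])
        scores, loadings, evr = pca_scores(em)
        assert evr[0] == pytest.approx(1.0)

    def test_groups_separate_on_planted_data(self, planted_expression):
        em, truth, *_ = planted_expression
        sub = ExpressionMatrix(em.values.loc[sorted(truth.de_genes)], em.design)
        scores, _, _ = pca_scores(sub)
        ctrl = scores.loc[em.design.index[em.design["group"] == "control"], "PC1"]
        wnd = scores.loc[em.design.index[em.design["group"] == "wounded"], "PC1"]
        assert min(wnd) > max(ctrl) or min(ctrl) > max(wnd)

    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(6)
        design = make_design(2)
        vals = rng.normal(8, 1, (10, 2))
        values = pd.DataFrame(
            np.hstack([vals, vals]), columns=design.index, index=[f"g{i}" for i in range(10)]
        )
        scores, _, _ = pca_scores(ExpressionMatrix(values, design))
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[2], atol=1e-9)
        np.testing.assert_allclose(scores.iloc[1], scores.iloc[3], atol=1e-9)

    def test_constant_matrix_rejected(self):
        em = make_matrix([[5.0] * 6, [5.0] * 6], index=["g1", "g2"])
        with pytest.raises(DegenerateInputError):
            pca_scores(em)

    def test_loading_sign_convention(self, planted_expression):
        em, *_ = planted_expression
        _, loadings, _ = pca_scores(em)
        assert (loadings.sum(axis=0) >= -1e-9).all()


class TestSAM:
    def test_d_reduces_to_scaled_t_for_single_gene(self):
        # with one gene s0 = median(s) = s, so d = mean / (2 s) = t / 2
        em = make_matrix([[0.0, 0.0, 0.0, 1.0, 2.0, 3.0]], index=["g"])
        out = sam_statistic(em, n_perm=10, seed=0)
        t = 2.0 / (1.0 / np.sqrt(3))
        assert out.loc["g", "d"] == pytest.approx(t / 2, rel=1e-12)

    def test_sign_flip_of_all_pairs_negates_d(self):
        rng = np.random.default_rng(7)
        design = make_design(3)
        values = pd.DataFrame(rng.normal(8, 1, (15, 6)), columns=design.index,
                              index=[f"g{i}" for i in range(15)])
        em = ExpressionMatrix(values, design)
        swapped = design.copy()
        swapped["group"] = swapped["group"].map({"control": "wounded", "wounded": "control"})
        d1 = sam_statistic(em, n_perm=10, seed=0)["d"]
        d2 = sam_statistic(ExpressionMatrix(values, swapped), n_perm=10, seed=0)["d"]
        np.testing.assert_allclose(d1.to_numpy(), -d2.to_numpy(), rtol=1e-12)

    def test_null_data_rarely_called(self):
        cfg_rng = np.random.default_rng(8)
        design = make_design(4)
        values = pd.DataFrame(cfg_rng.normal(8, 1, (300, 8)), columns=design.index,
                              index=[f"g{i}" for i in range(300)])
        out = sam_statistic(ExpressionMatrix(values, design), n_perm=100, seed=1)
        assert (out["q_sam"] <= 0.05).mean() <= 0.10

    def test_planted_genes_rank_on_top(self, planted_expression):
        em, truth, *_ = planted_expression
        out = sam_statistic(em, n_perm=50, seed=2)
        top = set(out["d"].abs().nlargest(len(truth.de_genes)).index)
        assert len(top & truth.de_genes) / len(truth.de_genes) >= 0.9


class TestTemplateMatch:
    def test_template_correlates_with_itself(self, planted_expression):
        em, *_ = planted_expression
        gene = em.values.index[0]
        res = template_match(em, gene, r_min=0.9)
        assert gene in res["positive"]

    def test_negated_profile_lands_in_negative_set(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        em = make_matrix([base, [-x + 10 for x in base]], index=["t", "anti"])
        res = template_match(em, "t")
        assert res["negative"] == ["anti"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        design = make_design(3)
        values = pd.DataFrame(rng.normal(8, 1, (20, 6)), columns=design.index,
                              index=[f"g{i}" for i in range(20)])
        em = ExpressionMatrix(values, design)
        res = template_match(em, "g0", r_min=0.5)
        expected_pos, expected_neg = [], []
        for g in values.index:
            r = np.corrcoef(values.loc[g], values.loc["g0"])[0, 1]
            if r >= 0.5:
                expected_pos.append(g)
            elif r <= -0.5:
                expected_neg.append(g)
        assert res["positive"] == expected_pos
        assert res["negative"] == expected_neg

    def test_zero_variance_profile_skipped_with_warning(self):
        em = make_matrix([[1, 2, 3, 4, 5, 6.0], [5.0] * 6], index=["t", "flat"])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = template_match(em, "t", r_min=0.1)
        assert "flat" not in res["positive"] + res["negative"]


def test_dendrogram_newick_is_parseable(planted_expression):
    from Bio import Phylo

    em, truth = planted_expression
    sub = ExpressionMatrix(em.values.iloc[:12], em.design)
    nwk = dendrogram_newick(sub)
    tree = Phylo.read(io.StringIO(nwk), "newick")
    leaves = {leaf.name for leaf in tree.get_terminals()}
    assert leaves == set(sub.values.index)
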