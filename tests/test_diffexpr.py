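"""Normalization, count-based and array-based DE, consistency, lineage,
UPGMA clustering, Q-PCR arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from mirdiv.config import SimConfig
from mirdiv.datatypes import DECall
from mirdiv.diffexpr import (
    assign_lineage,
    call_de_array,
    call_de_seq,
    direction_consistency,
    edger_filter,
    fisher_count_test,
    qpcr_relative_expression,
    quantile_normalize,
    tpm_normalize,
    upgma_cluster,
    upgma_from_distances,
)
from mirdiv.synthetic import simulate_counts


def hypergeom_two_sided(c1, N1, c2, N2):
    """Independent enumeration oracle: sum the probability of every table
    with the same margins whose probability is at most the observed."""
    K = c1 + c2
    obs = math.comb(N1, c1) * math.comb(N2, c2)
    total = num = 0
    for x in range(max(0, K - N2), min(K, N1) + 1):
        w = math.comb(N1, x) * math.comb(N2, K - x)
        total += w
        if w <= obs:
            num += w
    return num / total


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        assert np.allclose(quantile_normalize(df), df)

    def test_hand_computed_rank_means(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_ties_get_mean_of_reference(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = quantile_normalize(df)
        # the tied pair shares the mean of rank-1 and rank-2 reference values
        assert out["a"].iloc[0] == out["a"].iloc[1]

    @given(
        st.lists(
            st.lists(st.floats(min_value=0, max_value=1e4), min_size=5, max_size=5,
                     unique=True),
            min_size=2,
            max_size=4,
        )
    )
    def test_column_sums_equal(self, cols):
        # tie-free columns share the reference multiset exactly, so the
        # column sums coincide (ties are averaged and can perturb sums)
        df = pd.DataFrame({f"c{i}": v for i, v in enumerate(cols)})
        out = quantile_normalize(df)
        sums = out.sum()
        assert np.allclose(sums, sums.iloc[0], atol=1e-6)

    def test_single_column_noop_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(df)
        assert out.equals(df)


class TestTpm:
    def test_scale_and_zero(self):
        assert tpm_normalize(10, 1e6) == 10
        assert tpm_normalize(0, 123.0) == 0

    def test_column_sums_to_million(self):
        col = pd.Series([5.0, 15.0, 80.0])
        assert tpm_normalize(col, col.sum()).sum() == pytest.approx(1e6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm_normalize(5, 0)


class TestFisherCountTest:
    def test_identical_proportions_p_one(self):
        assert fisher_count_test(5, 100, 5, 100) == 1.0
        assert fisher_count_test(0, 10, 0, 10) == 1.0

    def test_matches_enumeration(self):
        assert fisher_count_test(12, 1000, 2, 1000) == pytest.approx(
            hypergeom_two_sided(12, 1000, 2, 1000), rel=1e-9
        )

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_count_test(11, 10, 0, 10)

    def test_null_p_values_not_anticonservative(self, de_sim):
        # under the near-Poisson null the exact conditional test is
        # conservative-to-uniform: ECDF <= diagonal + 0.03, and the
        # one-sided KS against anti-conservatism is not rejected
        cfg = SimConfig(seed=17, n_mirna=2000, depth=1e6, de_fraction=0.0)
        counts, _, _ = simulate_counts(cfg)
        pair = counts[["human_rep1", "chimpanzee_rep1"]].astype(float)
        norm = quantile_normalize(pair).round().astype(int)
        N1, N2 = int(norm.iloc[:, 0].sum()), int(norm.iloc[:, 1].sum())
        ps = np.array(
            [fisher_count_test(int(a), N1, int(b), N2) for a, b in norm.itertuples(index=False)]
        )
        grid = np.linspace(0, 1, 201)
        ecdf = np.searchsorted(np.sort(ps), grid, side="right") / len(ps)
        assert (ecdf - grid).max() <= 0.03
        assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.001


class TestCallDeSeq:
    def test_detection_filter_blocks_low_counts(self):
        counts = pd.DataFrame(
            {"human_rep1": [9], "human_rep2": [9], "chimpanzee_rep1": [0], "chimpanzee_rep2": [0]},
            index=["mir-low"],
        )
        meta = pd.DataFrame(
            {"species": ["human", "human", "chimpanzee", "chimpanzee"], "replicate": [1, 2, 1, 2]},
            index=counts.columns,
        )
        calls = call_de_seq(counts, meta, ("human", "chimpanzee"))
        assert not calls[0].passed and not calls[0].detected

    def test_species_swap_flips_direction_only(self, de_sim):
        _, counts, meta, _ = de_sim
        sub = counts.iloc[:50]
        a = call_de_seq(sub, meta, ("human", "chimpanzee"))
        b = call_de_seq(sub, meta, ("chimpanzee", "human"))
        flip = {"up-in-1": "up-in-2", "up-in-2": "up-in-1"}
        for ca, cb in zip(a, b):
            assert ca.passed == cb.passed
            assert ca.p_value == pytest.approx(cb.p_value)
            if ca.passed:
                assert cb.direction == flip[ca.direction]

    def test_single_replicate_fallback_flagged(self):
        rng = np.random.default_rng(1)
        bg = rng.integers(100, 1000, size=30)
        counts = pd.DataFrame(
            {"human_rep1": np.concatenate([[5000], bg]),
             "chimpanzee_rep1": np.concatenate([[400], bg + rng.integers(-20, 20, 30)])},
            index=["mir-de"] + [f"mir-bg{i}" for i in range(30)],
        )
        meta = pd.DataFrame({"species": ["human", "chimpanzee"], "replicate": [1, 1]},
                            index=counts.columns)
        calls = call_de_seq(counts, meta, ("human", "chimpanzee"))
        assert all(c.replicate_consistent is None for c in calls)
        assert calls[0].passed  # strong difference still callable

    def test_passed_implies_thresholds(self, de_sim):
        _, counts, meta, _ = de_sim
        for c in call_de_seq(counts, meta, ("human", "chimpanzee")):
            if c.passed:
                assert c.p_value < 0.01
                assert max(c.fold_change, 1 / c.fold_change) > 2
                assert c.detected


class TestEdgerHook:
    def test_filter_applies_published_thresholds(self):
        table = pd.DataFrame(
            {"p": [1e-4, 5e-4, 0.01, 1e-5], "fdr": [0.001, 0.05, 0.001, 0.009]},
            index=["a", "b", "c", "d"],
        )
        assert edger_filter(table) == ["a", "d"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            edger_filter(pd.DataFrame({"p": [0.1]}))


class TestCallDeArray:
    def test_identical_groups_not_passed(self):
        mat = pd.DataFrame(
            [[5.0, 5.1, 4.9, 5.0, 5.1, 4.9]], index=["mir-a"],
            columns=["h1", "h2", "h3", "c1", "c2", "c3"],
        )
        species = {c: ("human" if c.startswith("h") else "chimpanzee") for c in mat.columns}
        calls = call_de_array(mat, species, ("human", "chimpanzee"))
        assert not calls[0].passed

    def test_masked_mirna_absent_from_output(self):
        mat = pd.DataFrame(
            np.arange(12.0).reshape(2, 6), index=["mir-a", "mir-b"],
            columns=["h1", "h2", "h3", "c1", "c2", "c3"],
        )
        species = {c: ("human" if c.startswith("h") else "chimpanzee") for c in mat.columns}
        calls = call_de_array(mat, species, ("human", "chimpanzee"), masked_ids=["mir-a"])
        assert [c.mirna_id for c in calls] == ["mir-b"]

    def test_t_statistic_matches_closed_form(self):
        x = np.array([7.0, 8.0, 9.0])
        y = np.array([5.0, 5.5, 6.5])
        mat = pd.DataFrame([np.concatenate([x, y])], index=["mir-a"],
                           columns=["h1", "h2", "h3", "c1", "c2", "c3"])
        species = {c: ("human" if c.startswith("h") else "chimpanzee") for c in mat.columns}
        call = call_de_array(mat, species, ("human", "chimpanzee"))[0]
        sp = math.sqrt(((x.var(ddof=1) + y.var(ddof=1)) / 2) * (2 / 3))
        t = (x.mean() - y.mean()) / sp
        assert call.p_value == pytest.approx(2 * stats.t.sf(abs(t), df=4))

    def test_too_few_individuals_skipped_with_flag(self):
        mat = pd.DataFrame([[5.0, 6.0, 7.0]], index=["mir-a"], columns=["h1", "c1", "c2"])
        species = {"h1": "human", "c1": "chimpanzee", "c2": "chimpanzee"}
        call = call_de_array(mat, species, ("human", "chimpanzee"))[0]
        assert not call.passed and not call.detected


def _calls(n_passed, directions, prefix="mir"):
    return [
        DECall(f"{prefix}-{i}", 0.001, 3.0, d, True) for i, d in enumerate(directions[:n_passed])
    ]


class TestDirectionConsistency:
    @pytest.mark.parametrize(
        "n_shared,n_consistent,percent", [(37, 31, 84), (106, 82, 77), (37, 37, 100)]
    )
    def test_printed_percentages(self, n_shared, n_consistent, percent):
        a = _calls(n_shared, ["up-in-1"] * n_shared)
        b_dirs = ["up-in-1"] * n_consistent + ["up-in-2"] * (n_shared - n_consistent)
        b = [DECall(f"mir-{i}", 0.5, 1.0, d, False) for i, d in enumerate(b_dirs)]
        ns, nc, pct, bp = direction_consistency(a, b)
        assert (ns, nc, pct) == (n_shared, n_consistent, percent)
        if n_consistent == n_shared:
            assert bp == pytest.approx(0.5 ** n_shared)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            direction_consistency(_calls(3, ["up-in-1"] * 3, "x"), _calls(3, ["up-in-1"] * 3, "y"))


class TestAssignLineage:
    @pytest.mark.parametrize(
        "h,c,m,lineage",
        [(100, 10, 12, "human"), (10, 100, 12, "chimpanzee"), (100, 10, 55, "unassigned"),
         (5, 3, 3, "human"), (3, 3, 3, "unassigned")],
    )
    def test_outgroup_rule(self, h, c, m, lineage):
        assert assign_lineage("mir-x", h, c, m).lineage == lineage

    def test_missing_outgroup_flagged(self):
        call = assign_lineage("mir-x", 10, 5, None)
        assert call.lineage == "unassigned" and call.outgroup_missing


class TestUpgma:
    def test_identical_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        tree = upgma_cluster(df)
        sub = [c for c in tree.children if not c.is_leaf()][0]
        assert set(sub.leaves()) == {"a", "b"} and sub.height == 0

    def test_hand_computed_three_leaf_tree(self):
        d = pd.DataFrame([[0, 2, 8], [2, 0, 8], [8, 8, 0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = upgma_from_distances(d)
        assert tree.height == 4
        inner = [c for c in tree.children if not c.is_leaf()][0]
        assert inner.height == 1 and set(inner.leaves()) == {"A", "B"}

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 4))
        d = np.abs(pts @ pts.T)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        df = pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))
        tree = upgma_from_distances(df)
        Z = hierarchy.linkage(squareform(d), method="average")

        def heights(node, acc):
            if not node.is_leaf():
                acc.append(node.height)
                for ch in node.children:
                    heights(ch, acc)
            return acc

        assert np.allclose(sorted(heights(tree, [])), sorted(Z[:, 2] / 2))

    def test_constant_column_names_sample(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0], "c": [2.0, 1.0, 3.0]})
        with pytest.raises(ValueError, match="a"):
            upgma_cluster(df)

    def test_three_species_topology_recovered(self):
        cfg = SimConfig(seed=4, n_mirna=150, depth=1e6, de_fraction=0.15)
        counts, _, _ = simulate_counts(cfg)
        tree = upgma_cluster(np.log2(quantile_normalize(counts.astype(float)) + 1))
        parts = [set(c.leaves()) for c in tree.children]
        assert {"macaque_rep1", "macaque_rep2"} in parts


class TestQpcr:
    @pytest.mark.parametrize("ct,ref,expected", [(25, 25, 0), (24, 25, 1), (27, 25, -2)])
    def test_delta_ct(self, ct, ref, expected):
        assert qpcr_relative_expression(ct, ref) == expected
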