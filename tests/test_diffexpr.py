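import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from icpnet import diffexpr as de
from tests.conftest import toy_matrix

GROUPS6 = ["healthy", "healthy", "mild", "mild", "severe", "severe"]


def _random_matrix(n_genes=40, seed=0):
    rng = np.random.default_rng(seed)
    values = {f"g{i:03d}": rng.normal(8, 1, 6).tolist() for i in range(n_genes)}
    return toy_matrix(values, groups=GROUPS6)


class TestGroupFit:
    def test_exact_means_and_zero_variance(self):
        m = toy_matrix({"g": [1, 1, 2, 2, 3, 3]}, groups=GROUPS6)
        fit = de.fit_group_means(m)
        assert fit.means.loc["g", "healthy"] == 1
        assert fit.means.loc["g", "mild"] == 2
        assert fit.means.loc["g", "severe"] == 3
        assert fit.s2.loc["g"] == 0
        assert fit.dg == 3

    def test_within_group_sum_of_squares(self):
        # healthy arrays (0, 2): mean 1, SS contribution 2 -> s2 = 2/3
        m = toy_matrix({"g": [0, 2, 1, 1, 1, 1]}, groups=GROUPS6)
        fit = de.fit_group_means(m)
        assert fit.s2.loc["g"] == pytest.approx(2.0 / 3.0)

    def test_matches_ols_normal_equations(self):
        m = _random_matrix(seed=5)
        fit = de.fit_group_means(m)
        X = np.zeros((6, 3))
        for j, g in enumerate(GROUPS6):
            X[j, ["healthy", "mild", "severe"].index(g)] = 1.0
        for gene in m.gene_ids:
            y = m.values.loc[gene].to_numpy()
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            np.testing.assert_allclose(
                fit.means.loc[gene, ["healthy", "mild", "severe"]].to_numpy(),
                beta,
                atol=1e-12,
            )
            np.testing.assert_allclose(fit.s2.loc[gene], res[0] / 3, atol=1e-12)

    def test_single_array_group_rejected(self):
        m = toy_matrix(
            {"g": [1, 2, 3]}, groups=["healthy", "mild", "severe"]
        )
        with pytest.raises(ValueError, match="need >= 2"):
            de.fit_group_means(m)


class TestEbayes:
    def test_posterior_is_weighted_average(self):
        s2 = pd.Series([0.1, 0.2, 0.4])
        params, post = de.ebayes_moderate(s2, dg=3, d0=4.0, s0_sq=0.04)
        expected = (4 * 0.04 + 3 * s2) / 7
        np.testing.assert_allclose(post, expected)

    def test_zero_variance_gene_rescued_by_moderation(self):
        s2 = pd.Series([0.0, 0.2, 0.3])
        _, post = de.ebayes_moderate(s2, dg=3, d0=4.0, s0_sq=0.04)
        assert post.iloc[0] == pytest.approx(4 * 0.04 / 7)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            de.ebayes_moderate(pd.Series([0.0] * 20), dg=3)

    def test_d0_zero_limit_matches_ordinary_t(self):
        m = _random_matrix(seed=2)
        fit = de.fit_group_means(m)
        params, post = de.ebayes_moderate(fit.s2, fit.dg, d0=0.0, s0_sq=1.0)
        table = de.moderated_t_table(fit, params, post, "c", "severe", "healthy")
        lfc = fit.means["severe"] - fit.means["healthy"]
        ordinary = lfc / np.sqrt(fit.s2 * (0.5 + 0.5))
        np.testing.assert_allclose(table["moderated_t"], ordinary, atol=1e-10)

    def test_d0_infinite_limit_pins_posterior_at_prior(self):
        m = _random_matrix(seed=3)
        fit = de.fit_group_means(m)
        _, post = de.ebayes_moderate(fit.s2, fit.dg, d0=math.inf, s0_sq=0.25)
        assert np.allclose(post, 0.25)


class TestAdjustBH:
    def test_stepup_worked_example(self):
        np.testing.assert_allclose(
            de.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value(self):
        np.testing.assert_allclose(de.adjust_bh([1.0]), [1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            de.adjust_bh([0.5, 1.2])

    @staticmethod
    def brute_force_bh(p):
        # direct restatement: q_i = min over p_j >= p_i of m*p_j/rank(p_j)
        p = np.asarray(p, float)
        m = len(p)
        q = np.empty(m)
        for i in range(m):
            candidates = [
                m * pj / (p <= pj).sum() for pj in p if pj >= p[i]
            ]
            q[i] = min(1.0, min(candidates))
        return q

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_quadratic_oracle(self, p):
        np.testing.assert_allclose(de.adjust_bh(p), self.brute_force_bh(p), atol=1e-12)

    @given(st.permutations(list(range(8))))
    def test_permutation_equivariant(self, perm):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=8)
        q = de.adjust_bh(p)
        q_perm = de.adjust_bh(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])


class TestSelectDe:
    def _table(self, lfc, p):
        return pd.DataFrame(
            {"gene": ["g"], "contrast": ["c"], "log2fc": [lfc], "moderated_t": [1.0], "p": [p]}
        )

    def test_fc_gate_inclusive(self):
        out = de.select_de(self._table(math.log2(1.5), 0.01))
        assert out["call"].iloc[0] == "up"

    def test_p_gate_exclusive(self):
        out = de.select_de(self._table(1.0, 0.05))
        assert out["call"].iloc[0] == "ns"

    def test_down_direction(self):
        out = de.select_de(self._table(-1.0, 0.001))
        assert out["call"].iloc[0] == "down"

    def test_called_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "contrast": "c",
                "log2fc": rng.normal(0, 1, 200),
                "moderated_t": 0.0,
                "p": rng.uniform(0, 0.2, 200),
            }
        )
        loose = (de.select_de(table, 1.5, 0.05, 0.5)["call"] != "ns").sum()
        tight_fc = (de.select_de(table, 2.0, 0.05, 0.5)["call"] != "ns").sum()
        tight_p = (de.select_de(table, 1.5, 0.01, 0.5)["call"] != "ns").sum()
        assert tight_fc <= loose and tight_p <= loose


class TestSetAlgebra:
    def test_partition_of_union(self):
        out = de.de_set_algebra({"a": "up", "b": "up"}, {"b": "up", "c": "down"})
        assert set(out["intersection"]) == {"b"}
        assert set(out["mild_only"]) == {"a"}
        assert set(out["severe_only"]) == {"c"}

    def test_disjoint_and_equal_sets(self):
        assert de.de_set_algebra({"a": "up"}, {"b": "up"})["intersection"] == {}
        both = de.de_set_algebra({"a": "up"}, {"a": "up"})
        assert both["mild_only"] == {} and both["severe_only"] == {}

    def test_opposite_directions_both_recorded(self):
        out = de.de_set_algebra({"a": "up"}, {"a": "down"})
        assert out["intersection"]["a"] == ("up", "down")


class TestHierarchicalCluster:
    def test_identical_profiles_merge_at_zero(self):
        values = pd.DataFrame(
            {"a1": [1, 1, 5], "a2": [2, 2, 1], "a3": [3, 3, 2]},
            index=["g1", "g2", "g3"],
        )
        res = de.hierarchical_cluster(values)
        assert res.gene_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_merges_at_two(self):
        values = pd.DataFrame(
            {"a1": [1.0, -1.0], "a2": [2.0, -2.0], "a3": [3.0, -3.0]},
            index=["g1", "g2"],
        )
        res = de.hierarchical_cluster(values)
        assert res.gene_linkage[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_constant_gene_warns_and_gets_unit_distance(self):
        values = pd.DataFrame(
            {"a1": [1.0, 4.0], "a2": [1.0, 5.0], "a3": [1.0, 6.0]},
            index=["flat", "g"],
        )
        with pytest.warns(UserWarning, match="constant"):
            res = de.hierarchical_cluster(values)
        assert res.gene_linkage[0, 2] == pytest.approx(1.0)

    @staticmethod
    def naive_average_linkage(dist):
        # O(n^3) agglomeration oracle with scipy's cluster-id convention:
        # recompute every between-cluster average distance at each step
        n = dist.shape[0]
        active = {i: [i] for i in range(n)}
        Z = []
        next_id = n
        while len(active) > 1:
            ids = sorted(active)
            best = None
            for a in ids:
                for b in ids:
                    if a >= b:
                        continue
                    h = np.mean([dist[x, y] for x in active[a] for y in active[b]])
                    if best is None or h < best[2]:
                        best = (a, b, h)
            a, b, h = best
            members = active.pop(a) + active.pop(b)
            Z.append([a, b, h, len(members)])
            active[next_id] = members
            next_id += 1
        return np.array(Z)

    def test_matches_naive_agglomeration_oracle(self):
        rng = np.random.default_rng(12)
        values = pd.DataFrame(
            rng.normal(0, 1, (10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"a{j}" for j in range(6)],
        )
        res = de.hierarchical_cluster(values)
        dist = de.correlation_distance(values.to_numpy())
        oracle = self.naive_average_linkage(dist)
        np.testing.assert_allclose(res.gene_linkage[:, 2], oracle[:, 2], atol=1e-10)
        np.testing.assert_array_equal(
            res.gene_linkage[:, :2].astype(int), oracle[:, :2].astype(int)
        )

    def test_newick_parses_with_biopython(self):
        from io import StringIO

        from Bio import Phylo

        m = _random_matrix(n_genes=8, seed=6)
        res = de.hierarchical_cluster(m.values)
        tree = Phylo.read(StringIO(res.gene_newick), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == set(m.gene_ids)


class TestNullCalibration:
    def test_moderated_p_not_anticonservative_under_null(self):
        # pooled over 10 seeds, the global-null p-values must not sit
        # significantly below uniform (KS one-sided, alpha = 0.01)
        pooled = []
        for seed in range(10):
            m = _random_matrix(n_genes=400, seed=100 + seed)
            tables = de.de_analysis(m)
            pooled.append(tables["severe_vs_healthy"]["p"].to_numpy())
        stat = stats.kstest(np.concatenate(pooled), "uniform", alternative="greater")
        assert stat.pvalue > 0.01
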