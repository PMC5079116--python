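"""Correlation matrices, thresholded graphs, permutation nulls, MSTs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from scnpheno import (
    ExpressionMatrix,
    conditional_gene_network,
    graph_from_correlations,
    minimum_spanning_tree,
    pearson_matrix,
    permutation_threshold,
)
from scnpheno.networks import CorrelationMatrix
from oracles import brute_pearson, mst_total_weight


def expr(rows, index=None):
    vals = pd.DataFrame(rows)
    if index is not None:
        vals.index = index
    else:
        vals.index = [f"g{i}" for i in range(vals.shape[0])]
    return ExpressionMatrix(values=vals, stage="minus_ddCt")


class TestPearsonMatrix:
    def test_self_correlation_is_one(self, rng):
        x = expr(rng.normal(0, 1, (5, 20)))
        cm = pearson_matrix(x, "genes", min_obs=3)
        assert np.allclose(np.diag(cm.r.to_numpy()), 1.0)

    def test_perfect_anticorrelation(self):
        x = expr([[1.0, 2.0, 3.0], [6.0, 4.0, 2.0]])
        cm = pearson_matrix(x, "genes", min_obs=3)
        assert cm.r.iloc[0, 1] == pytest.approx(-1.0)

    def test_hand_formula_value(self):
        """(1,2,3) vs (1,2,4): r = 0.98198..."""
        x = expr([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]])
        cm = pearson_matrix(x, "genes", min_obs=3)
        assert cm.r.iloc[0, 1] == pytest.approx(0.9819805060619659, abs=1e-12)

    def test_matches_brute_force_with_missing_data(self, rng):
        vals = rng.normal(0, 1, (8, 40))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        x = expr(vals)
        cm = pearson_matrix(x, "genes", min_obs=3)
        for i in range(8):
            for j in range(i + 1, 8):
                r_oracle, n = brute_pearson(vals[i], vals[j])
                if n >= 3:
                    assert cm.r.iloc[i, j] == pytest.approx(r_oracle, abs=1e-12)
                    assert cm.n_obs.iloc[i, j] == n
                else:
                    assert np.isnan(cm.r.iloc[i, j])

    def test_symmetry_and_bounds(self, rng):
        vals = rng.normal(0, 1, (10, 25))
        cm = pearson_matrix(expr(vals), "genes", min_obs=3)
        r = cm.r.to_numpy()
        assert np.allclose(r, r.T)
        assert np.nanmin(r) >= -1 - 1e-12 and np.nanmax(r) <= 1 + 1e-12

    def test_zero_variance_gives_na_with_warning(self):
        x = expr([[1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = pearson_matrix(x, "genes", min_obs=3)
        assert np.isnan(cm.r.iloc[0, 1])

    def test_min_obs_enforced(self, rng):
        vals = rng.normal(0, 1, (2, 20))
        vals[0, :15] = np.nan  # only 5 shared observations
        cm = pearson_matrix(expr(vals), "genes", min_obs=10)
        assert np.isnan(cm.r.iloc[0, 1])


class TestGraphFromCorrelations:
    def _cm(self, r):
        labels = [f"n{i}" for i in range(len(r))]
        rdf = pd.DataFrame(r, index=labels, columns=labels)
        n = pd.DataFrame(100, index=labels, columns=labels)
        return CorrelationMatrix(r=rdf, n_obs=n, axis="cells")

    def test_threshold_one_strict_empty(self):
        cm = self._cm([[1, 0.9], [0.9, 1]])
        g = graph_from_correlations(cm, 1.0, strict=True)
        assert g.n_edges == 0

    def test_three_node_read_off(self):
        cm = self._cm([[1, 0.6, 0.2], [0.6, 1, 0.7], [0.2, 0.7, 1]])
        g = graph_from_correlations(cm, 0.5, strict=True)
        assert g.has_edge("n0", "n1") and g.has_edge("n1", "n2")
        assert not g.has_edge("n0", "n2")
        assert g.n_edges == 2

    def test_strict_vs_nonstrict_boundary(self):
        cm = self._cm([[1, 0.5], [0.5, 1]])
        assert graph_from_correlations(cm, 0.5, strict=True).n_edges == 0
        assert graph_from_correlations(cm, 0.5, strict=False).n_edges == 1

    def test_na_never_makes_an_edge(self):
        cm = self._cm([[1, np.nan], [np.nan, 1]])
        assert graph_from_correlations(cm, -1.0, strict=False).n_edges == 0

    def test_degrees_match_brute_count(self, rng):
        r = rng.uniform(-1, 1, (20, 20))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        cm = self._cm(r)
        thr = 0.3
        g = graph_from_correlations(cm, thr, strict=True)
        for i in range(20):
            expected = sum(1 for j in range(20) if j != i and r[i, j] > thr)
            assert g.degree(f"n{i}") == expected

    @given(st.floats(min_value=-1, max_value=1), st.floats(min_value=-1, max_value=1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, t1, t2):
        """Raising the threshold never adds edges."""
        rng = np.random.default_rng(0)
        r = rng.uniform(-1, 1, (12, 12))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        cm = self._cm(r)
        lo, hi = sorted((t1, t2))
        e_lo = {frozenset((u, v)) for u, v, _ in graph_from_correlations(cm, lo).edges()}
        e_hi = {frozenset((u, v)) for u, v, _ in graph_from_correlations(cm, hi).edges()}
        assert e_hi <= e_lo


class TestPermutationThreshold:
    def test_seed_reproducible(self, rng):
        x = expr(rng.normal(0, 1, (10, 30)))
        a = permutation_threshold(x, "genes", n_perm=100, seed=5)
        b = permutation_threshold(x, "genes", n_perm=100, seed=5)
        assert a.threshold == b.threshold

    def test_familywise_controls_null_data(self):
        """On iid noise, observed correlations stay below the familywise
        threshold in at least 95% of runs (by construction of the max-null)."""
        hits = 0
        runs = 40
        for s in range(runs):
            g = np.random.default_rng(1000 + s)
            x = expr(g.normal(0, 1, (8, 40)))
            thr = permutation_threshold(
                x, "genes", n_perm=100, quantile=0.95, seed=s, mode="familywise"
            )
            r = pearson_matrix(x, "genes", min_obs=3).r.to_numpy()
            iu = np.triu_indices_from(r, k=1)
            if np.nanmax(r[iu]) <= thr.threshold:
                hits += 1
        assert hits / runs >= 0.8  # 95% nominal; binomial slack over 40 runs

    def test_strong_signal_exceeds_threshold(self, rng):
        """Two planted blocks with within-block r ~ 0.9 clear the null."""
        shared = rng.normal(0, 1, 50)
        vals = np.vstack(
            [shared + rng.normal(0, 0.33, 50) for _ in range(4)]
            + [rng.normal(0, 1, 50) for _ in range(4)]
        )
        x = expr(vals)
        thr = permutation_threshold(x, "genes", n_perm=100, quantile=0.99, seed=1)
        r = pearson_matrix(x, "genes", min_obs=3).r.to_numpy()
        for i in range(4):
            for j in range(i + 1, 4):
                assert r[i, j] > thr.threshold

    def test_row_shuffle_matches_fresh_iid_null(self):
        """Thresholds from row-shuffled data and from fresh iid data with the
        same marginals are distributionally indistinguishable (KS)."""
        shuffled_thr, fresh_thr = [], []
        for s in range(30):
            g = np.random.default_rng(2000 + s)
            base = g.normal(0, 1, (6, 30))
            shuffled_thr.append(
                permutation_threshold(expr(base), "genes", n_perm=100, seed=s).threshold
            )
            fresh = np.vstack([g.permutation(row) for row in base])
            fresh_thr.append(
                permutation_threshold(expr(fresh), "genes", n_perm=100, seed=500 + s).threshold
            )
        assert ks_2samp(shuffled_thr, fresh_thr).pvalue > 0.01

    def test_bad_quantile_rejected(self, rng):
        x = expr(rng.normal(0, 1, (5, 20)))
        with pytest.raises(ValueError, match="quantile"):
            permutation_threshold(x, "genes", n_perm=100, quantile=1.5)


class TestConditionalGeneNetwork:
    def test_all_cells_filter_reproduces_unconditional(self, rng):
        vals = rng.normal(0, 1, (12, 30))
        x = expr(vals)
        full = conditional_gene_network(x, lambda c: True, threshold=0.3)
        uncond = graph_from_correlations(pearson_matrix(x, "genes"), 0.3, strict=True)
        assert {frozenset((u, v)) for u, v, _ in full.edges()} == {
            frozenset((u, v)) for u, v, _ in uncond.edges()
        }

    def test_variance_restriction_collapses_hub_degree(self, rng):
        """A ligand driven by a binary on/off state correlates with its
        downstream genes over all cells, but within the 'on' subset its
        variance is pure noise and its degree collapses — the Vip+
        phenomenon."""
        n = 200
        on = np.repeat([1.0, 0.0], n // 2)
        ligand = 5 * on + rng.normal(0, 0.3, n)
        downstream = np.vstack([5 * on + rng.normal(0, 0.3, n) for _ in range(6)])
        x = expr(np.vstack([ligand, downstream]), index=["lig"] + [f"d{i}" for i in range(6)])
        full = graph_from_correlations(pearson_matrix(x, "genes"), 0.5, strict=True)
        mask = pd.Series(on > 0.5, index=x.values.columns)
        cond = conditional_gene_network(x, mask, threshold=0.5)
        assert full.degree("lig") == 6
        assert cond.degree("lig") == 0

    def test_small_subset_is_error_naming_filter(self, rng):
        x = expr(rng.normal(0, 1, (5, 30)))
        mask = pd.Series(False, index=x.values.columns, name="empty_subset")
        with pytest.raises(ValueError, match="empty_subset"):
            conditional_gene_network(x, mask)


class TestMinimumSpanningTree:
    def test_three_node_hand_case(self):
        d = pd.DataFrame(
            [[0, 1, 3], [1, 0, 2], [3, 2, 0]], index=list("ABC"), columns=list("ABC")
        )
        t = minimum_spanning_tree(d)
        assert t.has_edge("A", "B") and t.has_edge("B", "C") and not t.has_edge("A", "C")
        assert sum(w for _, _, w in t.edges()) == 3

    def test_edge_count_n_minus_one(self, rng):
        n = 15
        d = rng.uniform(0.1, 2, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        t = minimum_spanning_tree(pd.DataFrame(d))
        assert t.n_edges == n - 1

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_total_weight_matches_enumeration(self, n, rng):
        d = rng.uniform(0.1, 2, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        t = minimum_spanning_tree(pd.DataFrame(d))
        weights = {
            frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)
        }
        assert sum(w for _, _, w in t.edges()) == pytest.approx(
            mst_total_weight(n, weights), abs=1e-12
        )

    def test_disconnected_gives_forest_with_warning(self):
        d = pd.DataFrame(
            [[0, 1, np.nan], [1, 0, np.nan], [np.nan, np.nan, 0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        with pytest.warns(UserWarning, match="forest"):
            t = minimum_spanning_tree(d)
        assert t.n_edges == 1
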