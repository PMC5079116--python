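"""Regime classification, enrichment testing, screening, network assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from scnpheno import (
    ExpressionMatrix,
    GroupPartition,
    LigandReceptorPair,
    build_interaction_network,
    classify_regime,
    dominant_interaction_screen,
    regime_enrichment,
)
from oracles import fisher_tail

PAIR = LigandReceptorPair("Lig", "Rec")


def ddct(lig, rec):
    cells = [f"c{i}" for i in range(len(lig))]
    vals = pd.DataFrame([lig, rec], index=["Lig", "Rec"], columns=cells, dtype=float)
    return ExpressionMatrix(vals, "minus_ddCt")


class TestClassifyRegime:
    def test_quadrant_truth_table(self):
        """The four sign quadrants map exactly to source/target/autocrine/none."""
        x = ddct([1.0, -1.0, 1.0, -1.0], [-1.0, 1.0, 1.0, -1.0])
        regime = classify_regime(x, PAIR).regime
        assert regime.tolist() == ["source", "target", "autocrine", "none"]

    def test_boundaries_are_nonpositive(self):
        """Exactly zero counts as 'low' on both axes."""
        x = ddct([0.0, 0.0, 1.0], [0.0, 1.0, 0.0])
        regime = classify_regime(x, PAIR).regime
        assert regime.tolist() == ["none", "target", "source"]

    def test_missing_value_gives_none_with_flag(self):
        x = ddct([np.nan, 1.0], [1.0, 1.0])
        res = classify_regime(x, PAIR)
        assert res.regime.iloc[0] == "none" and res.missing.iloc[0]
        assert res.regime.iloc[1] == "autocrine" and not res.missing.iloc[1]

    def test_every_cell_in_exactly_one_regime(self, rng):
        x = ddct(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
        res = classify_regime(x, PAIR)
        assert res.counts().sum() == 100

    def test_ligand_equal_receptor_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            LigandReceptorPair("Vip", "Vip")


class TestRegimeEnrichment:
    def _partition(self, labels, cells):
        return GroupPartition(assignment=pd.Series(labels, index=cells))

    def test_group_identical_to_regime_closed_form(self):
        """Group of 10 out of 100 = exactly the source set: p = 1/C(100,10)."""
        n = 100
        lig = np.full(n, -1.0)
        rec = np.full(n, -1.0)
        lig[:10] = 1.0  # first 10 are sources
        x = ddct(lig, rec)
        labels = [1] * 10 + [2] * 90
        table = regime_enrichment([classify_regime(x, PAIR)], self._partition(labels, x.cell_ids))
        row = table[(table.group == 1) & (table.regime == "source")].iloc[0]
        assert row.fraction == 1.0
        assert row.p_value == pytest.approx(1.0 / comb(100, 10, exact=True), rel=1e-9)

    def test_population_fraction_is_nonsignificant(self):
        """A group whose regime fraction equals the population fraction gets
        a large one-sided p."""
        n = 200
        lig = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)  # 50% sources everywhere
        rec = np.full(n, -1.0)
        x = ddct(lig, rec)
        labels = [1] * 40 + [2] * 160
        table = regime_enrichment([classify_regime(x, PAIR)], self._partition(labels, x.cell_ids))
        row = table[(table.group == 1) & (table.regime == "source")].iloc[0]
        assert row.p_value > 0.4

    def test_matches_exact_tail_enumeration(self, rng):
        """Fisher tail agreement with direct hypergeometric summation on
        random tables with n <= 60."""
        for _ in range(30):
            n = int(rng.integers(10, 61))
            k_group = int(rng.integers(1, n))
            k_regime = int(rng.integers(1, n))
            lig = np.full(n, -1.0)
            lig[rng.permutation(n)[:k_regime]] = 1.0
            rec = np.full(n, -1.0)
            x = ddct(lig, rec)
            labels = np.full(n, 2)
            labels[rng.permutation(n)[:k_group]] = 1
            table = regime_enrichment(
                [classify_regime(x, PAIR)], self._partition(labels, x.cell_ids)
            )
            row = table[(table.group == 1) & (table.regime == "source")].iloc[0]
            a = int(row.n_group_regime)
            oracle = fisher_tail(
                a, k_group - a, k_regime - a, n - k_group - k_regime + a
            )
            assert row.p_value == pytest.approx(oracle, abs=1e-12)

    def test_specific_2x2_table(self):
        """[8, 2; 2, 88]: one-sided p from tail summation."""
        n = 100
        lig = np.full(n, -1.0)
        lig[:8] = 1.0
        lig[10:12] = 1.0
        rec = np.full(n, -1.0)
        x = ddct(lig, rec)
        labels = np.full(n, 2)
        labels[:10] = 1
        table = regime_enrichment([classify_regime(x, PAIR)], self._partition(labels, x.cell_ids))
        row = table[(table.group == 1) & (table.regime == "source")].iloc[0]
        assert [row.n_group_regime, row.n_group - row.n_group_regime] == [8, 2]
        assert row.p_value == pytest.approx(fisher_tail(8, 2, 2, 88), abs=1e-12)

    def test_monotone_in_group_regime_overlap(self):
        """Moving one more group member into the regime never increases p."""
        n = 60
        rec = np.full(n, -1.0)
        labels = np.full(n, 2)
        labels[:15] = 1
        prev = 1.1
        for a in range(0, 16):
            lig = np.full(n, -1.0)
            lig[:a] = 1.0  # a group members in regime
            x = ddct(lig, rec)
            table = regime_enrichment(
                [classify_regime(x, PAIR)], self._partition(labels, x.cell_ids)
            )
            row = table[(table.group == 1) & (table.regime == "source")].iloc[0]
            assert row.p_value <= prev + 1e-12
            prev = row.p_value

    def test_missing_cells_excluded_from_counts(self):
        lig = [1.0, np.nan, 1.0, -1.0]
        rec = [-1.0, -1.0, -1.0, -1.0]
        x = ddct(lig, rec)
        table = regime_enrichment(
            [classify_regime(x, PAIR)], self._partition([1, 1, 2, 2], x.cell_ids)
        )
        assert (table.n_total == 3).all()


class TestDominantInteractionScreen:
    def test_identical_vectors_always_retained(self, rng):
        v = rng.normal(0, 1, 50)
        res = dominant_interaction_screen(ddct(v, v), [PAIR], n_perm=100, seed=0)
        assert res.retained == [PAIR]
        assert res.observed_r[PAIR.name] == pytest.approx(1.0)

    def test_constant_vector_skipped_with_warning(self, rng):
        x = ddct(np.full(30, 1.0), rng.normal(0, 1, 30))
        with pytest.warns(UserWarning, match="constant"):
            res = dominant_interaction_screen(x, [PAIR], n_perm=100, seed=0)
        assert res.retained == [] and res.skipped == [PAIR]

    def test_seed_reproduces_retained_set(self, rng):
        x = ddct(rng.normal(0, 1, 80), rng.normal(0, 1, 80))
        a = dominant_interaction_screen(x, [PAIR], n_perm=200, seed=7)
        b = dominant_interaction_screen(x, [PAIR], n_perm=200, seed=7)
        assert a.null_quantile.equals(b.null_quantile)
        assert [p.name for p in a.retained] == [p.name for p in b.retained]

    def test_null_retention_near_nominal(self):
        """Independent-noise pairs are retained ~5% of the time at the 0.95
        null quantile (spot check; the 500-run calibration lives in the
        acceptance suite)."""
        hits = 0
        runs = 100
        for s in range(runs):
            g = np.random.default_rng(s)
            x = ddct(g.normal(0, 1, 200), g.normal(0, 1, 200))
            res = dominant_interaction_screen(x, [PAIR], n_perm=100, seed=10_000 + s)
            hits += bool(res.retained)
        assert 0 <= hits / runs <= 0.12


class TestBuildInteractionNetwork:
    def _enrichment(self, rows):
        df = pd.DataFrame(
            rows, columns=["pair", "group", "regime", "fraction", "p_value"]
        )
        df["significant"] = df["p_value"] < 0.05
        return df

    def test_single_source_target_pair_one_edge(self):
        enr = self._enrichment(
            [
                ("Lig-Rec", 1, "source", 0.9, 1e-6),
                ("Lig-Rec", 2, "target", 0.8, 1e-5),
                ("Lig-Rec", 3, "source", 0.2, 0.9),
            ]
        )
        net = build_interaction_network(enr, [PAIR])
        assert net.n_edges == 1
        e = net.edges[0]
        assert (e.source, e.target, e.pair) == (1, 2, "Lig-Rec")
        assert e.source_fraction == 0.9 and e.target_fraction == 0.8

    def test_no_significance_no_edges(self):
        enr = self._enrichment([("Lig-Rec", 1, "source", 0.5, 0.5)])
        assert build_interaction_network(enr, [PAIR]).n_edges == 0

    def test_autocrine_self_loop(self):
        enr = self._enrichment([("Lig-Rec", 2, "autocrine", 0.7, 1e-4)])
        net = build_interaction_network(enr, [PAIR])
        assert net.n_edges == 1
        assert net.edges[0].source == net.edges[0].target == 2

    def test_unretained_pair_contributes_nothing(self):
        enr = self._enrichment(
            [("Lig-Rec", 1, "source", 0.9, 1e-6), ("Lig-Rec", 2, "target", 0.8, 1e-5)]
        )
        assert build_interaction_network(enr, []).n_edges == 0

    def test_tightening_alpha_only_removes_edges(self):
        enr = self._enrichment(
            [
                ("Lig-Rec", 1, "source", 0.9, 1e-6),
                ("Lig-Rec", 2, "target", 0.8, 1e-2),
                ("Lig-Rec", 3, "target", 0.9, 1e-8),
            ]
        )
        loose = build_interaction_network(enr, [PAIR], alpha=0.05)
        tight = build_interaction_network(enr, [PAIR], alpha=1e-4)
        loose_set = {(e.source, e.target, e.pair) for e in loose.edges}
        tight_set = {(e.source, e.target, e.pair) for e in tight.edges}
        assert tight_set <= loose_set and len(tight_set) < len(loose_set)


class TestEndToEndPlantedInteractions:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_planted_source_target_edge_recovered(self, seed):
        """A dataset generated with group A as paracrine source and group B
        as target for a pair yields the directed edge A -> B via that pair."""
        from scnpheno import default_config, generate_dataset, median_center, to_minus_dct
        from scnpheno.community import detect_communities, pool_residual
        from scnpheno.networks import cell_network

        cfg = default_config(seed=seed)
        ct, truth = generate_dataset(cfg)
        x = median_center(to_minus_dct(ct))
        lp = [c for c in x.cell_ids if ct.treatment[c] == "LP"]
        sub = ExpressionMatrix(x.values[lp], "minus_ddCt")
        part = pool_residual(cell_network(sub), detect_communities(cell_network(sub)))
        pairs = [LigandReceptorPair(p.ligand, p.receptor) for p in cfg.lr_pairs]
        enr = regime_enrichment([classify_regime(sub, p) for p in pairs], part)
        screen = dominant_interaction_screen(sub, pairs, n_perm=200, seed=seed)
        net = build_interaction_network(enr, screen, part)

        # map planted labels to detected ids by majority vote
        detected = part.assignment
        mapping = {}
        for lab in truth.true_group.unique():
            cells = [c for c in lp if truth.true_group[c] == lab]
            mapping[lab] = detected.loc[cells].mode().iloc[0]
        edge_set = {(e.source, e.target, e.pair) for e in net.edges}
        for p in cfg.lr_pairs:
            assert (mapping[p.source_group], mapping[p.target_group], p.name) in edge_set
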