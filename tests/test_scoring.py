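"""Importance, evidence, modulation scores and the permutation null."""

import numpy as np
import pandas as pd
import pytest

from boolpath.boolrules import Rule
from boolpath.data import CombinedDataset, binarize
from boolpath.inference import EquivalentRuleSet, TrainingStates
from boolpath.network import SignedNetwork
from boolpath.scoring import (
    bh_adjust,
    evidence_score,
    importance_scores,
    modulation_table,
    node_modulation,
    pathway_modulation,
    permutation_pvalue,
)
from boolpath.synthetic import (
    generate_ground_truth,
    generate_multiomics,
    generate_network,
)

from conftest import make_layer


def singleton_ers(rules: dict[str, Rule]) -> dict[str, EquivalentRuleSet]:
    return {
        n: EquivalentRuleSet(target=n, rules=(r,), fitness=0.0)
        for n, r in rules.items()
    }


@pytest.fixture
def chain_world(chain_network):
    """A -> B with the activating rule and one training state."""
    rule = Rule("B", (("A", 1),), frozenset({frozenset({0})}))
    layer = make_layer("l", {"A": [8.0, 4.0], "B": [8.0, 4.0]}, ["s1", "s2"])
    ds = CombinedDataset(layers=[layer], design={"s1": "c1", "s2": "c0"})
    return chain_network, singleton_ers({"B": rule}), ds


class TestImportance:
    def test_chain_source_scores_one_per_state(self, chain_world):
        net, ers, ds = chain_world
        imp = importance_scores(net, ers, binarize(ds), n_rule_samples=1, seed=0)
        # B is 0 under A-knockout and 1 under A-knock-in, in each of the
        # 2 training states -> I_A = 2
        assert imp["A"] == pytest.approx(2.0)

    def test_sink_scores_zero(self, chain_world):
        net, ers, ds = chain_world
        imp = importance_scores(net, ers, binarize(ds), n_rule_samples=1, seed=0)
        assert imp["B"] == 0.0

    def test_edgeless_network_all_zero(self):
        net = SignedNetwork.from_edges("flat", ["A", "B", "C"], [])
        layer = make_layer(
            "l", {g: [8.0, 4.0] for g in "ABC"}, ["s1", "s2"]
        )
        ds = CombinedDataset(layers=[layer], design={"s1": "c1", "s2": "c0"})
        imp = importance_scores(net, {}, binarize(ds), n_rule_samples=1, seed=0)
        assert (imp.scores == 0).all()

    def test_seeded_reproducibility(self):
        net = generate_network(8, seed=61)
        truth = generate_ground_truth(net, seed=62)
        ds, _ = generate_multiomics(truth, seed=63)
        ers = singleton_ers(truth.rules)
        a = importance_scores(net, ers, binarize(ds), n_rule_samples=3, seed=7)
        b = importance_scores(net, ers, binarize(ds), n_rule_samples=3, seed=7)
        pd.testing.assert_series_equal(a.scores, b.scores)

    def test_invalid_rule_samples(self, chain_world):
        net, ers, ds = chain_world
        with pytest.raises(ValueError):
            importance_scores(net, ers, binarize(ds), n_rule_samples=0)


class TestEvidence:
    def test_layer_counting(self):
        l1 = make_layer("a", {"G1": [1.0, 2.0], "G2": [1.0, 2.0]}, ["s1", "s2"])
        l2 = make_layer("b", {"G1": [1.0, 2.0]}, ["s1", "s2"])
        l3 = make_layer("c", {"G3": [1.0, 2.0]}, ["s1", "s2"])
        ds = CombinedDataset(layers=[l1, l2, l3], design={"s1": "c0", "s2": "c1"})
        assert evidence_score("G1", ds) == 2
        assert evidence_score("G2", ds) == 1
        assert evidence_score("NOPE", ds) == 0

    def test_upper_bound_is_layer_count(self):
        layers = [
            make_layer(f"l{i}", {"G": [1.0, 2.0]}, ["s1", "s2"]) for i in range(3)
        ]
        ds = CombinedDataset(layers=layers, design={"s1": "c0", "s2": "c1"})
        assert evidence_score("G", ds) == 3


class TestModulation:
    def test_hand_computed_combination(self):
        """I=2, E=2, layer terms |FC|*CV = 0.5 and 0.25 -> M = 3.0."""
        # layer a: |FC|=2, CV=0.25 -> 0.5 ; layer b: |FC|=1, CV=0.25 -> 0.25
        # gene values chosen to produce exactly those statistics
        la = make_layer("a", {"G": [5.0, 3.0]}, ["s1", "s2"])  # FC=2, sd/mean=sqrt2/4
        ds_fc_a = np.abs(5.0 - 3.0)
        cv_a = np.std([5, 3], ddof=1) / 4.0
        lb = make_layer("b", {"G": [4.5, 3.5]}, ["s1", "s2"])
        ds = CombinedDataset(layers=[la, lb], design={"s1": "c1", "s2": "c0"})
        imp = type("I", (), {"__getitem__": lambda self, g: 2.0})()
        m = node_modulation("G", ("c1", "c0"), imp, ds)
        cv_b = np.std([4.5, 3.5], ddof=1) / 4.0
        expected = 2.0 * 2 * (ds_fc_a * cv_a + 1.0 * cv_b)
        assert m == pytest.approx(expected)

    def test_zero_importance_zero_modulation(self, chain_world):
        net, ers, ds = chain_world
        imp = importance_scores(net, ers, binarize(ds), n_rule_samples=1, seed=0)
        assert imp["B"] == 0.0
        assert node_modulation("B", ("c1", "c0"), imp, ds) == 0.0

    def test_zero_fold_change_zero_modulation(self):
        net = SignedNetwork.from_edges("c", ["A", "B"], [("A", "B", 1)])
        rule = Rule("B", (("A", 1),), frozenset({frozenset({0})}))
        # A varies within each condition identically -> FC = 0
        layer = make_layer(
            "l", {"A": [8.0, 4.0, 8.0, 4.0], "B": [8.0, 4.0, 8.0, 4.0]},
            ["s1", "s2", "s3", "s4"],
        )
        ds = CombinedDataset(
            layers=[layer],
            design={"s1": "c1", "s2": "c1", "s3": "c0", "s4": "c0"},
        )
        imp = importance_scores(net, singleton_ers({"B": rule}), binarize(ds),
                                n_rule_samples=1, seed=0)
        assert imp["A"] > 0
        assert node_modulation("A", ("c1", "c0"), imp, ds) == 0.0

    def test_pathway_modulation_additive(self, chain_world):
        net, ers, ds = chain_world
        imp = importance_scores(net, ers, binarize(ds), n_rule_samples=1, seed=0)
        contrast = ("c1", "c0")
        total = pathway_modulation(net, contrast, imp, ds)
        by_gene = sum(node_modulation(g, contrast, imp, ds) for g in net.nodes)
        assert total == pytest.approx(by_gene)
        table = modulation_table(net, contrast, imp, ds)
        assert total == pytest.approx(table["modulation"].sum())

    def test_scale_invariance_of_z(self):
        """Scaling all abundances by c scales M_g, M_p by c^2 (FC and CV
        numerator both scale; CV denominator scales too, so CV is scale
        free and FC scales linearly) while z-scores are unchanged."""
        net = generate_network(8, seed=71)
        truth = generate_ground_truth(net, seed=72)
        ds, contrasts = generate_multiomics(truth, seed=73)
        name, ca, cb = contrasts.contrasts[0]
        ers = singleton_ers(truth.rules)
        imp = importance_scores(net, ers, binarize(ds), n_rule_samples=1, seed=0)

        scaled_layers = [
            make_layer(l.name, {g: (2.0 * l.abundance.loc[g]).tolist() for g in l.genes},
                       l.sample_ids)
            for l in ds.layers
        ]
        ds2 = CombinedDataset(layers=scaled_layers, design=ds.design)
        r1 = permutation_pvalue(net, name, (ca, cb), imp, ds, seed=5)
        r2 = permutation_pvalue(net, name, (ca, cb), imp, ds2, seed=5)
        # CV is invariant, FC doubles -> M_p doubles, z unchanged
        assert r2.modulation == pytest.approx(2.0 * r1.modulation)
        assert r2.z_score == pytest.approx(r1.z_score)
        assert r2.p_value == pytest.approx(r1.p_value)


class TestPermutation:
    def test_z_zero_maps_to_half(self):
        from scipy.stats import norm

        assert norm.sf(0.0) == 0.5

    def test_strong_signal_small_p(self):
        """A pathway whose genes carry far larger fold-changes than the
        background pool must reach p < 0.001."""
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(10)] + [f"BG{i}" for i in range(200)]
        cols = {}
        for s, cond in [("s1", "c1"), ("s2", "c1"), ("s3", "c0"), ("s4", "c0")]:
            base = np.where([g.startswith("G") and cond == "c1" for g in genes], 9.0, 5.0)
            cols[s] = base + rng.normal(0, 0.2, len(genes))
        layer = make_layer("l", dict(zip(genes, np.column_stack(list(cols.values())).tolist())),
                           list(cols))
        ds = CombinedDataset(
            layers=[layer], design={"s1": "c1", "s2": "c1", "s3": "c0", "s4": "c0"}
        )
        net = SignedNetwork.from_edges(
            "hot", [f"G{i}" for i in range(10)],
            [(f"G{i}", f"G{i+1}", 1) for i in range(9)],
        )
        imp = type("I", (), {"__getitem__": lambda self, g: 1.0})()
        res = permutation_pvalue(net, "c", ("c1", "c0"), imp, ds,
                                 n_permutations=1000, seed=1)
        assert res.p_value < 0.001

    def test_point_mass_null_degenerates(self, chain_world):
        """When the pool holds a single (FC, CV) pair per layer the null
        is a point mass and p falls back to the sign convention."""
        net = SignedNetwork.from_edges("solo", ["A", "B"], [("A", "B", 1)])
        layer = make_layer("l", {"A": [8.0, 4.0], "B": [8.0, 4.0]}, ["s1", "s2"])
        ds = CombinedDataset(layers=[layer], design={"s1": "c1", "s2": "c0"})
        rule = Rule("B", (("A", 1),), frozenset({frozenset({0})}))
        imp = importance_scores(net, singleton_ers({"B": rule}), binarize(ds),
                                n_rule_samples=1, seed=0)
        # both genes have identical (|FC|, CV) -> every draw reproduces M_p
        res = permutation_pvalue(net, "c", ("c1", "c0"), imp, ds,
                                 n_permutations=200, seed=2)
        assert res.null_sd == 0.0
        assert res.p_value == 0.5

    def test_importance_is_contrast_invariant(self):
        """I_g recomputed for another contrast is bitwise identical."""
        net = generate_network(8, seed=81)
        truth = generate_ground_truth(net, n_conditions=3, seed=82)
        ds, contrasts = generate_multiomics(truth, seed=83)
        ers = singleton_ers(truth.rules)
        a = importance_scores(net, ers, binarize(ds), n_rule_samples=2, seed=11)
        b = importance_scores(net, ers, binarize(ds), n_rule_samples=2, seed=11)
        assert (a.scores == b.scores).all()

    def test_min_permutations_enforced(self, chain_world):
        net, ers, ds = chain_world
        imp = importance_scores(net, ers, binarize(ds), n_rule_samples=1, seed=0)
        with pytest.raises(ValueError):
            permutation_pvalue(net, "c", ("c1", "c0"), imp, ds, n_permutations=10)


def reference_bh(pvalues: np.ndarray) -> np.ndarray:
    """Hand-rolled step-up BH, the independent check for bh_adjust."""
    n = len(pvalues)
    order = np.argsort(pvalues)
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        value = pvalues[i] * n / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


class TestBHAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_matches_independent_step_up(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            p = rng.uniform(size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(reference_bh(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
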