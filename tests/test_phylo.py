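"""Mk likelihoods, rate fitting and stochastic character mapping."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from xericfish.phylo import (fit_mk, marginal_ancestral_probs, mk_loglik,
                             prune_tree, stochastic_maps)
from xericfish.synth import gen_traits_and_tree


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestPrune:
    def test_identity_prune_keeps_topology(self):
        _, tree, states = gen_traits_and_tree(n_species=20, q_true=0.4, seed=1)
        sub = prune_tree(tree, list(states))
        assert len(sub.leaf_nodes()) == 20

    def test_two_tip_prune_preserves_path_length(self):
        tree = _tree("((A:1,B:2):3,(C:4,D:5):6);")
        with np.errstate(all="ignore"):
            sub = prune_tree(tree, ["A", "C"])
        assert len(sub.leaf_nodes()) == 2
        pdm = sub.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in sub.taxon_namespace}
        assert pdm.patristic_distance(taxa["A"], taxa["C"]) == pytest.approx(
            1 + 3 + 6 + 4)

    def test_random_subsets_preserve_patristic_distances(self, rng):
        _, tree, states = gen_traits_and_tree(n_species=30, q_true=0.4, seed=2)
        labels = sorted(states)
        keep = list(rng.choice(labels, size=12, replace=False))
        sub = prune_tree(tree, keep)
        pdm_f = tree.phylogenetic_distance_matrix()
        pdm_s = sub.phylogenetic_distance_matrix()
        tf = {t.label: t for t in tree.taxon_namespace}
        ts = {t.label: t for t in sub.taxon_namespace}
        for a, b in zip(keep[:6], keep[6:]):
            assert pdm_f.patristic_distance(tf[a], tf[b]) == pytest.approx(
                pdm_s.patristic_distance(ts[a], ts[b]))

    def test_too_few_matches_rejected(self):
        tree = _tree("((A:1,B:2):3,C:4);")
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                prune_tree(tree, ["A", "zzz"])


class TestMkLikelihood:
    def test_three_taxon_enumeration(self):
        tree = _tree("((A:0.3,B:0.7):0.5,C:1.0);")
        states = {"A": 0, "B": 1, "C": 0}
        q = 0.8

        def P(t, i, j):
            ps = 0.5 * (1 + math.exp(-2 * q * t))
            return ps if i == j else 1 - ps

        brute = sum(
            0.5 * P(0.5, r, m) * P(0.3, m, 0) * P(0.7, m, 1) * P(1.0, r, 0)
            for r, m in itertools.product([0, 1], repeat=2))
        assert mk_loglik(tree, states, q) == pytest.approx(math.log(brute))

    def test_rate_to_zero_limit_on_monomorphic_cherry(self):
        tree = _tree("(A:1,B:1);")
        lik = math.exp(mk_loglik(tree, {"A": 0, "B": 0}, 1e-9))
        assert lik == pytest.approx(0.5, abs=1e-6)

    def test_infinite_rate_limit_is_per_tip_independence(self):
        tree = _tree("((A:0.3,B:0.7):0.5,C:1.0);")
        lik = math.exp(mk_loglik(tree, {"A": 0, "B": 1, "C": 0}, 1e4))
        assert lik == pytest.approx(0.5 ** 3, rel=1e-4)

    def test_state_relabeling_symmetry(self):
        _, tree, states = gen_traits_and_tree(n_species=15, q_true=0.5, seed=5)
        flipped = {k: 1 - v for k, v in states.items()}
        assert mk_loglik(tree, states, 0.7) == pytest.approx(
            mk_loglik(tree, flipped, 0.7))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mk_loglik(_tree("(A:1,B:1);"), {"A": 0, "B": 0}, -1.0)


class TestFitMk:
    def test_monomorphic_tips_hit_lower_boundary(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_mk(tree, {"A": 1, "B": 1, "C": 1})
        assert fit.q <= 1e-6

    def test_optimum_beats_grid(self):
        _, tree, states = gen_traits_and_tree(n_species=25, q_true=0.5, seed=6)
        fit = fit_mk(tree, states)
        grid = np.geomspace(0.01, 10, 50)
        assert all(fit.loglik >= mk_loglik(tree, states, g) - 1e-6
                   for g in grid)

    def test_rate_recovery_within_factor_three(self):
        hits = total = 0
        for seed in range(12):
            _, tree, states = gen_traits_and_tree(n_species=100, q_true=0.3,
                                                  seed=seed)
            if len(set(states.values())) < 2:
                continue
            fit = fit_mk(tree, states)
            total += 1
            hits += 0.1 <= fit.q <= 0.9
        assert total >= 8 and hits / total >= 0.8


class TestStochasticMaps:
    def test_all_tips_state_one_gives_certain_nodes(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        sm = stochastic_maps(tree, {t: 1 for t in "ABCD"}, 1e-8,
                             n_maps=50, seed=0)
        assert np.allclose(sm.table["p_state1"], 1.0)

    def test_symmetric_half_split_root_near_half(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        sm = stochastic_maps(tree, {"A": 1, "B": 1, "C": 0, "D": 0}, 0.5,
                             n_maps=2000, seed=1)
        root = sm.table.loc[~sm.table["is_leaf"]].iloc[-1]
        assert root["p_state1"] == pytest.approx(0.5, abs=0.05)

    def test_node_frequencies_match_pruning_marginals(self):
        _, tree, states = gen_traits_and_tree(n_species=40, q_true=0.5, seed=2)
        fit = fit_mk(tree, states)
        marg = marginal_ancestral_probs(tree, states, fit.q)
        sm = stochastic_maps(tree, states, fit, n_maps=500, seed=3)
        m = marg.merge(sm.table, on=["node", "is_leaf"],
                       suffixes=("_marg", "_map"))
        internal = m[~m["is_leaf"]]
        se = np.sqrt(internal["p_state1_marg"]
                     * (1 - internal["p_state1_marg"]) / 500)
        dev = (internal["p_state1_map"] - internal["p_state1_marg"]).abs()
        assert (dev <= 3 * se + 1e-9).all()

    def test_tips_keep_observed_state(self):
        _, tree, states = gen_traits_and_tree(n_species=12, q_true=0.5, seed=7)
        sm = stochastic_maps(tree, states, 0.4, n_maps=100, seed=4)
        tips = sm.table[sm.table["is_leaf"]].set_index("node")["p_state1"]
        for label, s in states.items():
            assert tips[label] == float(s)

    def test_state_flip_mirrors_probabilities(self):
        _, tree, states = gen_traits_and_tree(n_species=15, q_true=0.5, seed=9)
        flipped = {k: 1 - v for k, v in states.items()}
        a = marginal_ancestral_probs(tree, states, 0.6)
        b = marginal_ancestral_probs(tree, flipped, 0.6)
        m = a.merge(b, on=["node", "is_leaf"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(m["p_state1_a"], 1 - m["p_state1_b"],
                                   atol=1e-9)

    def test_monte_carlo_error_shrinks_with_more_maps(self):
        _, tree, states = gen_traits_and_tree(n_species=20, q_true=0.5, seed=4)
        fit = fit_mk(tree, states)
        marg = marginal_ancestral_probs(tree, states, fit.q)
        errs = []
        for n_maps in (100, 2000):
            sm = stochastic_maps(tree, states, fit, n_maps=n_maps, seed=11)
            m = marg.merge(sm.table, on=["node", "is_leaf"],
                           suffixes=("_marg", "_map"))
            internal = m[~m["is_leaf"]]
            errs.append(np.sqrt(np.mean(
                (internal["p_state1_map"] - internal["p_state1_marg"]) ** 2)))
        assert errs[1] < errs[0]
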