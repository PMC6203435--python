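"""Pagel likelihoods, Monte-Carlo tests, and Bonferroni correction."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from rh1coev.correlated_evo import (
    RATE_NAMES_4,
    UntestableTraitError,
    _q_from_rates8,
    bonferroni,
    expand_independent_rates,
    fit_pagel,
    pagel_lnL,
    pagel_mc_test,
    simulate_joint_traits,
)
from rh1coev.trees import CladeTree, TreeArrays, balanced_tree


def _traits(ta, x, y):
    return dict(zip(ta.leaf_names, x)), dict(zip(ta.leaf_names, y))


class TestPagelLnL:
    def test_zero_length_tree_gives_root_probability(self):
        tree = CladeTree.from_newick("(a:0.0,b:0.0,c:0.0);")
        tx = {"a": 0, "b": 0, "c": 0}
        ty = {"a": 0, "b": 0, "c": 0}
        rates = np.array([1.0, 1.0, 1.0, 1.0])
        lnL = pagel_lnL(tree, tx, ty, "independent", rates)
        # stationary distribution of the symmetric chain is uniform
        assert lnL == pytest.approx(np.log(0.25), abs=1e-9)

    def test_dependent_with_tied_rates_equals_independent(self):
        tree = balanced_tree(8, 1.0)
        ta = TreeArrays.from_clade_tree(tree)
        rng = np.random.default_rng(0)
        x, y = simulate_joint_traits(
            ta, expand_independent_rates([1.0, 0.7, 1.3, 0.9]), 1, rng
        )
        tx, ty = _traits(ta, x[0], y[0])
        r4 = np.array([0.8, 1.2, 0.5, 1.5])
        li = pagel_lnL(tree, tx, ty, "independent", r4)
        ld = pagel_lnL(tree, tx, ty, "dependent",
                       expand_independent_rates(r4))
        assert ld == pytest.approx(li, abs=1e-12)

    def test_three_leaf_enumeration_oracle(self):
        tree = CladeTree.from_newick("((a:0.4,b:0.7):0.3,c:1.0);")
        tx = {"a": 1, "b": 0, "c": 0}
        ty = {"a": 1, "b": 1, "c": 0}
        r8 = np.array([2.0, 0.5, 1.0, 1.5, 0.7, 2.5, 0.3, 1.2])
        got = pagel_lnL(tree, tx, ty, "dependent", r8)

        ta = TreeArrays.from_clade_tree(tree)
        h = 1.0  # tree height: rates are per unit height; height == 1 here
        Q = _q_from_rates8(r8)
        A = np.vstack([Q.T, np.ones(4)])
        pi = np.linalg.lstsq(A, np.array([0, 0, 0, 0, 1.0]), rcond=None)[0]
        leaf_state = {}
        for i, name in enumerate(ta.leaf_names):
            leaf_state[i] = 2 * tx[name] + ty[name]
        internals = [n for n in range(ta.n_nodes) if ta.children[n]]
        Ps = {n: expm(Q * ta.edge_length[n]) for n in range(ta.n_nodes)
              if n != ta.root}
        acc = 0.0
        for states in itertools.product(range(4), repeat=len(internals)):
            assign = dict(zip(internals, states))
            assign.update(leaf_state)
            term = pi[assign[ta.root]]
            for n in range(ta.n_nodes):
                if n != ta.root:
                    term *= Ps[n][assign[ta.parent[n]], assign[n]]
            acc += term
        assert got == pytest.approx(np.log(acc), abs=1e-10)

    def test_relabeling_invariance_with_rate_swap(self):
        tree = balanced_tree(10, 1.0)
        ta = TreeArrays.from_clade_tree(tree)
        rng = np.random.default_rng(1)
        x, y = simulate_joint_traits(
            ta, expand_independent_rates([1, 1, 1, 1]), 1, rng
        )
        tx, ty = _traits(ta, x[0], y[0])
        tx_flip = {k: 1 - v for k, v in tx.items()}
        r8 = np.array([2.0, 0.5, 1.0, 1.5, 0.7, 2.5, 0.3, 1.2])
        # flip trait x: gains become losses and the y-rates swap x-context
        r8_flip = np.array([r8[2], r8[3], r8[0], r8[1],
                            r8[5], r8[4], r8[7], r8[6]])
        a = pagel_lnL(tree, tx, ty, "dependent", r8)
        b = pagel_lnL(tree, tx_flip, ty, "dependent", r8_flip)
        assert b == pytest.approx(a, abs=1e-10)

    def test_positive_rates_required(self):
        tree = balanced_tree(4, 1.0)
        tx = {t: 0 for t in tree.taxa}
        with pytest.raises(ValueError):
            pagel_lnL(tree, tx, tx, "independent", [1.0, 0.0, 1.0, 1.0])


class TestFitAndMC:
    def test_lrt_stat_nonnegative_and_nested(self):
        tree = balanced_tree(12, 1.0)
        ta = TreeArrays.from_clade_tree(tree)
        rng = np.random.default_rng(2)
        x, y = simulate_joint_traits(
            ta, expand_independent_rates([1, 1, 1, 1]), 1, rng
        )
        tx, ty = _traits(ta, x[0], y[0])
        fit = fit_pagel(tree, tx, ty, n_starts=2, seed=0)
        assert fit.lrt_stat >= 0.0
        assert fit.lnL_dep >= fit.lnL_indep - 1e-6
        assert set(fit.rates_indep) == set(RATE_NAMES_4)

    def test_monomorphic_trait_untestable(self):
        tree = balanced_tree(6, 1.0)
        tx = {t: 0 for t in tree.taxa}
        ty = {t: i % 2 for i, t in enumerate(tree.taxa)}
        with pytest.raises(UntestableTraitError):
            pagel_mc_test(tree, tx, ty, n_sim=9, seed=0)

    def test_p_mc_never_zero_and_in_range(self):
        tree = balanced_tree(10, 1.0)
        ta = TreeArrays.from_clade_tree(tree)
        rng = np.random.default_rng(3)
        x, y = simulate_joint_traits(
            ta, expand_independent_rates([1, 1, 1, 1]), 1, rng
        )
        tx, ty = _traits(ta, x[0], y[0])
        res = pagel_mc_test(tree, tx, ty, n_sim=49, seed=1,
                            n_starts=1, sim_n_starts=0, maxiter=120,
                            sim_maxiter=120)
        assert 1.0 / 50.0 <= res.p_mc <= 1.0

    def test_power_against_strongly_dependent_traits(self):
        """State-dependent rates on a 60-leaf tree are detected."""
        tree = balanced_tree(60, 1.0)
        ta = TreeArrays.from_clade_tree(tree)
        # y switches fast only when x == 1
        r8 = np.array([1.0, 1.0, 1.0, 1.0, 0.05, 8.0, 0.05, 8.0])
        hits = 0
        n_rep = 8
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            x, y = simulate_joint_traits(ta, r8, 1, rng)
            if len(set(x[0])) < 2 or len(set(y[0])) < 2:
                continue
            tx, ty = _traits(ta, x[0], y[0])
            res = pagel_mc_test(tree, tx, ty, n_sim=99, seed=rep,
                                n_starts=1, sim_n_starts=0,
                                maxiter=150, sim_maxiter=150)
            hits += res.p_mc < 0.05
        assert hits >= 0.8 * n_rep - 1


class TestBonferroni:
    def test_threshold_arithmetic(self):
        thr, calls = bonferroni([0.001] * 25, alpha=0.05)
        assert thr == pytest.approx(0.002)
        assert calls.all()

    def test_single_test_threshold_is_alpha(self):
        thr, _ = bonferroni([0.3], alpha=0.05)
        assert thr == 0.05

    def test_all_ones_nothing_significant(self):
        _, calls = bonferroni([1.0, 1.0, 1.0])
        assert not calls.any()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])
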