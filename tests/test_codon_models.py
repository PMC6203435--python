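"""Codon rate matrices, pruning likelihoods, model fits, and comparisons."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from rh1coev.codon_models import (
    CodonRateSpec,
    LikelihoodEngine,
    OptimizationError,
    SiteClassModelSpec,
    _mixture_from_spec,
    build_codon_Q,
    delta_aic,
    discretize_beta,
    empirical_codon_frequencies,
    fit_clade_model_C,
    fit_site_model,
    lrt,
    lrt_df,
    m8_warm_start_from_m8a,
    site_posterior_report,
)
from rh1coev.genetic_code import CODON_INDEX, N_CODONS
from rh1coev.io_core import CodonAlignment
from rh1coev.simulate import default_m0_spec, simulate_codon_alignment
from rh1coev.trees import CladeTree, TreeArrays, balanced_tree, two_clade_tree

UNIFORM_PI = np.full(N_CODONS, 1.0 / N_CODONS)


def _random_pi(seed=0):
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.full(N_CODONS, 5.0))
    return pi / pi.sum()


class TestBuildQ:
    @pytest.mark.parametrize("pi", [UNIFORM_PI, _random_pi(3)])
    @pytest.mark.parametrize("omega", [0.0, 0.3, 2.0])
    def test_rows_sum_to_zero_and_reversibility(self, pi, omega):
        Q = build_codon_Q(CodonRateSpec(2.5, pi, omega))
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        flux = pi[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-14)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        from rh1coev.genetic_code import NB_I, NB_IS_NONSYN, NB_J

        Q = build_codon_Q(CodonRateSpec(2.0, UNIFORM_PI, 0.0))
        assert np.all(Q[NB_I[NB_IS_NONSYN], NB_J[NB_IS_NONSYN]] == 0.0)

    def test_multi_nucleotide_changes_forbidden(self):
        Q = build_codon_Q(CodonRateSpec(2.0, UNIFORM_PI, 1.0))
        i = CODON_INDEX["AAA"]
        j = CODON_INDEX["ACC"]  # two changes
        assert Q[i, j] == 0.0

    def test_mean_rate_is_one(self):
        pi = _random_pi(7)
        Q = build_codon_Q(CodonRateSpec(3.0, pi, 0.4))
        assert -(pi @ np.diag(Q)) == pytest.approx(1.0, abs=1e-12)


def _aln_from_codons(rows: dict[str, list[str]]) -> CodonAlignment:
    codes = np.array(
        [[CODON_INDEX[c] if c != "---" else -1 for c in row]
         for row in rows.values()]
    )
    return CodonAlignment(
        taxa=list(rows), codes=codes,
        ref_map=np.arange(1, codes.shape[1] + 1),
    )


def _enumeration_lnL(aln, tree, mixture, pi):
    """Independent oracle: brute-force sum over all internal-node states.

    Transition matrices come from scipy's expm (a different algorithm from
    the engine's symmetrized eigendecomposition).
    """
    ta = TreeArrays.from_clade_tree(tree)
    order = {t: i for i, t in enumerate(aln.taxa)}
    leaf_rows = [order[t] for t in ta.leaf_names]
    internals = [n for n in range(ta.n_nodes) if ta.children[n]]
    total = np.zeros(aln.n_sites)
    for weight, Q in mixture:
        Ps = {
            n: expm(Q * ta.edge_length[n])
            for n in range(ta.n_nodes) if n != ta.root
        }
        site_lik = np.zeros(aln.n_sites)
        for s in range(aln.n_sites):
            obs = {
                n: aln.codes[leaf_rows[i], s]
                for i, n in enumerate(range(ta.n_leaves))
            }
            acc = 0.0
            for states in itertools.product(range(N_CODONS),
                                            repeat=len(internals)):
                assign = dict(zip(internals, states))
                assign.update({n: obs[n] for n in obs if obs[n] >= 0})
                term = pi[assign[ta.root]]
                ok = True
                for n in range(ta.n_nodes):
                    if n == ta.root:
                        continue
                    parent_state = assign[ta.parent[n]]
                    if n in assign:
                        term *= Ps[n][parent_state, assign[n]]
                    else:  # gap leaf: sum over its states = row sum = 1
                        term *= 1.0
                    if term == 0.0:
                        ok = False
                        break
                if ok:
                    acc += term
            site_lik[s] = acc
        total += weight * site_lik
    return float(np.log(total).sum())


class TestPruningLnL:
    def test_zero_branch_identical_taxa(self):
        tree = CladeTree.from_newick("(a:0.0,b:0.0);")
        aln = _aln_from_codons({"a": ["GAA"], "b": ["GAA"]})
        pi = UNIFORM_PI
        eng = LikelihoodEngine(aln, tree, pi=pi)
        lnL, _, _ = eng.mixture_lnL(2.0, [1.0], [[0.5]], 1.0)
        assert lnL == pytest.approx(np.log(pi[CODON_INDEX["GAA"]]), abs=1e-10)

    def test_two_taxon_matches_explicit_sum(self):
        tree = CladeTree.from_newick("(a:0.05,b:0.05);")
        aln = _aln_from_codons({"a": ["GAA"], "b": ["GAG"]})
        pi = _random_pi(11)
        eng = LikelihoodEngine(aln, tree, pi=pi)
        lnL, _, _ = eng.mixture_lnL(2.0, [1.0], [[0.5]], 1.0)
        Q = build_codon_Q(CodonRateSpec(2.0, pi, 0.5))
        P = expm(Q * 0.1)  # reversible: collapse both branches
        expected = np.log(pi[CODON_INDEX["GAA"]]
                          * P[CODON_INDEX["GAA"], CODON_INDEX["GAG"]])
        assert lnL == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("newick,rows", [
        ("((a:0.12,b:0.3):0.08,c:0.25);",
         {"a": ["GAA", "ATC"], "b": ["GAG", "ATC"], "c": ["CAA", "ATA"]}),
        ("((a:0.1,b:0.15):0.05,(c:0.2,d:0.1):0.08);",
         {"a": ["GAA"], "b": ["---"], "c": ["AAA"], "d": ["GAT"]}),
    ])
    def test_enumeration_oracle_with_mixture(self, newick, rows):
        tree = CladeTree.from_newick(newick)
        aln = _aln_from_codons(rows)
        pi = _random_pi(5)
        spec = SiteClassModelSpec(
            "M2a_rel", np.array([0.6, 0.1, 0.3]),
            class_omegas=np.array([0.05, 1.0, 0.8]),
        )
        w, om = _mixture_from_spec(spec, 1)
        eng = LikelihoodEngine(aln, tree, pi=pi)
        lnL, _, _ = eng.mixture_lnL(1.7, w, om, 1.0)
        # oracle rebuilds the scaled generators the same way
        from rh1coev.codon_models import _build_q_raw, mean_rate

        Qs = [_build_q_raw(1.7, pi, o) for o in om[:, 0]]
        rho = sum(wt * mean_rate(Q, pi) for wt, Q in zip(w, Qs))
        mixture = [(wt, Q / rho) for wt, Q in zip(w, Qs)]
        expected = _enumeration_lnL(aln, tree, mixture, pi)
        assert lnL == pytest.approx(expected, abs=1e-8)

    def test_taxon_mismatch_raises(self, quartet_tree):
        aln = _aln_from_codons({"a": ["GAA"], "b": ["GAA"], "x": ["GAA"],
                                "d": ["GAA"]})
        with pytest.raises(ValueError, match="mismatch"):
            LikelihoodEngine(aln, quartet_tree)


class TestFits:
    def test_m0_parameter_recovery(self):
        tree = balanced_tree(20, 1.0)
        aln, _ = simulate_codon_alignment(
            tree, default_m0_spec(0.2), 500, seed=42, pi=UNIFORM_PI
        )
        fit = fit_site_model(aln, tree, "M0", n_starts=1, seed=0,
                             pi=UNIFORM_PI)
        assert 0.15 <= fit.spec.class_omegas[0] <= 0.25

    def test_nesting_m8a_within_m8(self):
        tree = balanced_tree(6, 1.0)
        aln, _ = simulate_codon_alignment(
            tree, default_m0_spec(0.3), 60, seed=7, pi=UNIFORM_PI
        )
        f8a = fit_site_model(aln, tree, "M8a", n_starts=1, seed=0,
                             n_beta_cat=3, maxiter=60)
        warm = m8_warm_start_from_m8a(f8a)
        f8 = fit_site_model(aln, tree, "M8", n_starts=1, seed=0,
                            n_beta_cat=3, maxiter=60, extra_starts=[warm])
        assert f8.lnL >= f8a.lnL - 1e-6

    def test_cmc_with_equal_divergent_omegas_is_m2a_rel(self):
        tree = two_clade_tree(6, 1.0)
        tree.partitions = tree.partitions[:1]
        aln, _ = simulate_codon_alignment(
            tree, default_m0_spec(0.3), 40, seed=3, pi=UNIFORM_PI
        )
        eng = LikelihoodEngine(aln, tree, pi=UNIFORM_PI)
        m2a_rel = SiteClassModelSpec(
            "M2a_rel", np.array([0.5, 0.2, 0.3]),
            class_omegas=np.array([0.1, 1.0, 0.6]),
        )
        cmc = SiteClassModelSpec(
            "CmC", np.array([0.5, 0.2, 0.3]),
            class_omegas=np.array([0.1, 1.0, np.nan]),
            divergent_omegas={"background": 0.6, "cladeA": 0.6},
        )
        w1, om1 = _mixture_from_spec(m2a_rel, eng.n_categories)
        w2, om2 = _mixture_from_spec(cmc, eng.n_categories)
        l1, _, _ = eng.mixture_lnL(2.0, w1, om1, 1.0)
        l2, _, _ = eng.mixture_lnL(2.0, w2, om2, 1.0)
        assert l1 == pytest.approx(l2, abs=1e-4)

    def test_invariant_alignment_flagged_unidentifiable(self):
        tree = CladeTree.from_newick("((a:0.1,b:0.1):0.1,c:0.1);")
        aln = _aln_from_codons(
            {"a": ["GAA", "ATG"], "b": ["GAA", "ATG"], "c": ["GAA", "ATG"]}
        )
        fit = fit_site_model(aln, tree, "M0", n_starts=1, maxiter=30)
        assert not fit.identifiable

    def test_one_partition_cmc_has_one_more_param_than_m2a_rel(self):
        tree = two_clade_tree(6, 1.0)
        aln, _ = simulate_codon_alignment(
            tree, default_m0_spec(0.3), 30, seed=1, pi=UNIFORM_PI
        )
        one = CladeTree(tree.tree, tree.partitions[:1])
        null = fit_site_model(aln, tree, "M2a_rel", n_starts=1, maxiter=3)
        alt = fit_clade_model_C(aln, one, n_starts=1, maxiter=3)
        assert lrt_df(alt, null) == 1


class TestComparisons:
    def test_equal_lnL_gives_zero_statistic(self):
        stat, p = lrt(-100.0, -100.0, df=1)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_oracle(self):
        stat, p = lrt(-98.0795, -100.0, df=1)  # statistic 3.841
        assert stat == pytest.approx(3.841, abs=1e-9)
        assert p == pytest.approx(chi2.sf(3.841, 1), abs=1e-12)
        assert p == pytest.approx(0.050, abs=5e-4)

    def test_alt_below_null_is_an_error(self):
        with pytest.raises(OptimizationError):
            lrt(-105.0, -100.0, df=2)

    def test_mixture_boundary_null(self):
        stat, p = lrt(-99.0, -100.0, df=1, boundary="mixture")
        assert p == pytest.approx(0.5 * chi2.sf(2.0, 1), abs=1e-12)
        _, p0 = lrt(-100.0, -100.0, df=1, boundary="mixture")
        assert p0 == 1.0

    def test_delta_aic_identical_fits(self):
        fits = [(-100.0, 5), (-100.0, 5), (-100.0, 5)]
        np.testing.assert_allclose(delta_aic(fits), 0.0)

    def test_delta_aic_ordering_nonnegative(self):
        fits = [(-100.0, 5), (-98.0, 6), (-103.0, 4)]
        d = delta_aic(fits)
        assert d.min() == 0.0 and np.all(d >= 0)


class TestSitePosteriors:
    def test_m0_single_class_posterior_is_one(self):
        tree = balanced_tree(4, 0.5)
        aln, _ = simulate_codon_alignment(
            tree, default_m0_spec(0.3), 20, seed=9, pi=UNIFORM_PI
        )
        fit = fit_site_model(aln, tree, "M0", n_starts=1, maxiter=30)
        np.testing.assert_allclose(fit.site_posteriors, 1.0)
        rep = site_posterior_report(fit, aln.ref_map)
        assert list(rep["site"]) == list(aln.ref_map)

    def test_posteriors_sum_to_one(self):
        tree = balanced_tree(6, 1.0)
        aln, _ = simulate_codon_alignment(
            tree, default_m0_spec(0.3), 40, seed=10, pi=UNIFORM_PI
        )
        fit = fit_site_model(aln, tree, "M3", n_starts=1, maxiter=60)
        np.testing.assert_allclose(
            fit.site_posteriors.sum(axis=1), 1.0, atol=1e-8
        )

    def test_positively_selected_sites_detected_by_m8(self):
        tree = balanced_tree(16, 2.0)
        truth = SiteClassModelSpec(
            "M8", np.array([0.92, 0.08]), beta_shape=(0.2, 3.0),
            omega_p=2.0, n_beta_cat=4,
        )
        aln, classes = simulate_codon_alignment(
            tree, truth, 90, seed=21, pi=UNIFORM_PI
        )
        hot = np.nonzero(classes == 4)[0]  # the omega_p class
        assert hot.size >= 3
        fit = fit_site_model(aln, tree, "M8", n_starts=2, seed=0,
                             n_beta_cat=4, maxiter=300, pi=UNIFORM_PI)
        assert fit.site_posteriors[hot, -1].mean() > 0.9
        cold = np.setdiff1d(np.arange(aln.n_sites), hot)
        assert fit.site_posteriors[cold, -1].mean() < 0.1

    def test_beta_discretization_is_equal_probability_medians(self):
        from scipy.stats import beta as beta_dist

        cats = discretize_beta(0.3, 1.5, 10)
        expected = beta_dist.ppf((np.arange(10) + 0.5) / 10, 0.3, 1.5)
        np.testing.assert_allclose(cats, expected)


def test_f3x4_frequencies_sum_to_one():
    tree = balanced_tree(4, 0.5)
    aln, _ = simulate_codon_alignment(tree, default_m0_spec(0.3), 50, seed=2)
    for method in ("F3x4", "F61", "uniform"):
        pi = empirical_codon_frequencies(aln, method=method)
        assert pi.shape == (N_CODONS,)
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(pi > 0)


class TestNestingIdentities:
    """Constrained evaluations reproduce the smaller model's likelihood."""

    @pytest.fixture(scope="class")
    def engine(self):
        tree = balanced_tree(6, 1.0)
        aln, _ = simulate_codon_alignment(
            tree, default_m0_spec(0.3), 40, seed=17, pi=UNIFORM_PI
        )
        return LikelihoodEngine(aln, tree, pi=UNIFORM_PI)

    def test_m3_with_equal_omegas_is_m0(self, engine):
        m0 = SiteClassModelSpec("M0", np.array([1.0]),
                                class_omegas=np.array([0.3]))
        m3 = SiteClassModelSpec("M3", np.array([0.5, 0.3, 0.2]),
                                class_omegas=np.array([0.3, 0.3, 0.3]))
        w0, o0 = _mixture_from_spec(m0, 1)
        w3, o3 = _mixture_from_spec(m3, 1)
        l0, _, _ = engine.mixture_lnL(2.0, w0, o0, 1.0)
        l3, _, _ = engine.mixture_lnL(2.0, w3, o3, 1.0)
        assert l3 == pytest.approx(l0, abs=1e-9)

    def test_m8_with_vanishing_extra_class_is_m7(self, engine):
        m7 = SiteClassModelSpec("M7", np.full(4, 0.25), beta_shape=(0.4, 1.2),
                                n_beta_cat=4)
        m8 = SiteClassModelSpec("M8", np.array([1.0 - 1e-12, 1e-12]),
                                beta_shape=(0.4, 1.2), omega_p=1.0,
                                n_beta_cat=4)
        w7, o7 = _mixture_from_spec(m7, 1)
        w8, o8 = _mixture_from_spec(m8, 1)
        l7, _, _ = engine.mixture_lnL(2.0, w7, o7, 1.0)
        l8, _, _ = engine.mixture_lnL(2.0, w8, o8, 1.0)
        assert l8 == pytest.approx(l7, abs=1e-6)
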