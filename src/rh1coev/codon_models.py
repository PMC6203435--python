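"""Codon site-class and clade models of dN/dS: likelihoods, fits, tests.

The substitution process is a GY94-style Muse–Gaut/Goldman–Yang codon model:
instantaneous rates between sense codons differing at one nucleotide are
proportional to the target codon frequency, multiplied by the
transition/transversion ratio κ for transitions and by ω = dN/dS for
nonsynonymous changes.  Site-to-site variation in ω is a finite mixture
(M-series models: M0, M1a, M2a, M3, M7, M8, M8a, M2a_rel) and Clade Model C
adds a "divergent" site class whose ω differs between named branch
partitions and the background.

Likelihoods are computed by Felsenstein pruning with per-pattern scaling,
vectorized across site patterns and mixture classes.  Fits use bounded
quasi-Newton optimization of log/logit-transformed parameters with multiple
random restarts; site classification is naive empirical Bayes at the MLEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .genetic_code import (
    CODON_NT,
    N_CODONS,
    NB_I,
    NB_IS_NONSYN,
    NB_IS_TS,
    NB_J,
    uniform_codon_frequencies,
)
from .io_core import GAP, CodonAlignment
from .trees import CladeTree, TreeArrays

class OptimizationError(RuntimeError):
    pass


# ---------------------------------------------------------------- Q matrix
@dataclass
class CodonRateSpec:
    """κ, stationary codon frequencies π (61 sense codons), and ω."""

    kappa: float
    pi: np.ndarray
    omega: float

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.pi.shape != (N_CODONS,) or np.any(self.pi < 0):
            raise ValueError("pi must be 61 nonnegative frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must sum to 1")


def build_codon_Q(spec: CodonRateSpec, scale: bool = True) -> np.ndarray:
    """61x61 instantaneous rate matrix; mean rate 1 at stationarity if scaled."""
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = spec.pi[NB_J].copy()
    rates[NB_IS_TS] *= spec.kappa
    rates[NB_IS_NONSYN] *= spec.omega
    Q[NB_I, NB_J] = rates
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    if scale:
        rho = -float(spec.pi @ np.diag(Q))
        if rho > 0:
            Q /= rho
    return Q


def mean_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    return -float(pi @ np.diag(Q))


def _build_q_raw(kappa: float, pi: np.ndarray, omega: float) -> np.ndarray:
    """Unvalidated, unscaled GY94 rate matrix (hot path)."""
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[NB_J].copy()
    rates[NB_IS_TS] *= kappa
    rates[NB_IS_NONSYN] *= omega
    Q[NB_I, NB_J] = rates
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    return Q


def _eig_reversible(Q: np.ndarray, pi: np.ndarray):
    """Spectral factors (A, lam, B) with P(t) = A @ diag(exp(lam t)) @ B.

    Uses the symmetrization D^1/2 Q D^-1/2 of the reversible generator;
    falls back to scipy's expm-based path on numerical failure.
    """
    d = np.sqrt(np.clip(pi, 1e-300, None))
    S = (Q * d[:, None]) / d[None, :]
    S = 0.5 * (S + S.T)
    lam, V = np.linalg.eigh(S)
    A = V / d[:, None]
    B = V.T * d[None, :]
    return A, lam, B


def transition_matrices_for_lengths(
    Q: np.ndarray, pi: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """P(t) for every t in ``lengths``; shape (n, 61, 61)."""
    lengths = np.asarray(lengths, dtype=float)
    try:
        A, lam, B = _eig_reversible(Q, pi)
        E = np.exp(np.outer(lengths, lam))  # (n, 61)
        P = np.matmul(A[None, :, :] * E[:, None, :], B)
    except linalg.LinAlgError:  # pragma: no cover - defensive fallback
        P = np.stack([linalg.expm(Q * t) for t in lengths])
    np.clip(P, 0.0, None, out=P)
    return P


# ------------------------------------------------------------- model specs
SITE_MODELS = ("M0", "M1a", "M2a", "M3", "M7", "M8", "M8a", "M2a_rel")


@dataclass
class SiteClassModelSpec:
    model_id: str
    proportions: np.ndarray
    class_omegas: np.ndarray | None = None  # (C,) or (C, n_categories)
    beta_shape: tuple[float, float] | None = None
    omega_p: float | None = None
    n_beta_cat: int = 10
    divergent_omegas: dict | None = None  # CmC: {"background": ..., name: ...}

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("proportions must be in [0,1] and sum to 1")
        self.proportions = np.clip(p, 0.0, 1.0)


def discretize_beta(p: float, q: float, k: int) -> np.ndarray:
    """k equal-probability categories of Beta(p, q); median per bin."""
    quantiles = (np.arange(k) + 0.5) / k
    return beta_dist.ppf(quantiles, p, q)


def _mixture_from_spec(spec: SiteClassModelSpec, n_categories: int):
    """(weights (C,), omega matrix (C, n_categories)) for the lnL engine."""
    mid = spec.model_id
    if mid == "CmC":
        w = spec.proportions
        om = np.empty((3, n_categories))
        om[0, :] = spec.class_omegas[0]
        om[1, :] = 1.0
        keys = ["background"] + [
            k for k in spec.divergent_omegas if k != "background"
        ]
        om[2, :] = [spec.divergent_omegas[k] for k in keys]
        return w, om
    if mid in ("M7", "M8", "M8a"):
        p, q = spec.beta_shape
        cats = discretize_beta(p, q, spec.n_beta_cat)
        if mid == "M7":
            w = np.full(spec.n_beta_cat, 1.0 / spec.n_beta_cat)
            om = cats
        else:
            p0 = spec.proportions[0]
            w = np.concatenate(
                [np.full(spec.n_beta_cat, p0 / spec.n_beta_cat), [1.0 - p0]]
            )
            om = np.concatenate([cats, [spec.omega_p]])
    else:
        w = spec.proportions
        om = np.asarray(spec.class_omegas, dtype=float)
    return w, np.broadcast_to(om[:, None], (len(w), n_categories)).copy()


# --------------------------------------------------------------- fit record
@dataclass
class SiteClassFit:
    model_id: str
    lnL: float
    spec: SiteClassModelSpec
    kappa: float
    scale: float
    pi: np.ndarray
    n_free_params: int
    class_weights: np.ndarray
    class_omegas: np.ndarray  # (C, n_categories)
    site_posteriors: np.ndarray  # (n_sites, C)
    site_mean_omega: np.ndarray
    converged: bool = True
    identifiable: bool = True
    n_starts: int = 1
    partition_names: tuple[str, ...] = ()
    eb_method: str = "NEB"

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free_params - 2.0 * self.lnL


# --------------------------------------------------------- likelihood engine
def mixture_transition_matrices(
    ta: TreeArrays, pi: np.ndarray, kappa: float, weights, omega_matrix,
    scale: float = 1.0,
) -> np.ndarray:
    """(C, n_nodes, 61, 61) branch transition matrices for a class mixture.

    ``omega_matrix`` is (C, K) over branch categories; within each category
    the mixture-mean substitution rate is normalized to 1, so branch
    lengths read as expected substitutions per codon everywhere.
    """
    weights = np.asarray(weights, float)
    om = np.asarray(omega_matrix, float)
    C, K = om.shape
    P = np.empty((C, ta.n_nodes, N_CODONS, N_CODONS))
    for k in range(K):
        nodes = np.nonzero(ta.edge_category == k)[0]
        nodes = nodes[nodes != ta.root]
        if nodes.size == 0 and k > 0:
            continue
        Qs = [_build_q_raw(kappa, pi, om[c, k]) for c in range(C)]
        rho = sum(w * mean_rate(Q, pi) for w, Q in zip(weights, Qs))
        rho = max(rho, 1e-12)
        lengths = ta.edge_length[nodes] * (scale / rho)
        for c in range(C):
            P[c, nodes] = transition_matrices_for_lengths(
                Qs[c], pi, lengths
            )
    P[:, ta.root] = np.eye(N_CODONS)
    return P


class LikelihoodEngine:
    """Pattern-compressed pruning likelihood over a codon alignment."""

    def __init__(self, aln: CodonAlignment, tree: CladeTree, pi=None):
        ta = TreeArrays.from_clade_tree(tree)
        order = {t: i for i, t in enumerate(aln.taxa)}
        missing = [t for t in ta.leaf_names if t not in order]
        if missing or ta.n_leaves != aln.n_taxa:
            raise ValueError(
                f"taxon mismatch between alignment and tree: {missing}"
            )
        rows = [order[t] for t in ta.leaf_names]
        codes = aln.codes[rows]  # leaf order
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True
        )
        self.tree_arrays = ta
        self.pattern_index = inverse
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        self.n_sites = aln.n_sites
        self.n_categories = (
            max(int(ta.edge_category.max()), 0) + 1 if ta.n_nodes else 1
        )
        self.pi = (
            np.asarray(pi, dtype=float)
            if pi is not None
            else empirical_codon_frequencies(aln)
        )
        # leaf partial likelihoods: one-hot, gaps = all ones
        leaf = np.zeros((ta.n_leaves, self.n_patterns, N_CODONS))
        for i in range(ta.n_leaves):
            col = patterns[i]
            gap = col == GAP
            leaf[i, gap, :] = 1.0
            ok = ~gap
            leaf[i, ok, col[ok]] = 1.0
        self.leaf_partials = leaf
        self.variable = np.array(
            [len(set(patterns[:, j][patterns[:, j] >= 0])) > 1
             for j in range(self.n_patterns)]
        )

    # -- transition matrices -------------------------------------------
    def class_transition_matrices(
        self, kappa: float, weights, omega_matrix, scale: float
    ) -> np.ndarray:
        return mixture_transition_matrices(
            self.tree_arrays, self.pi, kappa, weights, omega_matrix, scale
        )

    # -- pruning --------------------------------------------------------
    def class_pattern_logliks(self, P: np.ndarray) -> np.ndarray:
        """Per-class per-pattern log-likelihoods; shape (C, n_patterns)."""
        ta = self.tree_arrays
        C = P.shape[0]
        n_pat = self.n_patterns
        partial: list = [None] * ta.n_nodes
        logscale = np.zeros((C, n_pat))
        for node in ta.postorder:
            kids = ta.children[node]
            if not kids:
                continue
            acc = np.ones((C, n_pat, N_CODONS))
            for ch in kids:
                Lc = (
                    self.leaf_partials[ch]
                    if ch < ta.n_leaves
                    else partial[ch]
                )
                acc *= np.matmul(Lc, P[:, ch].transpose(0, 2, 1))
                if ch >= ta.n_leaves:
                    partial[ch] = None
            m = np.clip(acc.max(axis=2), 1e-300, None)
            acc /= m[:, :, None]
            logscale += np.log(m)
            partial[node] = acc
        root = partial[ta.root]
        lik = root @ self.pi
        return np.log(np.clip(lik, 1e-300, None)) + logscale

    def mixture_lnL(
        self, kappa, weights, omega_matrix, scale
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """(lnL, per-pattern class posteriors (n_pat, C), pattern logliks)."""
        P = self.class_transition_matrices(kappa, weights, omega_matrix, scale)
        cls_ll = self.class_pattern_logliks(P)  # (C, n_pat)
        with np.errstate(divide="ignore"):
            logw = np.log(np.asarray(weights, float))
        z = cls_ll + logw[:, None]
        m = z.max(axis=0)
        lse = m + np.log(np.exp(z - m).sum(axis=0))
        lnL = float(self.counts @ lse)
        post = np.exp(z - lse[None, :]).T
        return lnL, post, lse

    def expand_to_sites(self, per_pattern: np.ndarray) -> np.ndarray:
        return per_pattern[..., self.pattern_index, :] if per_pattern.ndim > 1 else per_pattern[self.pattern_index]


def empirical_codon_frequencies(
    aln: CodonAlignment, method: str = "F3x4", pseudocount: float = 1.0
) -> np.ndarray:
    """π from observed codons: F3x4 (default), F61, or uniform."""
    obs = aln.codes[aln.codes >= 0]
    if method == "uniform" or obs.size == 0:
        return uniform_codon_frequencies()
    if method == "F61":
        counts = np.bincount(obs, minlength=N_CODONS) + pseudocount
        return counts / counts.sum()
    if method == "F3x4":
        nt = np.full((3, 4), pseudocount, dtype=float)
        for pos in range(3):
            nts = CODON_NT[obs, pos]
            nt[pos] += np.bincount(nts, minlength=4)
        nt /= nt.sum(axis=1, keepdims=True)
        from .genetic_code import codon_frequencies_f3x4

        pi = codon_frequencies_f3x4(nt)
        pi = np.clip(pi, 1e-8, None)
        return pi / pi.sum()
    raise ValueError(f"unknown frequency method {method!r}")


# ------------------------------------------------------- parameterizations
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softmax_weights(z: np.ndarray) -> np.ndarray:
    """K-1 free logits -> K-simplex (last logit pinned at 0)."""
    full = np.concatenate([z, [0.0]])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


_LOGIT_B = (-12.0, 12.0)
_LOGW_B = (np.log(1e-4), np.log(50.0))
_LOGBETA_B = (np.log(0.005), np.log(50.0))
_LOGWP_B = (-15.0, np.log(49.0))  # omega_p = 1 + exp(x)
_LOGK_B = (np.log(0.1), np.log(20.0))
_LOGS_B = (np.log(1e-3), np.log(1e3))


class _ModelDef:
    """Transformed-parameter layout for one model family."""

    def __init__(self, model_id: str, n_partitions: int = 0, n_beta_cat: int = 10):
        self.model_id = model_id
        self.n_partitions = n_partitions
        self.n_beta_cat = n_beta_cat
        table = {
            "M0": ([("omega", _LOGW_B)], [np.log(0.3)]),
            "M1a": (
                [("p0", _LOGIT_B), ("omega0", _LOGIT_B)],
                [1.0, -2.0],
            ),
            "M2a": (
                [("z0", _LOGIT_B), ("z1", _LOGIT_B), ("omega0", _LOGIT_B),
                 ("omega_p", _LOGWP_B)],
                [1.5, 0.5, -2.0, 0.0],
            ),
            "M2a_rel": (
                [("z0", _LOGIT_B), ("z1", _LOGIT_B), ("omega0", _LOGIT_B),
                 ("omega2", _LOGW_B)],
                [1.0, -0.5, -3.0, np.log(0.3)],
            ),
            "M3": (
                [("z0", _LOGIT_B), ("z1", _LOGIT_B), ("omega0", _LOGW_B),
                 ("omega1", _LOGW_B), ("omega2", _LOGW_B)],
                [0.5, 0.5, np.log(0.02), np.log(0.2), np.log(1.0)],
            ),
            "M7": ([("p", _LOGBETA_B), ("q", _LOGBETA_B)], [np.log(0.3), np.log(1.5)]),
            "M8": (
                [("p0", _LOGIT_B), ("p", _LOGBETA_B), ("q", _LOGBETA_B),
                 ("omega_p", _LOGWP_B)],
                [2.0, np.log(0.3), np.log(1.5), 0.0],
            ),
            "M8a": (
                [("p0", _LOGIT_B), ("p", _LOGBETA_B), ("q", _LOGBETA_B)],
                [2.0, np.log(0.3), np.log(1.5)],
            ),
        }
        if model_id == "CmC":
            if n_partitions < 1:
                raise ValueError("CmC needs >= 1 named partition")
            names = [("z0", _LOGIT_B), ("z1", _LOGIT_B), ("omega0", _LOGIT_B),
                     ("omega_d_bg", _LOGW_B)]
            x0 = [1.0, -0.5, -3.0, np.log(0.3)]
            for i in range(n_partitions):
                names.append((f"omega_d_{i}", _LOGW_B))
                x0.append(np.log(0.3))
            self.entries, self.x0 = names, x0
        else:
            if model_id not in table:
                raise ValueError(f"unknown model {model_id!r}")
            self.entries, self.x0 = table[model_id]

    @property
    def n_free(self) -> int:
        return len(self.entries)

    def bounds(self):
        return [b for (_, b) in self.entries]

    def spec_from_x(self, x: np.ndarray) -> SiteClassModelSpec:
        mid = self.model_id
        v = dict(zip((n for n, _ in self.entries), x))
        if mid == "M0":
            return SiteClassModelSpec(
                mid, np.array([1.0]), class_omegas=np.array([np.exp(v["omega"])])
            )
        if mid == "M1a":
            p0 = _sigmoid(v["p0"])
            return SiteClassModelSpec(
                mid,
                np.array([p0, 1 - p0]),
                class_omegas=np.array([_sigmoid(v["omega0"]), 1.0]),
            )
        if mid in ("M2a", "M2a_rel"):
            w = _softmax_weights(np.array([v["z0"], v["z1"]]))
            om2 = (
                1.0 + np.exp(v["omega_p"])
                if mid == "M2a"
                else np.exp(v["omega2"])
            )
            return SiteClassModelSpec(
                mid, w, class_omegas=np.array([_sigmoid(v["omega0"]), 1.0, om2])
            )
        if mid == "M3":
            w = _softmax_weights(np.array([v["z0"], v["z1"]]))
            return SiteClassModelSpec(
                mid,
                w,
                class_omegas=np.exp(
                    np.array([v["omega0"], v["omega1"], v["omega2"]])
                ),
            )
        if mid == "M7":
            return SiteClassModelSpec(
                mid,
                np.full(self.n_beta_cat, 1.0 / self.n_beta_cat),
                beta_shape=(np.exp(v["p"]), np.exp(v["q"])),
                n_beta_cat=self.n_beta_cat,
            )
        if mid in ("M8", "M8a"):
            p0 = _sigmoid(v["p0"])
            omega_p = 1.0 + np.exp(v["omega_p"]) if mid == "M8" else 1.0
            return SiteClassModelSpec(
                mid,
                np.array([p0, 1 - p0]),
                beta_shape=(np.exp(v["p"]), np.exp(v["q"])),
                omega_p=omega_p,
                n_beta_cat=self.n_beta_cat,
            )
        if mid == "CmC":
            w = _softmax_weights(np.array([v["z0"], v["z1"]]))
            div = {"background": np.exp(v["omega_d_bg"])}
            for i in range(self.n_partitions):
                div[f"partition_{i}"] = np.exp(v[f"omega_d_{i}"])
            return SiteClassModelSpec(
                mid,
                w,
                class_omegas=np.array([_sigmoid(v["omega0"]), 1.0, np.nan]),
                divergent_omegas=div,
            )
        raise AssertionError(mid)


# ----------------------------------------------------------------- fitting
def _fit_mixture_model(
    engine: LikelihoodEngine,
    mdef: _ModelDef,
    *,
    n_starts: int = 3,
    seed: int = 0,
    fit_kappa: bool = True,
    fit_scale: bool = True,
    kappa0: float = 2.0,
    scale0: float = 1.0,
    maxiter: int = 300,
    extra_starts: list | None = None,
    partition_names: tuple[str, ...] = (),
) -> SiteClassFit:
    rng = np.random.default_rng(seed)
    n_cat = engine.n_categories
    bounds = mdef.bounds() + ([_LOGK_B] if fit_kappa else []) + (
        [_LOGS_B] if fit_scale else []
    )
    base_x0 = np.array(
        mdef.x0
        + ([np.log(kappa0)] if fit_kappa else [])
        + ([np.log(scale0)] if fit_scale else [])
    )

    def unpack(x):
        k = mdef.n_free
        spec = mdef.spec_from_x(x[:k])
        kappa = np.exp(x[k]) if fit_kappa else kappa0
        scale = np.exp(x[-1]) if fit_scale else scale0
        return spec, kappa, scale

    def nll(x):
        spec, kappa, scale = unpack(x)
        w, om = _mixture_from_spec(spec, n_cat)
        lnL, _, _ = engine.mixture_lnL(kappa, w, om, scale)
        if not np.isfinite(lnL):
            return 1e12
        return -lnL

    starts = [base_x0] if n_starts >= 1 else []
    for _ in range(max(n_starts - 1, 0)):
        starts.append(base_x0 + rng.normal(scale=0.7, size=base_x0.size))
    for xs in extra_starts or []:
        starts.append(np.asarray(xs, dtype=float))
    if not starts:
        starts = [base_x0]
    starts = [np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds])
              for s in starts]

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or res.success
    if best is None or not np.isfinite(best.fun):
        raise OptimizationError(f"{mdef.model_id}: optimization failed")

    spec, kappa, scale = unpack(best.x)
    w, om = _mixture_from_spec(spec, n_cat)
    lnL, post_pat, _ = engine.mixture_lnL(kappa, w, om, scale)
    post = post_pat[engine.pattern_index]  # (n_sites, C)
    mean_omega = post @ om[:, 0]  # background-category omegas
    n_free = mdef.n_free + int(fit_kappa) + int(fit_scale)
    identifiable = bool(engine.variable.any())
    return SiteClassFit(
        model_id=mdef.model_id,
        lnL=lnL,
        spec=spec,
        kappa=kappa,
        scale=scale,
        pi=engine.pi,
        n_free_params=n_free,
        class_weights=w,
        class_omegas=om,
        site_posteriors=post,
        site_mean_omega=mean_omega,
        converged=converged,
        identifiable=identifiable,
        n_starts=len(starts),
        partition_names=partition_names,
    )


def fit_site_model(
    aln: CodonAlignment,
    tree: CladeTree,
    model_id: str,
    *,
    n_starts: int = 3,
    seed: int = 0,
    pi=None,
    n_beta_cat: int = 10,
    fit_kappa: bool = True,
    fit_scale: bool = True,
    kappa0: float = 2.0,
    scale0: float = 1.0,
    maxiter: int = 300,
    extra_starts: list | None = None,
    engine: LikelihoodEngine | None = None,
) -> SiteClassFit:
    """ML fit of a random-sites model (M0...M8a, M2a_rel) with restarts."""
    if model_id not in SITE_MODELS:
        raise ValueError(f"model_id must be one of {SITE_MODELS}")
    engine = engine or LikelihoodEngine(aln, tree, pi=pi)
    mdef = _ModelDef(model_id, n_beta_cat=n_beta_cat)
    return _fit_mixture_model(
        engine, mdef, n_starts=n_starts, seed=seed, fit_kappa=fit_kappa,
        fit_scale=fit_scale, kappa0=kappa0, scale0=scale0, maxiter=maxiter,
        extra_starts=extra_starts,
    )


def fit_clade_model_C(
    aln: CodonAlignment,
    tree: CladeTree,
    partitions=None,
    *,
    n_starts: int = 3,
    seed: int = 0,
    pi=None,
    fit_kappa: bool = True,
    fit_scale: bool = True,
    kappa0: float = 2.0,
    scale0: float = 1.0,
    maxiter: int = 300,
    extra_starts: list | None = None,
    engine: LikelihoodEngine | None = None,
) -> SiteClassFit:
    """Clade Model C: shared ω0 and ω1=1 classes, divergent ωd per partition."""
    work = tree if partitions is None else CladeTree(tree.tree, list(partitions))
    if not work.partitions:
        raise ValueError("CmC requires at least one named partition")
    engine = engine or LikelihoodEngine(aln, work, pi=pi)
    names = tuple(p.name for p in work.partitions)
    mdef = _ModelDef("CmC", n_partitions=len(names))
    fit = _fit_mixture_model(
        engine, mdef, n_starts=n_starts, seed=seed, fit_kappa=fit_kappa,
        fit_scale=fit_scale, kappa0=kappa0, scale0=scale0, maxiter=maxiter,
        extra_starts=extra_starts, partition_names=names,
    )
    # rename divergent omegas with the real partition labels
    div = fit.spec.divergent_omegas
    fit.spec.divergent_omegas = {"background": div["background"]} | {
        name: div[f"partition_{i}"] for i, name in enumerate(names)
    }
    return fit


def m8_warm_start_from_m8a(
    fit_m8a: SiteClassFit, fit_kappa: bool = True, fit_scale: bool = True
) -> np.ndarray:
    """Transformed M8 start at the M8a optimum (ωp just above 1)."""
    p0 = float(np.clip(fit_m8a.spec.proportions[0], 1e-6, 1 - 1e-6))
    p, q = fit_m8a.spec.beta_shape
    x = [
        np.log(p0 / (1 - p0)),
        np.log(p),
        np.log(q),
        -12.0,  # omega_p = 1 + e^-12
    ]
    if fit_kappa:
        x.append(np.log(fit_m8a.kappa))
    if fit_scale:
        x.append(np.log(fit_m8a.scale))
    return np.array(x)


# -------------------------------------------------------------- comparisons
def lrt(
    fit_alt: SiteClassFit | float,
    fit_null: SiteClassFit | float,
    df: int,
    boundary: str | None = None,
    tol: float = 1e-2,
) -> tuple[float, float]:
    """Likelihood-ratio test of nested fits.

    ``boundary="mixture"`` uses the 50:50 chi0/chi1 boundary null
    conventional for tests like M8 vs M8a where the constrained value sits
    on the parameter boundary.
    """
    la = fit_alt.lnL if hasattr(fit_alt, "lnL") else float(fit_alt)
    l0 = fit_null.lnL if hasattr(fit_null, "lnL") else float(fit_null)
    if df < 1:
        raise ValueError("df must be >= 1")
    if la < l0 - tol:
        raise OptimizationError(
            f"alternative lnL {la:.6f} below null {l0:.6f}: optimization failure"
        )
    stat = max(2.0 * (la - l0), 0.0)
    if boundary == "mixture":
        if df != 1:
            raise ValueError("mixture boundary null implemented for df=1")
        p = 1.0 if stat == 0.0 else 0.5 * chi2.sf(stat, 1)
    else:
        p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, float(p)


def lrt_df(fit_alt: SiteClassFit, fit_null: SiteClassFit) -> int:
    return int(fit_alt.n_free_params - fit_null.n_free_params)


def delta_aic(fits: list) -> np.ndarray:
    """ΔAIC of each fit relative to the minimum-AIC fit (AIC = 2k − 2lnL)."""
    if len(fits) < 2:
        raise ValueError("need at least two fits")
    aics = np.array(
        [
            f.aic if hasattr(f, "aic") else 2.0 * f[1] - 2.0 * f[0]
            for f in fits
        ]
    )
    return aics - aics.min()


def site_posterior_report(fit: SiteClassFit, ref_map=None) -> pd.DataFrame:
    """Per-site empirical-Bayes class posteriors and posterior-mean ω."""
    n_sites, C = fit.site_posteriors.shape
    sites = ref_map if ref_map is not None else np.arange(1, n_sites + 1)
    data = {"site": np.asarray(sites)}
    for c in range(C):
        data[f"p_class{c}"] = fit.site_posteriors[:, c]
    data["mean_omega"] = fit.site_mean_omega
    if fit.model_id == "CmC":
        data["p_divergent"] = fit.site_posteriors[:, -1]
    if fit.model_id == "M8":
        data["p_positive"] = fit.site_posteriors[:, -1]
    df = pd.DataFrame(data)
    df.attrs["eb_method"] = fit.eb_method
    return df
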