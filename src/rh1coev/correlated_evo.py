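"""Pagel-type tests for correlated evolution of two binary traits on a tree.

Two traits evolve jointly on the 4-state space {00, 01, 10, 11} under a
continuous-time Markov chain in which only single-trait transitions have
nonzero rate.  The independent model ties each trait's gain/loss rates
across the other trait's state (4 free rates); the dependent model frees
all 8.  Likelihoods are computed by pruning (numba-compiled kernel — the
Monte-Carlo test refits both models on every simulated replicate, so the
inner loop must be cheap).  Monte-Carlo p-values follow the parametric
bootstrap: simulate under the independent model at its MLEs, refit both
models per replicate, and use the add-one rank estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import optimize
from scipy.stats import chi2

from .io_core import BinaryTraitVector
from .trees import CladeTree, TreeArrays

RATE_BOUNDS = (1e-6, 100.0)  # on a tree scaled to unit height

#: dependent-model rate order
RATE_NAMES_8 = (
    "x_gain_y0", "x_gain_y1", "x_loss_y0", "x_loss_y1",
    "y_gain_x0", "y_gain_x1", "y_loss_x0", "y_loss_x1",
)
RATE_NAMES_4 = ("x_gain", "x_loss", "y_gain", "y_loss")


class UntestableTraitError(ValueError):
    """Raised when a trait is monomorphic on the tree (test undefined)."""


@dataclass
class PagelFit:
    lnL_indep: float
    lnL_dep: float
    rates_indep: dict
    rates_dep: dict
    lrt_stat: float
    p_asymptotic: float
    p_mc: float | None
    n_sim: int


def _q_from_rates8(r: np.ndarray) -> np.ndarray:
    Q = np.zeros((4, 4))
    Q[0, 2] = r[0]  # x gain | y=0
    Q[1, 3] = r[1]  # x gain | y=1
    Q[2, 0] = r[2]  # x loss | y=0
    Q[3, 1] = r[3]  # x loss | y=1
    Q[0, 1] = r[4]  # y gain | x=0
    Q[2, 3] = r[5]  # y gain | x=1
    Q[1, 0] = r[6]  # y loss | x=0
    Q[3, 2] = r[7]  # y loss | x=1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def expand_independent_rates(r4: np.ndarray) -> np.ndarray:
    xg, xl, yg, yl = r4
    return np.array([xg, xg, xl, xl, yg, yg, yl, yl])


@njit(cache=True)
def _pagel_lnL_kernel(r8, parent, postorder, edge_length, sx, sy,
                      n_leaves, root, root_equal):
    Q = np.zeros((4, 4))
    Q[0, 2] = r8[0]
    Q[1, 3] = r8[1]
    Q[2, 0] = r8[2]
    Q[3, 1] = r8[3]
    Q[0, 1] = r8[4]
    Q[2, 3] = r8[5]
    Q[1, 0] = r8[6]
    Q[3, 2] = r8[7]
    for i in range(4):
        s = 0.0
        for j in range(4):
            if j != i:
                s += Q[i, j]
        Q[i, i] = -s

    lam, V = np.linalg.eig(Q.astype(np.complex128))
    Vinv = np.linalg.inv(V)

    n_nodes = parent.shape[0]
    partial = np.ones((n_nodes, 4))
    for i in range(n_leaves):
        for s in range(4):
            partial[i, s] = 1.0
        x = sx[i]
        y = sy[i]
        for s in range(4):
            okx = (x < 0) or ((s >> 1) == x)
            oky = (y < 0) or ((s & 1) == y)
            if not (okx and oky):
                partial[i, s] = 0.0

    logscale = 0.0
    for k in range(postorder.shape[0]):
        node = postorder[k]
        if node == root:
            continue
        t = edge_length[node]
        # P = real(V diag(exp(lam t)) Vinv)
        el = np.empty(4, dtype=np.complex128)
        for m in range(4):
            el[m] = np.exp(lam[m] * t)
        P = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                acc = 0.0 + 0.0j
                for m in range(4):
                    acc += V[i, m] * el[m] * Vinv[m, j]
                val = acc.real
                if val < 0.0:
                    val = 0.0
                P[i, j] = val
        msg = np.zeros(4)
        mx = 0.0
        for i in range(4):
            acc2 = 0.0
            for j in range(4):
                acc2 += P[i, j] * partial[node, j]
            msg[i] = acc2
            if acc2 > mx:
                mx = acc2
        if mx <= 0.0:
            return -1e300
        logscale += np.log(mx)
        p = parent[node]
        for i in range(4):
            partial[p, i] *= msg[i] / mx

    # root distribution
    pi = np.full(4, 0.25)
    if not root_equal:
        # stationary: solve Q^T pi = 0 with the last row replaced by sum=1
        A = np.empty((4, 4))
        for i in range(3):
            for j in range(4):
                A[i, j] = Q[j, i]
        for j in range(4):
            A[3, j] = 1.0
        b = np.zeros(4)
        b[3] = 1.0
        sol = np.linalg.solve(A, b)
        tot = 0.0
        for i in range(4):
            if sol[i] < 0.0:
                sol[i] = 0.0
            tot += sol[i]
        if tot > 0:
            pi = sol / tot

    lik = 0.0
    for i in range(4):
        lik += pi[i] * partial[root, i]
    if lik <= 0.0:
        return -1e300
    return np.log(lik) + logscale


@njit(cache=True)
def _nll_logrates(logr, n_rates, parent, postorder, edge_length, sx, sy,
                  n_leaves, root, root_equal, lo, hi):
    r8 = np.empty(8)
    if n_rates == 4:
        r8[0] = r8[1] = np.exp(min(max(logr[0], lo), hi))
        r8[2] = r8[3] = np.exp(min(max(logr[1], lo), hi))
        r8[4] = r8[5] = np.exp(min(max(logr[2], lo), hi))
        r8[6] = r8[7] = np.exp(min(max(logr[3], lo), hi))
    else:
        for i in range(8):
            r8[i] = np.exp(min(max(logr[i], lo), hi))
    v = _pagel_lnL_kernel(r8, parent, postorder, edge_length, sx, sy,
                          n_leaves, root, root_equal)
    return -v


@njit(cache=True)
def _nm_fit(x0, n_rates, parent, postorder, edge_length, sx, sy,
            n_leaves, root, root_equal, lo, hi, maxiter):
    """Nelder-Mead over log-rates (bounds enforced by clipping)."""
    n = x0.shape[0]
    simplex = np.empty((n + 1, n))
    fvals = np.empty(n + 1)
    for i in range(n):
        simplex[0, i] = x0[i]
    for k in range(n):
        for i in range(n):
            simplex[k + 1, i] = x0[i]
        simplex[k + 1, k] += 0.5
    for k in range(n + 1):
        fvals[k] = _nll_logrates(simplex[k], n_rates, parent, postorder,
                                 edge_length, sx, sy, n_leaves, root,
                                 root_equal, lo, hi)
    alpha, gamma, rho_c, sigma = 1.0, 2.0, 0.5, 0.5
    for _ in range(maxiter):
        order = np.argsort(fvals)
        simplex = simplex[order]
        fvals = fvals[order]
        if fvals[n] - fvals[0] < 1e-9:
            break
        centroid = np.zeros(n)
        for k in range(n):
            for i in range(n):
                centroid[i] += simplex[k, i]
        centroid /= n
        xr = centroid + alpha * (centroid - simplex[n])
        fr = _nll_logrates(xr, n_rates, parent, postorder, edge_length,
                           sx, sy, n_leaves, root, root_equal, lo, hi)
        if fr < fvals[0]:
            xe = centroid + gamma * (xr - centroid)
            fe = _nll_logrates(xe, n_rates, parent, postorder, edge_length,
                               sx, sy, n_leaves, root, root_equal, lo, hi)
            if fe < fr:
                simplex[n] = xe
                fvals[n] = fe
            else:
                simplex[n] = xr
                fvals[n] = fr
        elif fr < fvals[n - 1]:
            simplex[n] = xr
            fvals[n] = fr
        else:
            xc = centroid + rho_c * (simplex[n] - centroid)
            fc = _nll_logrates(xc, n_rates, parent, postorder, edge_length,
                               sx, sy, n_leaves, root, root_equal, lo, hi)
            if fc < fvals[n]:
                simplex[n] = xc
                fvals[n] = fc
            else:
                for k in range(1, n + 1):
                    for i in range(n):
                        simplex[k, i] = simplex[0, i] + sigma * (
                            simplex[k, i] - simplex[0, i]
                        )
                    fvals[k] = _nll_logrates(
                        simplex[k], n_rates, parent, postorder, edge_length,
                        sx, sy, n_leaves, root, root_equal, lo, hi,
                    )
    best = int(np.argmin(fvals))
    return fvals[best], simplex[best]


def _traits_to_arrays(ta: TreeArrays, trait_x, trait_y):
    def as_map(t):
        if isinstance(t, BinaryTraitVector):
            return t.as_dict()
        return dict(t)

    mx, my = as_map(trait_x), as_map(trait_y)
    unknown = (set(mx) | set(my)) - set(ta.leaf_names)
    if unknown:
        raise ValueError(f"trait taxa not on tree: {sorted(unknown)}")
    sx = np.array(
        [-1 if mx.get(t) is None else int(mx[t]) for t in ta.leaf_names],
        dtype=np.int64,
    )
    sy = np.array(
        [-1 if my.get(t) is None else int(my[t]) for t in ta.leaf_names],
        dtype=np.int64,
    )
    return sx, sy


def _unit_height_arrays(tree: CladeTree | TreeArrays) -> tuple[TreeArrays, float]:
    ta = (
        tree
        if isinstance(tree, TreeArrays)
        else TreeArrays.from_clade_tree(tree)
    )
    # height = max root-to-leaf path
    depth = np.zeros(ta.n_nodes)
    for node in ta.postorder[::-1]:
        p = ta.parent[node]
        if p >= 0:
            depth[node] = depth[p] + ta.edge_length[node]
    h = float(depth[: ta.n_leaves].max())
    if h <= 0:
        # degenerate all-zero tree: leave lengths as-is (P(0) = I anyway)
        return ta, 1.0
    return ta.scaled(1.0 / h), h


def pagel_lnL(
    tree,
    trait_x,
    trait_y,
    model: str = "dependent",
    rates=None,
    root: str = "stationary",
) -> float:
    """Log-likelihood of the 4-state joint chain at the given rates.

    Rates are per unit tree height (the tree is rescaled internally).
    """
    ta, _ = _unit_height_arrays(tree)
    sx, sy = _traits_to_arrays(ta, trait_x, trait_y)
    r = np.asarray(rates, dtype=float)
    if model == "independent":
        if r.shape != (4,):
            raise ValueError("independent model takes 4 rates")
        r8 = expand_independent_rates(r)
    elif model == "dependent":
        if r.shape != (8,):
            raise ValueError("dependent model takes 8 rates")
        r8 = r
    else:
        raise ValueError(f"unknown model {model!r}")
    if np.any(r8 <= 0):
        raise ValueError("rates must be positive")
    return float(
        _pagel_lnL_kernel(
            r8, ta.parent, ta.postorder, ta.edge_length, sx, sy,
            ta.n_leaves, ta.root, root == "equal",
        )
    )


def _fit_model(
    ta: TreeArrays, sx, sy, n_rates: int, *,
    n_starts: int, rng: np.random.Generator,
    maxiter: int, root_equal: bool, x0_extra=None,
    optimizer: str = "lbfgs",
):
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    starts = []
    if n_starts >= 1:
        starts.append(np.zeros(n_rates))  # all rates = 1 per unit height
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(np.log(0.05), np.log(10.0), size=n_rates))
    if x0_extra is not None:
        starts.append(np.asarray(x0_extra))
    if not starts:
        starts = [np.zeros(n_rates)]

    if optimizer == "nm":
        best_f, best_x = np.inf, None
        for x0 in starts:
            f, x = _nm_fit(
                np.clip(np.asarray(x0, float), lo, hi), n_rates,
                ta.parent, ta.postorder, ta.edge_length, sx, sy,
                ta.n_leaves, ta.root, root_equal, lo, hi, maxiter,
            )
            if f < best_f:
                best_f, best_x = f, x
        return -best_f, np.exp(np.clip(best_x, lo, hi))

    def nll(logr):
        r = np.exp(logr)
        r8 = expand_independent_rates(r) if n_rates == 4 else r
        val = _pagel_lnL_kernel(
            r8, ta.parent, ta.postorder, ta.edge_length, sx, sy,
            ta.n_leaves, ta.root, root_equal,
        )
        return -val if np.isfinite(val) else 1e12

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, np.clip(x0, lo, hi), method="L-BFGS-B",
            bounds=[(lo, hi)] * n_rates,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, np.exp(best.x)


def fit_pagel(
    tree, trait_x, trait_y, *,
    n_starts: int = 5, seed: int = 0, maxiter: int = 200,
    root: str = "stationary", optimizer: str = "lbfgs",
) -> PagelFit:
    """ML fits of the independent (4-rate) and dependent (8-rate) models."""
    ta, _ = _unit_height_arrays(tree)
    sx, sy = _traits_to_arrays(ta, trait_x, trait_y)
    return _fit_pagel_arrays(
        ta, sx, sy, n_starts=n_starts, seed=seed, maxiter=maxiter,
        root_equal=(root == "equal"), optimizer=optimizer,
    )


def _fit_pagel_arrays(ta, sx, sy, *, n_starts, seed, maxiter, root_equal,
                      optimizer="lbfgs"):
    rng = np.random.default_rng(seed)
    lnL_i, r4 = _fit_model(
        ta, sx, sy, 4, n_starts=n_starts, rng=rng, maxiter=maxiter,
        root_equal=root_equal, optimizer=optimizer,
    )
    lnL_d, r8 = _fit_model(
        ta, sx, sy, 8, n_starts=n_starts, rng=rng, maxiter=maxiter,
        root_equal=root_equal, optimizer=optimizer,
        x0_extra=np.log(expand_independent_rates(r4)),
    )
    stat = max(2.0 * (lnL_d - lnL_i), 0.0)
    return PagelFit(
        lnL_indep=lnL_i,
        lnL_dep=lnL_d,
        rates_indep=dict(zip(RATE_NAMES_4, r4)),
        rates_dep=dict(zip(RATE_NAMES_8, r8)),
        lrt_stat=stat,
        p_asymptotic=float(chi2.sf(stat, 4)) if stat > 0 else 1.0,
        p_mc=None,
        n_sim=0,
    )


def simulate_joint_traits(
    ta_or_tree, rates8, n_sim: int, rng: np.random.Generator,
    root_equal: bool = False,
):
    """Leaf states of ``n_sim`` independent trait pairs; (n_sim, n_leaves).

    States are sampled exactly through per-branch transition probabilities
    of the joint 4-state chain (equivalent in law to event-level
    simulation along every branch).
    """
    ta = (
        ta_or_tree
        if isinstance(ta_or_tree, TreeArrays)
        else TreeArrays.from_clade_tree(ta_or_tree)
    )
    Q = _q_from_rates8(np.asarray(rates8, dtype=float))
    lam, V = np.linalg.eig(Q.astype(complex))
    Vinv = np.linalg.inv(V)
    if root_equal:
        pi = np.full(4, 0.25)
    else:
        A = np.vstack([Q.T, np.ones(4)])
        b = np.array([0.0, 0, 0, 0, 1.0])
        pi = np.linalg.lstsq(A, b, rcond=None)[0]
        pi = np.clip(pi, 0, None)
        pi /= pi.sum()
    states = np.empty((ta.n_nodes, n_sim), dtype=np.int64)
    states[ta.root] = rng.choice(4, size=n_sim, p=pi)
    preorder = ta.postorder[::-1]
    for node in preorder:
        if node == ta.root:
            continue
        t = ta.edge_length[node]
        P = np.real(V @ np.diag(np.exp(lam * t)) @ Vinv)
        P = np.clip(P, 0, None)
        P /= P.sum(axis=1, keepdims=True)
        rows = P[states[ta.parent[node]]]  # (n_sim, 4)
        u = rng.random(n_sim)
        states[node] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
    leaf = states[: ta.n_leaves].T  # (n_sim, n_leaves)
    return leaf >> 1, leaf & 1


def pagel_mc_test(
    tree, trait_x, trait_y, *,
    n_sim: int = 1000, seed: int = 0,
    n_starts: int = 5, sim_n_starts: int = 1,
    maxiter: int = 200, sim_maxiter: int = 200,
    root: str = "stationary", optimizer: str = "nm",
) -> PagelFit:
    """Monte-Carlo (parametric bootstrap) Pagel test.

    Simulates ``n_sim`` trait pairs under the independent model at its
    MLEs, refits both models per replicate, and returns
    p_mc = (1 + #{sim LRT >= observed}) / (n_sim + 1).
    """
    ta, _ = _unit_height_arrays(tree)
    sx, sy = _traits_to_arrays(ta, trait_x, trait_y)
    for name, arr in (("x", sx), ("y", sy)):
        vals = set(arr[arr >= 0].tolist())
        if vals != {0, 1}:
            raise UntestableTraitError(
                f"trait {name} is monomorphic on the tree; test undefined"
            )
    obs = _fit_pagel_arrays(
        ta, sx, sy, n_starts=n_starts, seed=seed, maxiter=maxiter,
        root_equal=(root == "equal"), optimizer=optimizer,
    )
    rng = np.random.default_rng(seed + 1)
    r8_null = expand_independent_rates(
        np.array([obs.rates_indep[k] for k in RATE_NAMES_4])
    )
    simx, simy = simulate_joint_traits(
        ta, r8_null, n_sim, rng, root_equal=(root == "equal")
    )
    warm4 = np.log(np.clip(
        np.array([obs.rates_indep[k] for k in RATE_NAMES_4]),
        RATE_BOUNDS[0], RATE_BOUNDS[1],
    ))
    n_ge = 0
    for s in range(n_sim):
        sxx = simx[s].astype(np.int64)
        syy = simy[s].astype(np.int64)
        # masked leaves stay masked in the refit
        sxx[sx < 0] = -1
        syy[sy < 0] = -1
        rng_s = np.random.default_rng(seed + 2 + s)
        lnL_i, r4 = _fit_model(
            ta, sxx, syy, 4, n_starts=sim_n_starts, rng=rng_s,
            maxiter=sim_maxiter, root_equal=(root == "equal"),
            x0_extra=warm4, optimizer=optimizer,
        )
        lnL_d, _ = _fit_model(
            ta, sxx, syy, 8, n_starts=sim_n_starts, rng=rng_s,
            maxiter=sim_maxiter, root_equal=(root == "equal"),
            x0_extra=np.log(expand_independent_rates(r4)), optimizer=optimizer,
        )
        if max(2.0 * (lnL_d - lnL_i), 0.0) >= obs.lrt_stat:
            n_ge += 1
    p_mc = (1.0 + n_ge) / (n_sim + 1.0)
    return PagelFit(
        lnL_indep=obs.lnL_indep,
        lnL_dep=obs.lnL_dep,
        rates_indep=obs.rates_indep,
        rates_dep=obs.rates_dep,
        lrt_stat=obs.lrt_stat,
        p_asymptotic=obs.p_asymptotic,
        p_mc=p_mc,
        n_sim=n_sim,
    )


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni threshold alpha/m and significance calls (p < threshold)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    threshold = alpha / p.size
    return threshold, p < threshold
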