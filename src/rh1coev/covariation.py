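"""Weighted, APC-corrected mutual information scan with a randomization cutoff.

Columns of an amino-acid alignment are compared by mutual information (in
nats) computed on sequence-weighted, pseudocount-smoothed pair frequencies.
The average-product correction (APC) removes the shared background signal;
z-scores standardize each corrected pair against a null of within-column
shuffles.  Dataset-level significance uses the highest |z| seen across
fully randomized datasets (independent within-column shuffles), mirroring
randomization-cutoff practice for intrafamily alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import AMINO_ACIDS
from .io_core import CodonAlignment

N_AA = len(AMINO_ACIDS)


@dataclass
class MIResult:
    pair: tuple[int, int]
    mi_raw: float
    mi_corrected: float
    z: float
    cutoff: float | None = None
    n_random: int | None = None

    @property
    def significant(self) -> bool | None:
        if self.cutoff is None:
            return None
        return self.z > self.cutoff


def aa_matrix_from_codon_alignment(aln: CodonAlignment) -> np.ndarray:
    return aln.aa_matrix()


# ---------------------------------------------------------------- weights
def sequence_weights(aa: np.ndarray, identity_threshold: float = 0.62) -> np.ndarray:
    """1/(cluster size) weights from single-linkage identity clustering.

    Two sequences link if their pairwise identity (over positions where both
    are ungapped) is >= the threshold.
    """
    aa = np.asarray(aa)
    n = aa.shape[0]
    if n == 0 or aa.size == 0:
        raise ValueError("empty alignment")
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            both = (aa[i] >= 0) & (aa[j] >= 0)
            m = both.sum()
            ident = (aa[i][both] == aa[j][both]).sum() / m if m else 0.0
            if ident >= identity_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = [find(i) for i in range(n)]
    sizes = {}
    for r in roots:
        sizes[r] = sizes.get(r, 0) + 1
    return np.array([1.0 / sizes[r] for r in roots])


# --------------------------------------------------------------------- MI
def _joint_freqs(col_i, col_j, weights, pseudocount):
    both = (col_i >= 0) & (col_j >= 0)
    if not both.any():
        raise ValueError("no jointly ungapped sequences for this pair")
    ci, cj, w = col_i[both], col_j[both], weights[both]
    J = np.zeros((N_AA, N_AA))
    np.add.at(J, (ci, cj), w)
    J /= J.sum()
    if pseudocount > 0:
        fi = J.sum(axis=1)
        fj = J.sum(axis=0)
        J = (1.0 - pseudocount) * J + pseudocount * np.outer(fi, fj)
    return J


def _mi_from_joint(J: np.ndarray) -> float:
    fi = J.sum(axis=1)
    fj = J.sum(axis=0)
    mask = J > 0
    denom = np.outer(fi, fj)
    mi = float(np.sum(J[mask] * np.log(J[mask] / denom[mask])))
    return max(mi, 0.0)


def weighted_mi(col_i, col_j, weights=None, pseudocount: float = 0.05) -> float:
    """Mutual information (nats) of two columns on weighted frequencies."""
    col_i = np.asarray(col_i)
    col_j = np.asarray(col_j)
    if col_i.shape != col_j.shape:
        raise ValueError("columns differ in length")
    if weights is None:
        weights = np.ones(col_i.shape[0])
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return _mi_from_joint(_joint_freqs(col_i, col_j, weights, pseudocount))


def mi_matrix(aa: np.ndarray, weights=None, pseudocount: float = 0.05) -> np.ndarray:
    """Full symmetric MI matrix over columns (diagonal = 0).

    Fast one-hot path when the alignment is gap-free; otherwise per-pair.
    """
    aa = np.asarray(aa)
    n_seq, n_col = aa.shape
    if weights is None:
        weights = np.ones(n_seq)
    weights = np.asarray(weights, dtype=float)
    M = np.zeros((n_col, n_col))
    if (aa >= 0).all():
        X = np.zeros((n_seq, n_col, N_AA))
        X[np.arange(n_seq)[:, None], np.arange(n_col)[None, :], aa] = 1.0
        Xf = X.reshape(n_seq, n_col * N_AA)
        C = (Xf * weights[:, None]).T @ Xf  # (n_col*A, n_col*A)
        total = weights.sum()
        J = C.reshape(n_col, N_AA, n_col, N_AA).transpose(0, 2, 1, 3) / total
        f = (Xf * weights[:, None]).sum(axis=0).reshape(n_col, N_AA) / total
        outer = f[:, None, :, None] * f[None, :, None, :]
        if pseudocount > 0:
            J = (1.0 - pseudocount) * J + pseudocount * outer
        safe = np.where(outer > 0, outer, 1.0)
        T = np.where(J > 0, J * np.log(np.where(J > 0, J, 1.0) / safe), 0.0)
        M = T.sum(axis=(2, 3))
        np.clip(M, 0.0, None, out=M)
        M = np.triu(M, 1)  # mirror upper triangle: mi(i,j) == mi(j,i) exactly
        M = M + M.T
    else:
        for i in range(n_col):
            for j in range(i + 1, n_col):
                M[i, j] = M[j, i] = weighted_mi(
                    aa[:, i], aa[:, j], weights, pseudocount
                )
    return M


def apc_correct(M: np.ndarray) -> np.ndarray:
    """Average-product correction: subtract (row mean x col mean)/grand mean."""
    n = M.shape[0]
    if n < 2:
        return M.copy()
    off = ~np.eye(n, dtype=bool)
    row_mean = (M.sum(axis=1)) / (n - 1)
    grand = M[off].mean()
    if grand <= 0:
        return M - 0.0
    apc = np.outer(row_mean, row_mean) / grand
    out = M - apc
    np.fill_diagonal(out, 0.0)
    return out


def _shuffle_columns(aa: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent within-column permutation of every column."""
    out = np.empty_like(aa)
    n_seq = aa.shape[0]
    for j in range(aa.shape[1]):
        out[:, j] = aa[rng.permutation(n_seq), j]
    return out


def apc_z_scores(
    aa: np.ndarray,
    weights=None,
    pseudocount: float = 0.05,
    n_column_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
    mi_obs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(APC-corrected MI, z) matrices for every column pair.

    z standardizes the corrected MI against within-column shuffles of the
    whole alignment (weights held fixed: shuffles preserve column
    composition).
    """
    if n_column_shuffles < 2:
        raise ValueError("need at least 2 shuffles for a null sd")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if mi_obs is None:
        mi_obs = mi_matrix(aa, weights, pseudocount)
    corr_obs = apc_correct(mi_obs)
    null = np.empty((n_column_shuffles,) + mi_obs.shape)
    for r in range(n_column_shuffles):
        shuf = _shuffle_columns(aa, rng)
        null[r] = apc_correct(mi_matrix(shuf, weights, pseudocount))
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.zeros_like(corr_obs)
    ok = sd > 1e-12
    z[ok] = (corr_obs[ok] - mu[ok]) / sd[ok]
    np.fill_diagonal(z, 0.0)
    return corr_obs, z


def randomization_cutoff(
    aa: np.ndarray,
    weights=None,
    pseudocount: float = 0.05,
    n_random: int = 150,
    n_column_shuffles: int = 100,
    seed: int = 0,
) -> float:
    """z* = max |z| over all pairs across fully randomized datasets."""
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(n_random):
        rand = _shuffle_columns(aa, rng)
        _, z = apc_z_scores(
            rand, weights, pseudocount,
            n_column_shuffles=n_column_shuffles, seed=rng,
        )
        best = max(best, float(np.abs(z).max()))
    return best


def mi_scan(
    aln_or_aa,
    focal_site: int,
    ref_map=None,
    weights=None,
    identity_threshold: float = 0.62,
    pseudocount: float = 0.05,
    n_column_shuffles: int = 100,
    n_random: int = 150,
    seed: int = 0,
) -> pd.DataFrame:
    """Full scan: MI / APC / z against the focal site, with cutoff z*.

    Accepts a CodonAlignment (translated internally) or an amino-acid index
    matrix plus ``ref_map``.  The report is restricted to pairs containing
    the focal site but computed from the full matrix (APC needs it).
    """
    if isinstance(aln_or_aa, CodonAlignment):
        aa = aln_or_aa.aa_matrix()
        ref_map = aln_or_aa.ref_map
    else:
        aa = np.asarray(aln_or_aa)
        if ref_map is None:
            ref_map = np.arange(1, aa.shape[1] + 1)
    ref_map = np.asarray(ref_map)
    focal_col = int(np.nonzero(ref_map == focal_site)[0][0])
    if weights is None:
        weights = sequence_weights(aa, identity_threshold)
    mi = mi_matrix(aa, weights, pseudocount)
    corr, z = apc_z_scores(
        aa, weights, pseudocount,
        n_column_shuffles=n_column_shuffles, seed=seed,
    )
    cutoff = randomization_cutoff(
        aa, weights, pseudocount,
        n_random=n_random, n_column_shuffles=n_column_shuffles,
        seed=seed + 1,
    )
    rows = []
    for col in range(aa.shape[1]):
        if col == focal_col:
            continue
        rows.append(
            {
                "site": int(ref_map[col]),
                "focal_site": focal_site,
                "mi": mi[focal_col, col],
                "mi_corrected": corr[focal_col, col],
                "z": z[focal_col, col],
                "cutoff": cutoff,
                "significant": z[focal_col, col] > cutoff,
                "n_random": n_random,
            }
        )
    return pd.DataFrame(rows)
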