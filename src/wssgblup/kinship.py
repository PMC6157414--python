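"""Relationship structures for single-step evaluation.

Pedigree side: the numerator relationship matrix A by the tabular method,
inbreeding coefficients F by the Meuwissen–Luo ancestor recursion
(diag(A) = 1 + F), and the sparse A inverse by Henderson's rules with the
inbreeding-adjusted Mendelian-sampling variances.

Genomic side: the VanRaden-style weighted genomic relationship
G = Z D Z' / k with Z the allele-frequency-centered codes, D the per-SNP
weights (normalized to mean 1) and k = sum_j 2 p_j (1-p_j) d_j, blended
with A22 for invertibility.

Combined: H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1] confined to the genotyped
block, stored sparse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = [
    "inbreeding",
    "build_A",
    "extract_A22",
    "a22_from_pedigree",
    "build_A_inverse",
    "build_G",
    "blend_G",
    "invert_spd",
    "build_H_inverse",
    "KinshipBundle",
    "build_kinship_bundle",
    "export_coo",
]


def _mendelian_d(F: np.ndarray, s: int, d: int) -> float:
    """Mendelian-sampling variance for an animal with parents s, d (-1 unknown).

    Equals 0.5 - 0.25 (F_s + F_d) with an unknown parent entering as F = -1,
    giving 0.75 - 0.25 F_known for one known parent and 1 for a founder.
    """
    fs = F[s] if s >= 0 else -1.0
    fd = F[d] if d >= 0 else -1.0
    return 0.5 - 0.25 * (fs + fd)


def inbreeding(ped) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo ancestor recursion.

    For each animal the diagonal a_ii = sum_j L_ij^2 D_j is accumulated by
    tracing ancestors from youngest to oldest, where L carries the expected
    gene contributions and D the Mendelian-sampling variances; F = a_ii - 1.
    Exactly matches diag(A) - 1 from the tabular method.
    """
    n = len(ped)
    sire, dam = ped.sire_idx, ped.dam_idx
    F = np.zeros(n)
    D = np.empty(n)
    for i in range(n):
        D[i] = _mendelian_d(F, sire[i], dam[i])
        if sire[i] < 0 or dam[i] < 0:
            F[i] = 0.0
            continue
        # accumulate a_ii over ancestors of i
        L: dict[int, float] = {i: 1.0}
        total = 0.0
        for j in range(i, -1, -1):
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            total += lj * lj * D[j]
            if sire[j] >= 0:
                L[sire[j]] = L.get(sire[j], 0.0) + 0.5 * lj
            if dam[j] >= 0:
                L[dam[j]] = L.get(dam[j], 0.0) + 0.5 * lj
        F[i] = total - 1.0
    return F


def build_A(ped) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    a_ij = 0.5 (a_{i,sire(j)} + a_{i,dam(j)}) for i < j and
    a_jj = 1 + 0.5 a_{sire(j),dam(j)}; unknown parents contribute zero.
    """
    n = len(ped)
    sire, dam = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        col = np.zeros(j)
        if s >= 0:
            col += 0.5 * A[:j, s]
        if d >= 0:
            col += 0.5 * A[:j, d]
        A[:j, j] = col
        A[j, :j] = col
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def extract_A22(A: np.ndarray, genotyped_idx: np.ndarray) -> np.ndarray:
    """Genotyped-row/column submatrix of A (order = genotyped_idx)."""
    return A[np.ix_(genotyped_idx, genotyped_idx)]


def a22_from_pedigree(ped, genotyped_idx: np.ndarray) -> np.ndarray:
    """A22 by recursive ancestor tracing, without materializing full A.

    Memoized pairwise relationship recursion; identical to extracting the
    tabular A's genotyped block.
    """
    sire, dam = ped.sire_idx, ped.dam_idx
    memo: dict[tuple[int, int], float] = {}

    def rel(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            v = 1.0 + 0.5 * rel(sire[i], dam[i])
        else:
            # j is the younger animal (later in topological order)
            v = 0.5 * (rel(i, sire[j]) + rel(i, dam[j]))
        memo[key] = v
        return v

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(ped) + 1000))
    try:
        g = np.asarray(genotyped_idx)
        m = len(g)
        out = np.empty((m, m))
        for a in range(m):
            for b in range(a, m):
                out[a, b] = out[b, a] = rel(int(g[a]), int(g[b]))
    finally:
        sys.setrecursionlimit(old)
    return out


def build_A_inverse(ped, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Each animal contributes 1/D_i on the pattern (i, -0.5 s, -0.5 d) where
    D_i is its Mendelian-sampling variance from parental inbreeding; at most
    nine entries per animal.
    """
    if F is None:
        F = inbreeding(ped)
    n = len(ped)
    sire, dam = ped.sire_idx, ped.dam_idx
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        b = 1.0 / _mendelian_d(F, sire[i], dam[i])
        entries = [(i, 1.0)]
        if sire[i] >= 0:
            entries.append((sire[i], -0.5))
        if dam[i] >= 0:
            entries.append((dam[i], -0.5))
        for r, cr in entries:
            for c, cc in entries:
                rows.append(r)
                cols.append(c)
                vals.append(b * cr * cc)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def build_G(
    M_imputed: np.ndarray,
    weights: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted genomic relationship matrix.

    Returns (G, normalized weights d, scale k).  Z = M - 2p column-centers
    the imputed codes at the observed ("current") allele frequencies;
    G = Z D Z' / k with k = sum_j 2 p_j q_j d_j, and d rescaled to mean 1 so
    k stays on the unweighted sum-2pq scale across weight iterations.
    """
    M = np.asarray(M_imputed, dtype=np.float64)
    n, m = M.shape
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=np.float64)
    d = np.ones(m) if weights is None else np.asarray(weights, dtype=np.float64)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("SNP weights must be finite and non-negative")
    dm = d.mean()
    if dm <= 0:
        raise ValueError("SNP weights sum to zero")
    d = d / dm
    k = float(np.sum(2.0 * p * (1.0 - p) * d))
    if k <= 0:
        raise ValueError("all SNPs monomorphic: G scale k = 0")
    Z = M - 2.0 * p
    G = (Z * d) @ Z.T / k
    G = 0.5 * (G + G.T)
    return G, d, k


def blend_G(G: np.ndarray, A22: np.ndarray, alpha: float = 0.95) -> np.ndarray:
    """G_b = alpha G + (1-alpha) A22; makes G invertible at full rank of A22."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    Gb = alpha * G + (1.0 - alpha) * A22
    return 0.5 * (Gb + Gb.T)


def invert_spd(M: np.ndarray, context: str = "matrix") -> np.ndarray:
    """Dense SPD inverse via Cholesky, symmetry enforced."""
    try:
        c, low = sla.cho_factor(M, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"{context} numerically singular ({err}); "
            "for a blended G, retry with a smaller alpha"
        ) from None
    inv = sla.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)


def build_H_inverse(
    A_inv: sp.spmatrix,
    A22_inv: np.ndarray,
    G_inv: np.ndarray,
    genotyped_idx: np.ndarray,
) -> sp.csr_matrix:
    """H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1] on the genotyped block."""
    g = np.asarray(genotyped_idx)
    corr = G_inv - A22_inv
    rows = np.repeat(g, len(g))
    cols = np.tile(g, len(g))
    add = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=A_inv.shape)
    return (A_inv + add).tocsr()


@dataclass
class KinshipBundle:
    """All relationship structures for one (weighted) single-step fit."""

    F: np.ndarray
    A_inv: sp.csr_matrix
    A22: np.ndarray
    A22_inv: np.ndarray
    G: np.ndarray
    G_blended: np.ndarray
    G_inv: np.ndarray
    H_inv: sp.csr_matrix
    genotyped_idx: np.ndarray
    weights: np.ndarray
    freqs: np.ndarray
    k: float
    alpha: float


def build_kinship_bundle(
    ped,
    geno_imputed: np.ndarray,
    genotyped_ids: list[str],
    weights: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    alpha: float = 0.95,
    A: np.ndarray | None = None,
) -> KinshipBundle:
    """Assemble F, A^-1, A22, weighted blended G and H^-1 in one pass."""
    gidx = ped.subset_indices(genotyped_ids)
    F = inbreeding(ped)
    A_inv = build_A_inverse(ped, F)
    if A is None:
        A = build_A(ped)
    A22 = extract_A22(A, gidx)
    p = geno_imputed.mean(axis=0) / 2.0 if freqs is None else freqs
    G, d, k = build_G(geno_imputed, weights, p)
    Gb = blend_G(G, A22, alpha)
    G_inv = invert_spd(Gb, "blended G")
    A22_inv = invert_spd(A22, "A22")
    H_inv = build_H_inverse(A_inv, A22_inv, G_inv, gidx)
    return KinshipBundle(
        F=F, A_inv=A_inv, A22=A22, A22_inv=A22_inv, G=G, G_blended=Gb,
        G_inv=G_inv, H_inv=H_inv, genotyped_idx=gidx, weights=d,
        freqs=np.asarray(p), k=k, alpha=alpha,
    )


def export_coo(M, path, ids: list[str] | None = None) -> None:
    """Upper-triangle coordinate text export (row, col, value), 1-based."""
    if sp.issparse(M):
        M = M.tocoo()
        with open(path, "w") as fh:
            for r, c, v in zip(M.row, M.col, M.data):
                if r <= c:
                    fh.write(f"{r + 1}\t{c + 1}\t{v:.12g}\n")
    else:
        M = np.asarray(M)
        with open(path, "w") as fh:
            for r in range(M.shape[0]):
                for c in range(r, M.shape[1]):
                    if M[r, c] != 0.0:
                        fh.write(f"{r + 1}\t{c + 1}\t{M[r, c]:.12g}\n")
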