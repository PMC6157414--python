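"""Weighted single-step GBLUP association: SNP effects, weights, windows.

Each iteration is the three-step loop: (1) set per-SNP weights (all 1.0 for
iteration one, i.e. standard ssGBLUP), (2) rebuild G/H^-1 with the weights
and solve the mixed model for GEBVs, (3) back-solve SNP effects from the
genotyped animals' GEBVs, u_hat = D Z' G_b^-1 a_g / k, and derive new
weights d_j = u_hat_j^2 * 2 p_j (1 - p_j).  Additive variance is then
decomposed into sliding windows of adjacent SNPs (default 50, step 1,
confined within chromosomes) and expressed as a percentage of either the
REML additive variance (default) or the variance of the total direct
genomic value (self-normalizing alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinship
from .geno_io import GenotypeMatrix, SnpMap, _natural_chrom_key
from .mme import ModelFit, ModelSpec, VarianceComponents, assemble_mme, reml_estimate, solve_mme

__all__ = [
    "backsolve_snp_effects",
    "update_weights",
    "window_variance",
    "rank_windows",
    "run_wssgblup",
    "IterationResult",
    "WssgblupResult",
]


def backsolve_snp_effects(
    a_genotyped: np.ndarray,
    Z: np.ndarray,
    weights: np.ndarray,
    k: float,
    G_inv: np.ndarray,
) -> np.ndarray:
    """SNP effects from genotyped GEBVs: u_hat = D Z' G_b^-1 a_g / k.

    Uses the same centered matrix Z, weights D, scale k and (blended) G
    inverse as the fit, so with an unblended G the identity
    Z u_hat = a_g holds exactly.
    """
    a_genotyped = np.asarray(a_genotyped, dtype=np.float64)
    if Z.shape[0] != a_genotyped.shape[0]:
        raise ValueError(
            f"Z has {Z.shape[0]} animals but GEBV vector has {a_genotyped.shape[0]}"
        )
    if Z.shape[1] != len(weights):
        raise ValueError("weights length does not match SNP count")
    return weights * (Z.T @ (G_inv @ a_genotyped)) / k


def update_weights(u_hat: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """New weights d_j = u_hat_j^2 * 2 p_j (1-p_j), rescaled to mean 1.

    If every raw weight is zero (no signal at all) the uninformative flat
    weight vector is returned instead of dividing by zero.
    """
    u_hat = np.asarray(u_hat, dtype=np.float64)
    p = np.asarray(freqs, dtype=np.float64)
    if np.any(~np.isfinite(u_hat)):
        raise FloatingPointError("NaN/inf in SNP effects; cannot form weights")
    raw = u_hat**2 * 2.0 * p * (1.0 - p)
    m = raw.mean()
    if m == 0.0:
        return np.ones_like(raw)
    return raw / m


def _window_spans(snp_map: SnpMap, window_size: int, step: int):
    """(start, stop, chromosome, is_tail) spans in map_index coordinates.

    Full windows start at every step-th index up to m - window_size within a
    chromosome; a chromosome shorter than the window yields one shorter
    window flagged as a tail.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    spans = []
    for chrom, sl in snp_map.chromosome_slices().items():
        m = sl.stop - sl.start
        if window_size > m:
            spans.append((sl.start, sl.stop, chrom, True))
            continue
        for s in range(sl.start, sl.stop - window_size + 1, step):
            spans.append((s, s + window_size, chrom, False))
    return spans


def window_variance(
    u_hat: np.ndarray,
    Z: np.ndarray,
    sigma2_a: float,
    snp_map: SnpMap,
    window_size: int = 50,
    step: int = 1,
    denominator: str = "sigma2_a",
) -> pd.DataFrame:
    """Sliding-window share of additive genetic variance.

    For window w the partial direct genomic value of animal i is
    u_w(i) = sum_{j in w} z_ij u_hat_j; the window's percentage is
    Var_i(u_w) / denom * 100 with denom either the REML additive variance
    ``sigma2_a`` (default) or ``dgv``, the variance of the total direct
    genomic value Z u_hat (under which one genome-wide window is exactly
    100%).  Windows are index-based (never base pairs) and never span
    chromosomes; a window is labeled by its first SNP.
    """
    u_hat = np.asarray(u_hat, dtype=np.float64)
    max_chrom = max(
        sl.stop - sl.start for sl in snp_map.chromosome_slices().values()
    )
    if window_size > max_chrom and window_size > len(snp_map):
        raise ValueError(
            f"window_size {window_size} exceeds every chromosome's SNP count"
        )
    if denominator == "sigma2_a":
        denom = float(sigma2_a)
    elif denominator == "dgv":
        dgv = Z @ u_hat
        denom = float(np.var(dgv))
    else:
        raise ValueError("denominator must be 'sigma2_a' or 'dgv'")
    if denom <= 0:
        raise ValueError("window denominator must be positive")

    # prefix sums of per-animal partial DGVs make sliding windows O(n*m)
    contrib = Z * u_hat  # (animals, snps)
    csum = np.concatenate(
        [np.zeros((Z.shape[0], 1)), np.cumsum(contrib, axis=1)], axis=1
    )
    rows = []
    ids = snp_map.snp_ids
    pos = snp_map.positions
    for start, stop, chrom, tail in _window_spans(snp_map, window_size, step):
        u_w = csum[:, stop] - csum[:, start]
        pct = float(np.var(u_w) / denom * 100.0)
        rows.append(
            {
                "chromosome": chrom,
                "start_index": start,
                "end_index": stop - 1,
                "start_pos": int(pos[start]),
                "end_pos": int(pos[stop - 1]),
                "n_snps": stop - start,
                "pct_variance": pct,
                "is_tail": tail,
                "snp_ids": ",".join(ids[start:stop]),
            }
        )
    return pd.DataFrame(rows)


def rank_windows(table: pd.DataFrame, threshold_percent: float = 1.0) -> pd.DataFrame:
    """Sort windows by percentage descending, flag those at/above threshold.

    Ties are broken by (chromosome, start position) ascending.
    """
    if table.empty:
        raise ValueError("window table is empty")
    df = table.copy()
    df["_ck"] = df["chromosome"].map(_natural_chrom_key)
    df = df.sort_values(
        ["pct_variance", "_ck", "start_pos"],
        ascending=[False, True, True],
        kind="stable",
    ).drop(columns="_ck")
    df["significant"] = df["pct_variance"] >= threshold_percent
    return df.reset_index(drop=True)


@dataclass
class IterationResult:
    iteration: int
    fit: ModelFit
    effects: pd.DataFrame  # map_index, snp_id, u_hat, weight, freq
    windows: pd.DataFrame
    weights: np.ndarray
    k: float
    bundle: "kinship.KinshipBundle"


@dataclass
class WssgblupResult:
    iterations: list[IterationResult]
    vc: VarianceComponents

    @property
    def final(self) -> IterationResult:
        return self.iterations[-1]


def run_wssgblup(
    ped,
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    spec: ModelSpec | None = None,
    vc: VarianceComponents | None = None,
    n_iterations: int = 2,
    alpha: float = 0.95,
    window_size: int = 50,
    step: int = 1,
    denominator: str = "sigma2_a",
    reestimate_vc: bool = False,
    solver: str = "direct",
) -> WssgblupResult:
    """Full weighted single-step GBLUP loop on QC'd inputs.

    Iteration 1 uses flat weights (standard ssGBLUP); variance components
    are REML-estimated once on the iteration-1 relationship matrices and
    held fixed afterwards unless ``reestimate_vc``.  Every iteration's fit,
    SNP effects, weights, and window table are retained.
    """
    from .geno_io import impute_missing  # local to avoid cycle at import time

    spec = spec or ModelSpec()
    M = impute_missing(geno)
    freqs = M.mean(axis=0) / 2.0
    A = kinship.build_A(ped)
    weights = np.ones(geno.n_snps)
    results: list[IterationResult] = []

    for it in range(1, n_iterations + 1):
        bundle = kinship.build_kinship_bundle(
            ped, M, geno.animal_ids, weights=weights, freqs=freqs, alpha=alpha, A=A
        )
        if vc is None or (reestimate_vc and it > 1):
            vc = _estimate_vc(ped, bundle, pheno, spec)
        system = assemble_mme(spec, bundle.H_inv, vc, pheno, ped)
        fit = solve_mme(system, spec, vc, method=solver)

        a_g = fit.a.iloc[bundle.genotyped_idx].to_numpy()
        Z = M - 2.0 * freqs
        u_hat = backsolve_snp_effects(a_g, Z, bundle.weights, bundle.k, bundle.G_inv)
        if np.any(~np.isfinite(u_hat)):
            raise FloatingPointError(f"NaN in SNP effects at iteration {it}")
        effects = pd.DataFrame(
            {
                "map_index": np.arange(geno.n_snps),
                "snp_id": geno.snp_map.snp_ids,
                "u_hat": u_hat,
                "weight": bundle.weights,
                "freq": freqs,
                "iteration": it,
            }
        )
        windows = window_variance(
            u_hat, Z, vc.sigma2_a, geno.snp_map,
            window_size=window_size, step=step, denominator=denominator,
        )
        results.append(
            IterationResult(
                iteration=it, fit=fit, effects=effects, windows=windows,
                weights=bundle.weights.copy(), k=bundle.k, bundle=bundle,
            )
        )
        weights = update_weights(u_hat, freqs)
        if np.any(~np.isfinite(weights)):
            raise FloatingPointError(f"NaN in SNP weights after iteration {it}")

    return WssgblupResult(iterations=results, vc=vc)


def _estimate_vc(ped, bundle, pheno, spec) -> VarianceComponents:
    """REML on the phenotyped animals' H submatrix."""
    from .mme import build_design

    H = np.linalg.inv(bundle.H_inv.toarray())
    pidx = ped.subset_indices(pheno["animal"].tolist())
    K = H[np.ix_(pidx, pidx)]
    y, X, _, _, _, _ = build_design(pheno, spec, ped)
    fam = pheno["family"].to_numpy() if spec.family else None
    return reml_estimate(y, X, K=K if spec.animal else None, family=fam)
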