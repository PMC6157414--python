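"""Single-trait mixed model: y = Xb + Z1 a + Z2 w + e.

The animal effect a is correlated with covariance H sigma2_a (the combined
pedigree/genomic relationship), the full-sib family effect w is i.i.d. with
variance sigma2_w (shared rearing environment), and e is the residual.
Fixed effects (harvest group, hatch year, ...) use reference-level coding.

Henderson's mixed-model equations are assembled sparse and solved either by
a direct sparse factorization or by preconditioned conjugate gradients.
Variance components come from average-information REML on the phenotyped
animals' covariance, with an EM fixed-point fallback whenever an AI step
proposes a non-positive component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "ModelFit",
    "build_design",
    "assemble_mme",
    "solve_mme",
    "reml_estimate",
]


@dataclass
class ModelSpec:
    """Model terms: trait column, fixed factors, and which random terms enter."""

    trait: str = "trait"
    fixed: tuple[str, ...] = ("harvest_group", "hatch_year")
    animal: bool = True
    family: bool = True


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_w: float
    sigma2_e: float
    converged: bool = True
    n_rounds: int = 0
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def lambda_a(self) -> float:
        return self.sigma2_e / self.sigma2_a

    @property
    def lambda_w(self) -> float:
        return self.sigma2_e / self.sigma2_w

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_w + self.sigma2_e
        return self.sigma2_a / tot

    @property
    def c2(self) -> float:
        tot = self.sigma2_a + self.sigma2_w + self.sigma2_e
        return self.sigma2_w / tot


@dataclass
class ModelFit:
    """Solutions of the mixed-model equations.

    ``a`` spans the whole pedigree (animals without phenotypes are carried
    by the relationship structure), so it holds the GEBVs of every animal.
    """

    b: pd.Series
    a: pd.Series
    w: pd.Series
    residuals: pd.Series
    vc: VarianceComponents
    solver: str = "direct"
    iterations: int = 0


def build_design(
    pheno: pd.DataFrame, spec: ModelSpec, ped, family_levels: list[str] | None = None
):
    """Incidence matrices X (dense), Z1 and Z2 (sparse selection).

    X gets an intercept plus reference-level (drop-first) dummies per fixed
    factor; a rank check names confounded factors.  Z1 maps records to
    pedigree positions; Z2 maps records to family levels.
    """
    n = len(pheno)
    y = pheno[spec.trait].to_numpy(dtype=np.float64)

    cols = [np.ones(n)]
    names = ["intercept"]
    for f in spec.fixed:
        levels = sorted(pheno[f].astype(str).unique())
        for lv in levels[1:]:
            cols.append((pheno[f].astype(str) == lv).to_numpy(dtype=np.float64))
            names.append(f"{f}={lv}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient fixed-effect design: factors {list(spec.fixed)} "
            "are confounded after reference-level coding"
        )

    Z1 = None
    if spec.animal:
        ridx = ped.subset_indices(pheno["animal"].tolist())
        Z1 = sp.csr_matrix(
            (np.ones(n), (np.arange(n), ridx)), shape=(n, len(ped))
        )

    Z2 = None
    fam_levels: list[str] = []
    if spec.family:
        fams = pheno["family"].astype(str)
        fam_levels = family_levels or sorted(fams.unique())
        fmap = {f: i for i, f in enumerate(fam_levels)}
        Z2 = sp.csr_matrix(
            (np.ones(n), (np.arange(n), fams.map(fmap).to_numpy())),
            shape=(n, len(fam_levels)),
        )
    return y, X, names, Z1, Z2, fam_levels


def assemble_mme(
    spec: ModelSpec,
    H_inv: sp.spmatrix | None,
    vc: VarianceComponents,
    pheno: pd.DataFrame,
    ped,
):
    """Assemble the symmetric sparse MME coefficient matrix and RHS.

    Block system (lambda_a = sigma2_e/sigma2_a, lambda_w = sigma2_e/sigma2_w):

        [X'X      X'Z1             X'Z2        ] [b]   [X'y ]
        [Z1'X     Z1'Z1 + H^-1 la  Z1'Z2       ] [a] = [Z1'y]
        [Z2'X     Z2'Z1            Z2'Z2 + I lw] [w]   [Z2'y]
    """
    y, X, names, Z1, Z2, fam_levels = build_design(pheno, spec, ped)
    Xs = sp.csr_matrix(X)
    blocks_rows = []
    rhs_parts = [X.T @ y]
    top = [Xs.T @ Xs]
    if Z1 is not None:
        if H_inv.shape[0] != len(ped):
            raise ValueError("H_inv dimension must equal pedigree size")
        top.append(Xs.T @ Z1)
    if Z2 is not None:
        top.append(Xs.T @ Z2)
    blocks_rows.append(top)

    if Z1 is not None:
        row = [Z1.T @ Xs, Z1.T @ Z1 + sp.csr_matrix(H_inv) * vc.lambda_a]
        if Z2 is not None:
            row.append(Z1.T @ Z2)
        blocks_rows.append(row)
        rhs_parts.append(Z1.T @ y)
    if Z2 is not None:
        row = [Z2.T @ Xs]
        if Z1 is not None:
            row.append(Z2.T @ Z1)
        row.append(Z2.T @ Z2 + sp.identity(Z2.shape[1], format="csr") * vc.lambda_w)
        blocks_rows.append(row)
        rhs_parts.append(Z2.T @ y)

    C = sp.bmat(blocks_rows, format="csr")
    rhs = np.concatenate(rhs_parts)
    meta = {
        "fixed_names": names,
        "n_fixed": X.shape[1],
        "n_animal": len(ped) if Z1 is not None else 0,
        "n_family": len(fam_levels),
        "fam_levels": fam_levels,
        "y": y,
        "X": X,
        "Z1": Z1,
        "Z2": Z2,
        "animal_ids": ped.ids if Z1 is not None else [],
        "pheno_animals": pheno["animal"].tolist(),
    }
    return C, rhs, meta


def solve_mme(
    system, spec: ModelSpec, vc: VarianceComponents, method: str = "direct",
    tol: float = 1e-10, maxiter: int = 20000,
) -> ModelFit:
    """Solve the assembled MME; 'direct' sparse LU or 'cg' (Jacobi PCG)."""
    C, rhs, meta = system
    if method == "direct":
        sol = spla.spsolve(C.tocsc(), rhs)
        iters = 0
    elif method == "cg":
        diag = C.diagonal()
        M = sp.diags(1.0 / diag)
        counter = {"n": 0}

        def _cb(_):
            counter["n"] += 1

        sol, info = spla.cg(C, rhs, rtol=tol, maxiter=maxiter, M=M, callback=_cb)
        if info != 0:
            res = np.linalg.norm(C @ sol - rhs) / np.linalg.norm(rhs)
            raise RuntimeError(
                f"PCG failed to converge in {maxiter} iterations "
                f"(relative residual {res:.3e})"
            )
        iters = counter["n"]
    else:
        raise ValueError(f"unknown solver {method!r}")

    nf, na, nw = meta["n_fixed"], meta["n_animal"], meta["n_family"]
    b = pd.Series(sol[:nf], index=meta["fixed_names"], name="fixed")
    a = pd.Series(sol[nf:nf + na], index=meta["animal_ids"], name="gebv")
    w = pd.Series(sol[nf + na:nf + na + nw], index=meta["fam_levels"], name="family")
    yhat = meta["X"] @ sol[:nf]
    if meta["Z1"] is not None:
        yhat = yhat + meta["Z1"] @ sol[nf:nf + na]
    if meta["Z2"] is not None:
        yhat = yhat + meta["Z2"] @ sol[nf + na:]
    resid = pd.Series(meta["y"] - yhat, index=meta["pheno_animals"], name="residual")
    return ModelFit(b=b, a=a, w=w, residuals=resid, vc=vc, solver=method, iterations=iters)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _loglik(Vchol, XtViX, yPy) -> float:
    logdetV = 2.0 * np.sum(np.log(np.diag(Vchol)))
    sign, logdetX = np.linalg.slogdet(XtViX)
    return -0.5 * (logdetV + logdetX + yPy)


def reml_estimate(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    family: np.ndarray | None = None,
    init: VarianceComponents | None = None,
    max_rounds: int = 50,
    tol: float = 1e-8,
) -> VarianceComponents:
    """Average-information REML for (sigma2_a, sigma2_w, sigma2_e).

    Operates on the phenotyped animals' covariance
    V = sigma2_a K + sigma2_w Z2 Z2' + sigma2_e I, where K is the
    relationship (H) submatrix among phenotyped animals and ``family``
    labels records sharing a family.  Pass K=None to drop the animal term,
    family=None to drop the family term.

    Each round forms P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 and takes a
    Newton step with the average-information matrix
    AI_ij = 0.5 y'P V_i P V_j P y; if any proposed component is
    non-positive the round falls back to the EM fixed point
    theta_i <- theta_i * (y'P V_i P y) / tr(P V_i), which preserves
    positivity and does not decrease the restricted likelihood.
    Convergence: max relative parameter change < tol, or max_rounds.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    X = np.asarray(X, dtype=np.float64)

    comps: list[str] = []
    Vmats: list = []
    if K is not None:
        comps.append("a")
        Vmats.append(np.asarray(K, dtype=np.float64))
    if family is not None:
        fam = pd.factorize(np.asarray(family))[0]
        Z2 = sp.csr_matrix(
            (np.ones(n), (np.arange(n), fam)), shape=(n, fam.max() + 1)
        )
        Vw = (Z2 @ Z2.T).toarray()
        comps.append("w")
        Vmats.append(Vw)
    comps.append("e")
    Vmats.append(np.eye(n))

    vary = float(np.var(y, ddof=1))
    if init is None:
        start = vary / (len(comps))
        theta = np.full(len(comps), start)
    else:
        full = {"a": init.sigma2_a, "w": init.sigma2_w, "e": init.sigma2_e}
        theta = np.array([full[c] for c in comps])
    if np.any(theta <= 0):
        raise ValueError("initial variance components must be positive")

    floor = 1e-10 * vary

    def _ll_at(th: np.ndarray) -> float:
        V = sum(t * Vm for t, Vm in zip(th, Vmats))
        try:
            c, low = sla.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        Vi = sla.cho_solve((c, low), np.eye(n), check_finite=False)
        W = Vi @ X
        XtViX = X.T @ W
        Pv = Vi - W @ np.linalg.solve(XtViX, W.T)
        return _loglik(c, XtViX, float(y @ (Pv @ y)))

    ll_trace: list[float] = []
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        V = sum(t * Vm for t, Vm in zip(theta, Vmats))
        c, low = sla.cho_factor(V, lower=True, check_finite=False)
        Vinv = sla.cho_solve((c, low), np.eye(n), check_finite=False)
        W = Vinv @ X
        XtViX = X.T @ W
        XtViX_inv = np.linalg.inv(XtViX)
        P = Vinv - W @ XtViX_inv @ W.T
        Py = P @ y
        yPy = float(y @ Py)
        ll_trace.append(_loglik(c, XtViX, yPy))

        ViPy = [Vm @ Py for Vm in Vmats]
        PViPy = [P @ v for v in ViPy]
        trPVi = np.array([float(np.sum(P * Vm)) for Vm in Vmats])  # symmetric
        yPViPy = np.array([float(Py @ v) for v in ViPy])
        score = -0.5 * (trPVi - yPViPy)
        AI = 0.5 * np.array(
            [[float(ViPy[i] @ PViPy[j]) for j in range(len(comps))]
             for i in range(len(comps))]
        )

        new_theta = None
        ll_now = ll_trace[-1]
        try:
            delta = np.linalg.solve(AI, score)
            # step-halving: accept the (possibly reduced) AI step only if it
            # does not decrease the restricted likelihood
            for _ in range(5):
                proposal = theta + delta
                if np.all(proposal > 0):
                    cand = proposal
                else:
                    free_i = np.flatnonzero(proposal > 0)
                    if not free_i.size:
                        delta = 0.5 * delta
                        continue
                    cand = np.full_like(theta, floor)
                    cand[free_i] = theta[free_i] + delta[free_i]
                    if np.any(cand[free_i] <= 0):
                        delta = 0.5 * delta
                        continue
                if _ll_at(cand) >= ll_now - 1e-8 * max(1.0, abs(ll_now)):
                    new_theta = cand
                    break
                delta = 0.5 * delta
        except np.linalg.LinAlgError:
            pass
        if new_theta is None:
            # EM fixed point; strictly positive, likelihood non-decreasing
            ratio = np.where(trPVi > 0, yPViPy / np.maximum(trPVi, 1e-300), 1.0)
            new_theta = np.maximum(theta * ratio, floor)

        # components pinned at the boundary (≈0) are excluded from the
        # convergence check: their relative change never settles
        boundary = 1e-8 * vary
        free = (theta > boundary) | (new_theta > boundary)
        if free.any():
            rel = np.max(
                np.abs(new_theta[free] - theta[free])
                / np.maximum(np.abs(theta[free]), floor)
            )
        else:
            rel = 0.0
        theta = new_theta
        if rel < tol:
            converged = True
            break

    full = dict(zip(comps, theta))
    return VarianceComponents(
        sigma2_a=float(full.get("a", 0.0)),
        sigma2_w=float(full.get("w", 0.0)),
        sigma2_e=float(full["e"]),
        converged=converged,
        n_rounds=rounds,
        loglik_trace=ll_trace,
    )
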