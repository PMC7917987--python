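"""Animal-model BLUP via Henderson's mixed-model equations, the
multi-trait adjustment model, adjusted phenotypes, yearling-weight
standardization, and a single-trait EM-REML.

The core system, for records y = Xb + Za + e with Var(a) = K * sigma_a^2
and Var(e) = I * sigma_e^2, is

    [X'X   X'Z          ] [b]   [X'y]
    [Z'X   Z'Z + k K^-1 ] [a] = [Z'y],   k = sigma_e^2 / sigma_a^2.

K is the pedigree matrix A for PBLUP and the hybrid matrix H for
single-step GBLUP; only K^-1 is ever supplied. Solutions are obtained by
a dense Cholesky solve at desk scale with a conjugate-gradient fallback
for larger systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from scipy.sparse.linalg import cg as _cg

from .genomic import MarkerPanel, blend_G, build_G, build_H_inverse, center_genotypes
from .pedigree import PedigreeTable, build_A_inverse, extract_A22

DENSE_LIMIT = 6000  # equations; beyond this fall back to conjugate gradients


class ModelError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """Additive and residual variances of a single-trait animal model."""

    sigma_a2: float
    sigma_e2: float

    def __post_init__(self):
        if self.sigma_a2 <= 0 or self.sigma_e2 <= 0:
            raise ModelError("variance components must be positive")

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    @property
    def lam(self) -> float:
        return self.sigma_e2 / self.sigma_a2


@dataclass
class RemlResult(VarianceComponents):
    converged: bool = True
    n_rounds: int = 0
    history: list = field(default_factory=list)


@dataclass
class BlupSolution:
    """Fixed-effect estimates, breeding-value predictions and residuals."""

    b: pd.Series              # fixed-effect estimates, named levels
    a: pd.Series              # EBV/GEBV per animal (pedigree order)
    e: np.ndarray             # residual per record
    y: np.ndarray             # observed records
    record_animals: np.ndarray
    fitted_fixed: np.ndarray  # Xb per record
    method: str = "direct"

    @property
    def mu(self) -> float:
        return float(self.b.iloc[0])


def make_design(
    table: pd.DataFrame, factors=(), covariates=(), intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design with first-level-zero constraint per factor."""
    cols, names = [], []
    n = len(table)
    if intercept:
        cols.append(np.ones(n))
        names.append("mu")
    for f in factors:
        levels = pd.unique(table[f])
        for lev in levels[1:]:  # first level constrained to zero
            cols.append((table[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}:{lev}")
    for c in covariates:
        cols.append(table[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols) if cols else np.zeros((n, 0))
    return X, names


def incidence(record_animals, ped: PedigreeTable) -> sparse.csr_matrix:
    """Record-to-animal incidence matrix Z (n_records x n_animals)."""
    rows = np.arange(len(record_animals))
    cols = np.array([ped.position(a) for a in record_animals], dtype=np.int64)
    data = np.ones(len(record_animals))
    return sparse.csr_matrix((data, (rows, cols)), shape=(len(record_animals), ped.n))


def solve_blup(
    y: np.ndarray,
    X: np.ndarray,
    Z: sparse.spmatrix,
    K_inv,
    vc: VarianceComponents,
    fixed_names: list[str] | None = None,
    animal_ids: np.ndarray | None = None,
    record_animals: np.ndarray | None = None,
    tol: float = 1e-10,
) -> BlupSolution:
    """Solve Henderson's MME for one trait."""
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    nrec = len(y)
    p = X.shape[1]
    if fixed_names is None:
        fixed_names = [f"b{j}" for j in range(p)]
    if p and np.linalg.matrix_rank(X) < p:
        # name the columns involved in the deficiency
        _, R = np.linalg.qr(X)
        dep = [fixed_names[j] for j in range(p) if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ModelError(f"fixed-effect design is rank deficient (confounded: {dep})")
    Z = sparse.csr_matrix(Z)
    q = Z.shape[1]
    Kd = K_inv.toarray() if sparse.issparse(K_inv) else np.asarray(K_inv, dtype=np.float64)
    lam = vc.lam
    neq = p + q
    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = (Z.T @ Z).toarray()
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    method = "direct"
    if neq <= DENSE_LIMIT:
        C = np.empty((neq, neq))
        C[:p, :p] = XtX
        C[:p, p:] = XtZ
        C[p:, :p] = XtZ.T
        C[p:, p:] = ZtZ + lam * Kd
        try:
            sol = linalg.solve(C, rhs, assume_a="pos")
        except np.linalg.LinAlgError:  # pragma: no cover - near-singular fallback
            sol = linalg.lstsq(C, rhs)[0]
    else:  # pragma: no cover - exercised only at large scale
        method = "cg"
        C = sparse.bmat(
            [
                [sparse.csr_matrix(XtX), sparse.csr_matrix(XtZ)],
                [sparse.csr_matrix(XtZ.T), sparse.csr_matrix(ZtZ) + lam * sparse.csr_matrix(Kd)],
            ]
        ).tocsr()
        sol, info = _cg(C, rhs, rtol=tol, maxiter=50 * neq)
        if info != 0:
            raise ModelError(f"conjugate-gradient solver did not converge (info={info})")
    b = pd.Series(sol[:p], index=fixed_names)
    if animal_ids is None:
        animal_ids = np.arange(q)
    a = pd.Series(sol[p:], index=animal_ids)
    fitted_fixed = X @ sol[:p]
    e = y - fitted_fixed - Z @ sol[p:]
    if record_animals is None:
        record_animals = np.asarray(Z.argmax(axis=1)).ravel()
    return BlupSolution(
        b=b, a=a, e=e, y=y, record_animals=np.asarray(record_animals, dtype=object),
        fitted_fixed=fitted_fixed, method=method,
    )


def pblup(
    ped: PedigreeTable,
    y: pd.Series,
    vc: VarianceComponents,
    A_inv: sparse.spmatrix | None = None,
) -> BlupSolution:
    """Pedigree-based single-trait evaluation: y = 1*mu + Za + e, Var(a)=A*sigma_a2."""
    if A_inv is None:
        A_inv = build_A_inverse(ped)
    rec_animals = np.asarray(y.index, dtype=object)
    Z = incidence(rec_animals, ped)
    X = np.ones((len(y), 1))
    return solve_blup(
        y.to_numpy(dtype=float), X, Z, A_inv, vc,
        fixed_names=["mu"], animal_ids=ped.animal, record_animals=rec_animals,
    )


def ssgblup(
    ped: PedigreeTable,
    panel: MarkerPanel,
    y: pd.Series,
    vc: VarianceComponents,
    weights: np.ndarray | None = None,
    g_coef: float = 0.95,
    a_coef: float = 0.05,
) -> BlupSolution:
    """Single-step evaluation: PBLUP model with A^-1 replaced by H^-1."""
    from .genomic import allele_frequencies

    A_inv = build_A_inverse(ped)
    A22 = extract_A22(ped, panel.ids)
    p = allele_frequencies(panel, warn_monomorphic=False)
    M = center_genotypes(panel.genotypes, p)
    G = build_G(M, p, weights)
    Gb = blend_G(G, A22, g_coef, a_coef)
    gidx = np.array([ped.position(a) for a in panel.ids], dtype=np.int64)
    H_inv = build_H_inverse(A_inv, Gb, A22, gidx)
    rec_animals = np.asarray(y.index, dtype=object)
    Z = incidence(rec_animals, ped)
    X = np.ones((len(y), 1))
    return solve_blup(
        y.to_numpy(dtype=float), X, Z, H_inv, vc,
        fixed_names=["mu"], animal_ids=ped.animal, record_animals=rec_animals,
    )


def multitrait_blup(
    ys: dict[str, pd.Series],
    Xs: dict[str, tuple[np.ndarray, list[str]]],
    ped: PedigreeTable,
    G0: np.ndarray,
    R0: np.ndarray,
    A_inv: sparse.spmatrix | None = None,
) -> dict[str, BlupSolution]:
    """Multi-trait animal model with Var(u) = G0 (x) A and Var(e) = R0 (x) I.

    ``ys[t]`` is the record vector of trait t indexed by animal id;
    ``Xs[t]`` its fixed design (rows aligned with ``ys[t]``). Animals may
    miss traits: the residual covariance is sub-blocked to the traits
    observed on each animal.
    """
    traits = list(ys)
    T = len(traits)
    G0 = np.asarray(G0, dtype=float)
    R0 = np.asarray(R0, dtype=float)
    for name, mat in (("G0", G0), ("R0", R0)):
        if mat.shape != (T, T) or not np.allclose(mat, mat.T):
            raise ModelError(f"{name} must be a symmetric {T}x{T} matrix")
        if np.linalg.eigvalsh(mat).min() <= 0:
            raise ModelError(f"{name} is not positive definite")
    if A_inv is None:
        A_inv = build_A_inverse(ped)
    Ainv = A_inv.toarray() if sparse.issparse(A_inv) else np.asarray(A_inv)
    q = ped.n

    # stack records, grouped later by animal for the residual blocks
    recs = []  # (trait_index, animal_pos, y, X_row)
    p_off = [0]
    for k, t in enumerate(traits):
        Xk, _ = Xs[t]
        Xk = np.atleast_2d(np.asarray(Xk, dtype=float))
        if Xk.shape[0] != len(ys[t]):
            raise ModelError(f"design rows for trait {t} do not match records")
        p_off.append(p_off[-1] + Xk.shape[1])
        for r, (animal, val) in enumerate(ys[t].items()):
            recs.append((k, ped.position(animal), float(val), Xk[r]))
    p_tot = p_off[-1]
    n_unk = p_tot + T * q
    LHS = np.zeros((n_unk, n_unk))
    RHS = np.zeros(n_unk)

    def col_of(k, rec):
        _, apos, _, xrow = rec
        fixed_cols = np.arange(p_off[k], p_off[k + 1])
        return fixed_cols, p_tot + k * q + apos, xrow

    by_animal: dict[int, list] = {}
    for rec in recs:
        by_animal.setdefault(rec[1], []).append(rec)
    for apos, rows in by_animal.items():
        obs = [r[0] for r in rows]
        Rinv = np.linalg.inv(R0[np.ix_(obs, obs)])
        cols, xparts, yvals = [], [], []
        for r in rows:
            fc, uc, xrow = col_of(r[0], r)
            cols.append((fc, uc, xrow))
            yvals.append(r[2])
        for i, (fci, uci, xi) in enumerate(cols):
            for j, (fcj, ucj, xj) in enumerate(cols):
                w = Rinv[i, j]
                LHS[np.ix_(fci, fcj)] += w * np.outer(xi, xj)
                LHS[fci, ucj] += w * xi
                LHS[ucj, fci] += w * xi
                LHS[uci, ucj] += w
            contrib = sum(Rinv[i, j] * yvals[j] for j in range(len(cols)))
            RHS[fci] += contrib * xi
            RHS[uci] += contrib
    G0_inv = np.linalg.inv(G0)
    LHS[p_tot:, p_tot:] += np.kron(G0_inv, Ainv)
    sol = linalg.lstsq(LHS, RHS)[0]

    out = {}
    for k, t in enumerate(traits):
        Xk, namesk = Xs[t]
        Xk = np.atleast_2d(np.asarray(Xk, dtype=float))
        bk = sol[p_off[k]:p_off[k + 1]]
        uk = sol[p_tot + k * q: p_tot + (k + 1) * q]
        rec_animals = np.asarray(ys[t].index, dtype=object)
        yk = ys[t].to_numpy(dtype=float)
        fitted = Xk @ bk
        apos = np.array([ped.position(a) for a in rec_animals])
        out[t] = BlupSolution(
            b=pd.Series(bk, index=namesk),
            a=pd.Series(uk, index=ped.animal),
            e=yk - fitted - uk[apos],
            y=yk,
            record_animals=rec_animals,
            fitted_fixed=fitted,
            method="multitrait",
        )
    return out


def adjust_phenotypes(fit: BlupSolution) -> pd.Series:
    """Adjusted phenotype per recorded animal: EBV + residual = y - Xb."""
    vals = fit.y - fit.fitted_fixed
    return pd.Series(vals, index=fit.record_animals)


def yearling_weight(w_t, w_t1, t, t1):
    """Standardized 365-day weight from two weighings:
    YW = ((W_t - W_t1)/(t - t1)) * (365 - t1) + W_t1 (kg)."""
    w_t, w_t1 = np.asarray(w_t, dtype=float), np.asarray(w_t1, dtype=float)
    t, t1 = np.asarray(t, dtype=float), np.asarray(t1, dtype=float)
    if np.any(t <= t1) or np.any(t1 <= 0):
        raise ModelError("weighing days must satisfy t > t1 > 0")
    if np.any(w_t <= 0) or np.any(w_t1 <= 0):
        raise ModelError("weights must be positive")
    out = (w_t - w_t1) / (t - t1) * (365.0 - t1) + w_t1
    return float(out) if out.ndim == 0 else out


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z: sparse.spmatrix,
    A_inv,
    max_rounds: int = 500,
    rtol: float = 1e-6,
    init: tuple[float, float] | None = None,
) -> RemlResult:
    """Single-trait EM-REML for (sigma_a2, sigma_e2).

    Classic Henderson EM updates on the MME, with fixed effects absorbed
    so each round is O(q^2) after a one-time generalized
    eigendecomposition of (Z'SZ, A^-1), S the projection off the fixed
    effects: C_aa = (Z'SZ + k A^-1)^-1 diagonalizes simultaneously.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = sparse.csr_matrix(Z)
    n, p = X.shape
    q = Z.shape[1]
    Ainv = A_inv.toarray() if sparse.issparse(A_inv) else np.asarray(A_inv, dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    Zd = Z.toarray()
    SZ = Zd - X @ (XtX_inv @ (X.T @ Zd))
    ZSZ = Zd.T @ SZ
    ZSy = SZ.T @ y
    w, V = linalg.eigh(ZSZ, Ainv)  # ZSZ V = Ainv V diag(w), V' Ainv V = I
    c = V.T @ ZSy
    vy = float(np.var(y))
    sa2, se2 = init if init is not None else (vy / 2, vy / 2)
    hist = [(sa2, se2)]
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        lam = se2 / sa2
        ahat = V @ (c / (w + lam))
        tr = float(np.sum(1.0 / (w + lam)))
        sa2_new = (ahat @ (Ainv @ ahat) + tr * se2) / q
        bhat = XtX_inv @ (X.T @ (y - Zd @ ahat))
        resid = y - X @ bhat - Zd @ ahat
        se2_new = float(y @ resid) / (n - p)
        rel = max(abs(sa2_new - sa2) / sa2, abs(se2_new - se2) / se2)
        sa2, se2 = float(sa2_new), float(se2_new)
        hist.append((sa2, se2))
        if rel < rtol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM-REML did not converge in {max_rounds} rounds; returning last iterate",
            stacklevel=2,
        )
    return RemlResult(
        sigma_a2=sa2, sigma_e2=se2, converged=converged, n_rounds=rounds, history=hist
    )
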