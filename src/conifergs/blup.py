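"""Pedigree BLUP via Henderson's mixed-model equations.

Model: y = 1*mu + Z_a a + Z_d d + e with var(a) = A sigma2_a (numerator
relationship matrix from the pedigree, tabular method), var(d) = D sigma2_d
and var(e) = I sigma2_e. The non-additive effect d is a clone-level
deviation shared by the ramets of a clone, so D is the identity over clones
and Z_d maps records to clones. Variance components are fixed at the
simulation truth (no REML). Per-clone accuracy comes from the prediction
error variance: r_i = sqrt(1 - PEV_i / (A_ii sigma2_a)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

__all__ = [
    "EvaluationResult",
    "MixedModelSpec",
    "build_A",
    "build_A_from_arrays",
    "solve_mme",
    "ebv_accuracy_summary",
]


@dataclass
class EvaluationResult:
    """Per-clone predicted additive values and their accuracies."""

    clone_ids: np.ndarray
    ebv: np.ndarray
    accuracy_r: np.ndarray | None = None
    method: str = "BLUP"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": self.clone_ids,
                "ebv": self.ebv,
                "accuracy_r": np.nan if self.accuracy_r is None else self.accuracy_r,
                "method": self.method,
            }
        )


def build_A_from_arrays(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``sire``/``dam`` hold row indices of each individual's parents, or -1
    for an unknown (base) parent; parents must precede offspring. The full
    recursion is used, so inbreeding accumulates on the diagonal.
    """
    n = len(sire)
    if len(dam) != n:
        raise ValueError("sire and dam arrays differ in length")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = int(sire[i]), int(dam[i])
        if s >= i or d >= i:
            raise ValueError(f"pedigree not sorted: parent of {i} does not precede it")
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def build_A(pedigree: pd.DataFrame) -> np.ndarray:
    """Tabular-method A from a pedigree table with columns id, sire, dam.

    Unknown parents are encoded as NaN, 0 or -1. Rows must list parents
    before their offspring; a parent id that never appears as an individual
    is treated as unknown base. Cyclic or unordered pedigrees raise.
    """
    ids = pedigree["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    index = {v: i for i, v in enumerate(ids)}

    def code(col):
        out = np.full(len(ids), -1, dtype=np.int64)
        for i, v in enumerate(pedigree[col].to_numpy()):
            if pd.isna(v) or v in (0, -1):
                continue
            if v in index:
                out[i] = index[v]
        return out

    return build_A_from_arrays(code("sire"), code("dam"))


@dataclass
class MixedModelSpec:
    """Dense specification of one mixed-model instance."""

    y: np.ndarray
    Z_a: np.ndarray  # records x n_a incidence
    Z_d: np.ndarray  # records x n_d incidence
    A: np.ndarray
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    D: np.ndarray | None = None  # defaults to identity over d-levels


def _accuracy_from_pev(pev: np.ndarray, a_diag: np.ndarray, sigma2_a: float) -> np.ndarray:
    rel = 1.0 - pev / (a_diag * sigma2_a)
    return np.sqrt(np.clip(rel, 0.0, 1.0))


def solve_mme(spec: MixedModelSpec, with_accuracy: bool = True) -> EvaluationResult:
    """Solve Henderson's MME for (mu, a, d); EBV = a-hat.

    Raises a ``LinAlgError`` naming the confounded blocks if the coefficient
    matrix is singular.
    """
    y = np.asarray(spec.y, dtype=float)
    Za = np.asarray(spec.Z_a, dtype=float)
    Zd = np.asarray(spec.Z_d, dtype=float)
    n_a, n_d = Za.shape[1], Zd.shape[1]
    lam_a = spec.sigma2_e / spec.sigma2_a
    lam_d = spec.sigma2_e / spec.sigma2_d
    Ainv = sla.inv(spec.A)
    Dinv = sla.inv(spec.D) if spec.D is not None else np.eye(n_d)
    X = np.ones((len(y), 1))
    W = np.hstack([X, Za, Zd])
    C = W.T @ W
    C[1 : 1 + n_a, 1 : 1 + n_a] += lam_a * Ainv
    C[1 + n_a :, 1 + n_a :] += lam_d * Dinv
    rhs = W.T @ y
    try:
        cf = sla.cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular mixed-model equations: mean, additive and non-additive "
            "blocks are confounded (check incidence matrices)"
        ) from exc
    sol = sla.cho_solve(cf, rhs)
    a_hat = sol[1 : 1 + n_a]
    acc = None
    if with_accuracy:
        Cinv_diag = _chol_inverse_diag(cf[0])
        pev = Cinv_diag[1 : 1 + n_a] * spec.sigma2_e
        acc = _accuracy_from_pev(pev, np.diag(spec.A), spec.sigma2_a)
    return EvaluationResult(
        clone_ids=np.arange(n_a), ebv=a_hat, accuracy_r=acc, method="BLUP"
    )


def _chol_inverse_diag(L: np.ndarray) -> np.ndarray:
    """Diagonal of C^-1 from its (lower) Cholesky factor."""
    inv, info = sla.lapack.dpotri(L, lower=True)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed on MME coefficient matrix")
    return np.diag(inv).copy()


def solve_collapsed_clone_model(
    y_clone_mean: np.ndarray,
    n_records: np.ndarray,
    A: np.ndarray,
    sigma2_a: float,
    sigma2_d: float,
    sigma2_e: float,
    with_accuracy: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Exact clone-mean reduction of the clonal mixed model.

    With D = I and Z_d = Z_a, a clone's non-additive deviation enters only
    its own records, so on clone means it is indistinguishable from
    residual: y_bar_i = mu + a_i + eps_i with var(eps_i) = sigma2_d +
    sigma2_e / n_i. The resulting MME (1 + n_clones equations) yields the
    same EBVs and PEV-based accuracies as the full ramet-level system.
    """
    y = np.asarray(y_clone_mean, dtype=float)
    n_rec = np.asarray(n_records, dtype=float)
    n = len(y)
    r_inv = 1.0 / (sigma2_d + sigma2_e / n_rec)  # per-clone precision
    C = np.zeros((n + 1, n + 1))
    C[0, 0] = r_inv.sum()
    C[0, 1:] = r_inv
    C[1:, 0] = r_inv
    C[1:, 1:] = sla.inv(A) / sigma2_a
    idx = np.arange(n)
    C[1 + idx, 1 + idx] += r_inv
    rhs = np.concatenate([[(r_inv * y).sum()], r_inv * y])
    cf = sla.cho_factor(C, lower=True, check_finite=False)
    sol = sla.cho_solve(cf, rhs, check_finite=False)
    ebv = sol[1:]
    acc = None
    if with_accuracy:
        pev = _chol_inverse_diag(cf[0])[1:]
        acc = _accuracy_from_pev(pev, np.diag(A), sigma2_a)
    return ebv, acc


def ebv_accuracy_summary(ebv: np.ndarray | EvaluationResult, tbv: np.ndarray) -> float:
    """Realised accuracy: Pearson correlation of (G)EBV with true breeding value."""
    if isinstance(ebv, EvaluationResult):
        ebv = ebv.ebv
    ebv = np.asarray(ebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if ebv.std() == 0 or tbv.std() == 0:
        raise ValueError("zero-variance predictions: realised accuracy undefined")
    return float(np.corrcoef(ebv, tbv)[0, 1])
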