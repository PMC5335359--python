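"""Exploratory factor analysis for sample clustering.

Samples (arrays) are projected into a low-dimensional factor space computed
over a chosen gene subset — all DEGs, ligand/receptor DEGs, or M1/M2
signature DEGs — so that related macrophage/SC populations cluster together.
The retained factor count comes from Velicer's minimum-average-partial (MAP)
procedure; loadings are fitted by maximum likelihood (EM on the sample
correlation matrix), rotated by varimax, and samples get regression
(Thomson) factor scores.

Note on orientation: here the *genes* are the variables and the *samples*
are the observations being scored, matching the cited clustering workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, LRCatalog
from .errors import ConfigError, ConvergenceError, DataError

HEYWOOD_FLOOR = 0.005


# -- feature selection ---------------------------------------------------------

def select_features(
    matrix: ExpressionMatrix,
    mode: str,
    deg_sets: dict[str, set[str]] | set[str],
    catalog: LRCatalog | None = None,
    signatures: dict[str, set[str]] | None = None,
) -> ExpressionMatrix:
    """Restrict rows to the requested gene subset.

    mode: "all_degs" (union of the supplied DEG sets), "lr_degs" (DEGs that
    are catalog ligands or receptors), or "signature_degs" (DEGs in any
    supplied signature set).
    """
    degs: set[str] = set()
    if isinstance(deg_sets, dict):
        for s in deg_sets.values():
            degs |= set(s)
    else:
        degs = set(deg_sets)
    degs = {g.upper() for g in degs}
    if mode == "all_degs":
        wanted = degs
    elif mode == "lr_degs":
        if catalog is None:
            raise ConfigError("lr_degs mode needs a catalog")
        wanted = degs & (catalog.ligand_set | catalog.receptor_set)
    elif mode == "signature_degs":
        if not signatures:
            raise ConfigError("signature_degs mode needs signature sets")
        sig_union = {g.upper() for s in signatures.values() for g in s}
        wanted = degs & sig_union
    else:
        raise ConfigError(f"unknown feature mode {mode!r}")
    reduced = matrix.subset_genes(wanted)
    if reduced.values.shape[0] == 0:
        raise DataError(f"feature mode {mode!r} selected no genes present in the matrix")
    return reduced


# -- Velicer's minimum average partial -----------------------------------------

@dataclass(frozen=True)
class MAPResult:
    m_star: int
    criterion: tuple[float, ...]  # criterion[m] for m = 0..max_m

    def as_series(self) -> pd.Series:
        return pd.Series(self.criterion, index=range(len(self.criterion)), name="avg_sq_partial")


def velicer_map(corr: np.ndarray, max_m: int | None = None, power: int = 2) -> MAPResult:
    """Velicer's MAP factor-retention criterion.

    For m = 0..max_m, partial out the first m principal components
    (C_m = C - A_m A_m' with A_m the component loadings), convert the
    residual matrix to partial correlations, and average the off-diagonal
    entries raised to `power` (2 for the original criterion, 4 for the
    revision). The retained count m* is the argmin (smallest m on ties);
    m* = 0 means the matrix carries no common variance worth factoring.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise DataError("correlation matrix must be square")
    if power not in (2, 4):
        raise ConfigError("power must be 2 or 4")
    p = corr.shape[0]
    if max_m is None:
        max_m = min(8, p - 1)
    max_m = min(max_m, p - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    off = ~np.eye(p, dtype=bool)
    crit: list[float] = []
    for m in range(max_m + 1):
        if m == 0:
            partial = corr
        else:
            lam = np.clip(eigvals[:m], 0.0, None)
            A = eigvecs[:, :m] * np.sqrt(lam)[None, :]
            resid = corr - A @ A.T
            d = np.diag(resid).copy()
            if np.any(d <= 1e-12):
                break  # components exhaust a variable: criterion undefined past here
            denom = np.sqrt(np.outer(d, d))
            partial = resid / denom
        # squared partials are <= 1 analytically; clip float overshoot
        crit.append(float(min(1.0, np.mean(np.abs(partial[off]) ** power))))
    m_star = int(np.argmin(crit))
    return MAPResult(m_star=m_star, criterion=tuple(crit))


# -- maximum-likelihood factor analysis ----------------------------------------

@dataclass
class FactorModel:
    loadings: pd.DataFrame  # variables x m
    uniquenesses: pd.Series  # variable -> (0, 1]
    rotation: str
    log_likelihood: float
    n_iter: int
    converged: bool

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    def model_correlation(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        return L @ L.T + np.diag(self.uniquenesses.to_numpy())


def _gaussian_loglik(S: np.ndarray, sigma: np.ndarray) -> float:
    """Per-observation Gaussian log-likelihood (up to an additive constant)."""
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdet + float(np.trace(np.linalg.solve(sigma, S))))


def ml_factor_fit(
    data: np.ndarray | pd.DataFrame,
    m: int,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> FactorModel:
    """Fit loadings and uniquenesses by EM on the sample correlation matrix.

    `data` is observations x variables. The start point truncates the eigen
    decomposition of the correlation matrix; EM iterates the standard
    conditional-moment updates and stops when the per-observation
    log-likelihood improves by less than `tol`. Uniquenesses hitting the
    Heywood boundary are clamped at 0.005 with a warning. The likelihood is
    asserted non-decreasing every iteration.
    """
    frame = pd.DataFrame(data)
    n, p = frame.shape
    if m < 1:
        raise ConfigError("m must be >= 1")
    if n <= m:
        raise DataError(f"need more observations than factors (n={n}, m={m})")
    sd = frame.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = list(frame.columns[sd <= 0])[:5]
        raise DataError(f"zero-variance variables cannot be factored: {bad}")
    S = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
    S = np.atleast_2d(S)

    # eigen-based start: uniquenesses from squared multiple correlations,
    # loadings from the excess (>1) eigenvalues of the rescaled correlation
    with np.errstate(all="ignore"):
        inv_diag = np.diag(np.linalg.pinv(S))
    psi = np.clip(np.where(np.isfinite(inv_diag) & (inv_diag > 0),
                           1.0 / inv_diag, 0.5), 0.05, 1.0)
    phi = S / np.sqrt(np.outer(psi, psi))
    eigvals, eigvecs = np.linalg.eigh(phi)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    L = (np.sqrt(psi)[:, None]
         * eigvecs[:, :m] * np.sqrt(np.clip(eigvals[:m] - 1.0, 0.0, None))[None, :])
    psi = np.clip(np.diag(S - L @ L.T), HEYWOOD_FLOOR, 1.0)

    ll_old = _gaussian_loglik(S, L @ L.T + np.diag(psi))
    heywood = False
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        sigma = L @ L.T + np.diag(psi)
        beta = np.linalg.solve(sigma, L).T  # m x p
        Ezz = np.eye(m) - beta @ L + beta @ S @ beta.T
        Cxz = S @ beta.T  # p x m
        L = Cxz @ np.linalg.inv(Ezz)
        psi = np.diag(S - L @ (beta @ S))
        if np.any(psi < HEYWOOD_FLOOR):
            heywood = True
            psi = np.clip(psi, HEYWOOD_FLOOR, None)
        psi = np.minimum(psi, 1.0)
        ll_new = _gaussian_loglik(S, L @ L.T + np.diag(psi))
        if ll_new < ll_old - 1e-9 and not heywood:
            raise ConvergenceError("EM log-likelihood decreased", residual=ll_old - ll_new)
        if abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new
    if heywood:
        warnings.warn("Heywood case: uniqueness clamped at 0.005")
    var_names = list(frame.columns)
    return FactorModel(
        loadings=pd.DataFrame(L, index=var_names, columns=[f"F{i+1}" for i in range(m)]),
        uniquenesses=pd.Series(psi, index=var_names),
        rotation="none",
        log_likelihood=float(ll_old),
        n_iter=n_iter,
        converged=converged,
    )


# -- varimax rotation ----------------------------------------------------------

def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


def varimax_rotate(loadings: pd.DataFrame | np.ndarray, tol: float = 1e-12,
                   max_iter: int = 1000) -> tuple[pd.DataFrame, np.ndarray]:
    """Orthogonal varimax rotation with deterministic column signs.

    Returns (rotated loadings, rotation matrix R with R'R = I). For m = 1 the
    rotation is the identity (up to the sign convention). Each column's sign
    is fixed so its largest-magnitude loading is positive.
    """
    frame = pd.DataFrame(loadings)
    L = frame.to_numpy(dtype=float)
    p, m = L.shape
    R = np.eye(m)
    if m >= 2:
        d = 0.0
        for _ in range(max_iter):
            Lr = L @ R
            u, s, vt = np.linalg.svd(
                L.T @ (Lr**3 - (1.0 / p) * Lr @ np.diag(np.diag(Lr.T @ Lr)))
            )
            R = u @ vt
            d_new = float(s.sum())
            if d_new <= d * (1.0 + tol):
                break
            d = d_new
    rotated = L @ R
    signs = np.ones(m)
    for j in range(m):
        k = int(np.argmax(np.abs(rotated[:, j])))
        if rotated[k, j] < 0:
            signs[j] = -1.0
    rotated = rotated * signs[None, :]
    R = R * signs[None, :]
    return pd.DataFrame(rotated, index=frame.index, columns=frame.columns), R


def rotate_model(model: FactorModel) -> FactorModel:
    rotated, _ = varimax_rotate(model.loadings)
    return FactorModel(
        loadings=rotated,
        uniquenesses=model.uniquenesses.copy(),
        rotation="varimax",
        log_likelihood=model.log_likelihood,
        n_iter=model.n_iter,
        converged=model.converged,
    )


# -- factor scores -------------------------------------------------------------

def factor_scores(data: np.ndarray | pd.DataFrame, model: FactorModel) -> pd.DataFrame:
    """Regression (Thomson) factor scores for each observation.

    scores = Z Psi^-1 Lambda (Lambda' Psi^-1 Lambda + I)^-1 with Z the
    column-standardized data.
    """
    frame = pd.DataFrame(data)
    if list(frame.columns) != list(model.loadings.index):
        frame = frame[list(model.loadings.index)]
    sd = frame.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise DataError("zero-variance variables cannot be scored")
    Z = (frame - frame.mean(axis=0)) / sd
    L = model.loadings.to_numpy()
    psi_inv = 1.0 / model.uniquenesses.to_numpy()
    A = L * psi_inv[:, None]  # Psi^-1 Lambda
    M = L.T @ A + np.eye(model.m)
    try:
        W = A @ np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise DataError(f"singular score system: {exc}") from exc
    scores = Z.to_numpy(dtype=float) @ W
    return pd.DataFrame(scores, index=frame.index, columns=list(model.loadings.columns))


def efa_cluster(
    matrix: ExpressionMatrix,
    mode: str,
    deg_sets,
    catalog: LRCatalog | None = None,
    signatures: dict[str, set[str]] | None = None,
    max_m: int | None = None,
    min_factors: int = 1,
) -> tuple[MAPResult, FactorModel, pd.DataFrame]:
    """MAP + ML fit + varimax + scores over a feature subset, in one call.

    Variables are the selected genes; observations are the samples. Genes
    with zero variance across samples are dropped up front.
    """
    reduced = select_features(matrix, mode, deg_sets, catalog, signatures)
    data = reduced.values.T  # samples x genes
    sd = data.std(axis=0, ddof=1)
    data = data.loc[:, sd > 0]
    if data.shape[1] < 2:
        raise DataError("need >=2 informative genes for factor analysis")
    corr = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    map_result = velicer_map(corr, max_m=max_m)
    m = max(map_result.m_star, min_factors)
    model = rotate_model(ml_factor_fit(data, m))
    scores = factor_scores(data, model)
    return map_result, model, scores
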