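"""Matrix hygiene between raw input and statistics.

Three operations: quantile normalization (forcing identical per-column value
distributions), parametric empirical-Bayes batch adjustment of the ComBat
family, and filtering to genes with strong (one-to-one, flagged) orthologs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .errors import ConvergenceError, DataError

TRUTHY_FLAGS = {"1", "true", "yes", "y", "t"}


# -- quantile normalization ----------------------------------------------------

def quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns of a DataFrame.

    Every column acquires the reference distribution formed by the row means
    of the column-sorted input. Ties within a column receive the mean of the
    destination values their ranks span.
    """
    if values.shape[1] == 0 or values.shape[0] == 0:
        raise DataError("cannot quantile-normalize an empty matrix")
    arr = values.to_numpy(dtype=float)
    n, m = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        dest = np.empty(n)
        dest[order] = reference
        # ties: average the destination values over each tied group
        out[:, j] = pd.Series(dest).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return ExpressionMatrix(quantile_normalize_frame(matrix.values), matrix.sample_meta.copy())


# -- ComBat-style batch adjustment ---------------------------------------------

def _design_matrix(batches: pd.Series, preserve: pd.Series | None) -> tuple[np.ndarray, np.ndarray]:
    """Batch indicator block plus (optionally) group covariate block."""
    batch_dummies = pd.get_dummies(batches).to_numpy(dtype=float)
    if preserve is None:
        return batch_dummies, np.zeros((len(batches), 0))
    group_dummies = pd.get_dummies(preserve, drop_first=True).to_numpy(dtype=float)
    return batch_dummies, group_dummies


def combat_adjust(
    matrix: ExpressionMatrix,
    batch_labels=None,
    preserve=None,
    max_iter: int = 1000,
    conv: float = 1e-6,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene and batch, an additive shift (normal prior across genes) and a
    multiplicative residual scale (inverse-gamma prior) are estimated on
    standardized data, shrunk toward method-of-moments hyperpriors by the
    usual iterative conditional solution, and removed. Group-mean structure
    named in `preserve` is protected through the design matrix. Each gene is
    finally recentered to its original grand mean, so the adjustment is pure
    batch removal.

    Parameters
    ----------
    batch_labels
        Per-sample batch labels; defaults to `sample_meta["batch"]`.
    preserve
        Per-sample biological group labels to protect (default:
        `sample_meta["group"]`); pass `False` to protect nothing.
    """
    meta = matrix.sample_meta.loc[list(matrix.samples)]
    batches = pd.Series(batch_labels, index=matrix.samples) if batch_labels is not None \
        else meta["batch"]
    batches = batches.astype(str)
    if preserve is False:
        groups = None
    elif preserve is None:
        groups = meta["group"]
    else:
        groups = pd.Series(preserve, index=matrix.samples)

    counts = batches.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise DataError(f"every batch needs >=2 samples; too small: {small}")
    if len(counts) == 1:
        return matrix.copy()
    if groups is not None:
        for b in counts.index:
            if groups[batches == b].nunique() == 1 and groups.nunique() > 1:
                raise DataError(f"batch {b!r} is confounded with a single group")

    Y = matrix.values.to_numpy(dtype=float)
    n_genes, n = Y.shape
    batch_ids = list(counts.sort_index().index)
    batchmod, covmod = _design_matrix(batches, groups)
    # order batch columns to match batch_ids
    batchmod = pd.get_dummies(batches)[batch_ids].to_numpy(dtype=float)
    design = np.hstack([batchmod, covmod])

    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # (p, genes)
    n_batch = len(batch_ids)
    batch_sizes = np.array([counts[b] for b in batch_ids], dtype=float)
    grand_mean = (batch_sizes / n) @ beta[:n_batch, :]  # per gene
    resid = Y.T - design @ beta
    var_pooled = (resid**2).mean(axis=0)  # per gene, denominator n
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_design = design.copy()
    stand_design[:, :n_batch] = 0.0
    stand_mean = grand_mean[None, :] + stand_design @ beta  # (n, genes)
    s_data = (Y.T - stand_mean) / np.sqrt(var_pooled)[None, :]

    batch_masks = [np.asarray(batches == b) for b in batch_ids]
    gamma_star = np.empty((n_batch, n_genes))
    delta_star = np.empty((n_batch, n_genes))
    for bi, mask in enumerate(batch_masks):
        sb = s_data[mask]
        nb = sb.shape[0]
        gamma_hat = sb.mean(axis=0)
        delta_hat = sb.var(axis=0, ddof=1)
        gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        if s2 <= 0:
            a_prior, b_prior = 2.0, m if m > 0 else 1.0  # flat-ish fallback
        else:
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
        g_old, d_old = gamma_hat.copy(), delta_hat.copy()
        for _ in range(max_iter):
            g_new = (nb * tau2 * gamma_hat + d_old * gamma_bar) / (nb * tau2 + d_old)
            sum2 = ((sb - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior) / (nb / 2.0 + a_prior - 1.0)
            change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        else:
            raise ConvergenceError("empirical-Bayes batch solution did not converge",
                                   residual=float(change))
        gamma_star[bi], delta_star[bi] = g_old, np.maximum(d_old, 1e-12)

    adjusted = s_data.copy()
    for bi, mask in enumerate(batch_masks):
        adjusted[mask] = (s_data[mask] - gamma_star[bi][None, :]) / np.sqrt(delta_star[bi])[None, :]
    adjusted = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean
    out = adjusted.T
    # pure batch removal: restore each gene's original grand mean
    out += (Y.mean(axis=1) - out.mean(axis=1))[:, None]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.sample_meta.copy())


# -- ortholog filtering --------------------------------------------------------

def one_to_one_map(ortholog_table: pd.DataFrame) -> dict[str, str]:
    """Strong-ortholog mapping: flagged rows with an unambiguous target.

    Rows with an unset support flag are ignored; among flagged rows, a source
    symbol participating in more than one mapping is dropped entirely. Two
    sources may legitimately share a target (paralogs collapsing onto one
    ortholog), which downstream deduplication handles.
    """
    required = {"source_symbol", "target_symbol", "support_flag"}
    missing = required - set(ortholog_table.columns)
    if missing:
        raise DataError(f"ortholog table missing columns: {sorted(missing)}")
    flagged = ortholog_table[
        ortholog_table["support_flag"].astype(str).str.strip().str.lower().isin(TRUTHY_FLAGS)
    ]
    src = flagged["source_symbol"].astype(str).str.strip().str.upper()
    tgt = flagged["target_symbol"].astype(str).str.strip().str.upper()
    pairs = pd.DataFrame({"src": src, "tgt": tgt}).drop_duplicates()
    src_counts = pairs["src"].value_counts()
    keep = pairs[pairs["src"].map(src_counts) == 1]
    return dict(zip(keep["src"], keep["tgt"]))


def filter_orthologs(matrix: ExpressionMatrix, ortholog_table: pd.DataFrame) -> ExpressionMatrix:
    """Retain only genes with a strong (flagged one-to-one) ortholog, order kept."""
    mapping = one_to_one_map(ortholog_table)
    keep = [g for g in matrix.genes if str(g).upper() in mapping]
    return ExpressionMatrix(matrix.values.loc[keep], matrix.sample_meta.copy())
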