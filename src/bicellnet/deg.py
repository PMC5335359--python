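"""Empirical-Bayes moderated-t differential expression between two groups.

The model is the standard microarray one: per gene a two-sample contrast on
log2 intensities with pooled variance s^2 on df degrees of freedom; the s^2
are assumed to follow a scaled F around a common prior variance s0^2 with d0
prior degrees of freedom. (d0, s0^2) are fitted by the method of moments on
log variances (digamma/trigamma inversion), the posterior variance

    s2_post = (d0 * s0^2 + df * s^2) / (d0 + df)

replaces s^2 in the t statistic, and p-values use d0 + df degrees of freedom.
DEGs are called by the joint fold-change / FDR rule (fold > 2x strict,
BH q < 0.05 by default; the injury-timecourse comparison uses fold > 3x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ExpressionMatrix
from .errors import DataError


@dataclass(frozen=True)
class ModerationParams:
    """Prior degrees of freedom and prior variance of the variance model.

    ``d0 = math.inf`` is the sentinel for "log-variances are no more spread
    than sampling noise": all genes share s0_sq.
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise DataError("d0 must be positive (math.inf allowed)")
        if not (self.s0_sq > 0):
            raise DataError("s0_sq must be positive")


def contrast_stats(matrix: ExpressionMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-gene means, log2 fold change (a minus b), pooled variance and df.

    `group_a` / `group_b` are lists of sample IDs, or ``(cell_type, group)``
    tuples resolved against the sample metadata.
    """
    cols_a = matrix.samples_where(*group_a) if isinstance(group_a, tuple) else list(group_a)
    cols_b = matrix.samples_where(*group_b) if isinstance(group_b, tuple) else list(group_b)
    na, nb = len(cols_a), len(cols_b)
    if na < 2 or nb < 2:
        raise DataError(f"both groups need >=2 samples (got {na} and {nb})")
    A = matrix.values[cols_a].to_numpy(dtype=float)
    B = matrix.values[cols_b].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ss_a = ((A - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((B - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = (ss_a + ss_b) / df
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": mean_a - mean_b,
            "s2": s2,
            "df": df,
            "n_a": na,
            "n_b": nb,
        },
        index=matrix.genes,
    )


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex target)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_moderation(s2, df, min_genes: int = 10) -> ModerationParams:
    """Method-of-moments fit of (d0, s0^2) on log sample variances.

    With z = log(s^2), E[z] = log(s0^2) + psi(df/2) - log(df/2) - psi(d0/2)
    + log(d0/2) and Var[z] = psi'(df/2) + psi'(d0/2); the excess of the
    empirical variance of z over psi'(df/2) identifies d0. When the excess is
    non-positive, d0 is infinite and every gene shares s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < min_genes:
        raise DataError(f"need >= {min_genes} genes with positive variance (got {s2.size})")
    df = float(df)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return ModerationParams(d0=math.inf, s0_sq=math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderated_t(statistics: pd.DataFrame, params: ModerationParams) -> pd.DataFrame:
    """Moderated t and two-sided p per gene; d0=inf and d0->0 recover the
    z-like and ordinary pooled-t limits."""
    df = statistics["df"].to_numpy(dtype=float)
    s2 = statistics["s2"].to_numpy(dtype=float)
    if math.isinf(params.d0):
        s2_post = np.full_like(s2, params.s0_sq)
        dof = np.full_like(df, np.inf)
    else:
        s2_post = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
        dof = df + params.d0
    se = np.sqrt(s2_post * (1.0 / statistics["n_a"] + 1.0 / statistics["n_b"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = statistics["log2fc"].to_numpy(dtype=float) / se
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)
    p = np.where(
        np.isinf(dof),
        2.0 * stats.norm.sf(np.abs(t_mod)),
        2.0 * stats.t.sf(np.abs(t_mod), np.where(np.isinf(dof), 1.0, dof)),
    )
    out = statistics.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["p"] = np.clip(p, 0.0, 1.0)
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_i = min over j with p_(j) >= p_(i) of m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def deg_table(matrix: ExpressionMatrix, group_a, group_b) -> pd.DataFrame:
    """Full moderated-t table for one two-group contrast."""
    statistics = contrast_stats(matrix, group_a, group_b)
    params = fit_moderation(statistics["s2"], statistics["df"].iloc[0])
    table = moderated_t(statistics, params)
    table["q"] = bh_fdr(table["p"])
    table["fold"] = 2.0 ** table["log2fc"].abs()
    table.attrs["moderation"] = params
    return table


def call_degs(table: pd.DataFrame, fold_cut: float = 2.0, q_cut: float = 0.05) -> pd.DataFrame:
    """Call DEGs: 2^|log2fc| strictly above fold_cut AND q below q_cut."""
    fold = 2.0 ** table["log2fc"].abs()
    called = (fold > fold_cut) & (table["q"] < q_cut)
    out = table.copy()
    out["fold"] = fold
    out["called"] = called
    out["direction"] = np.sign(table["log2fc"]).astype(int)
    return out


def called_genes(table: pd.DataFrame) -> set[str]:
    return set(table.index[table["called"]])


def write_deg_table(table: pd.DataFrame, path) -> None:
    cols = ["mean_a", "mean_b", "log2fc", "fold", "s2", "t_mod", "p", "q"]
    extra = [c for c in ("called", "direction") if c in table.columns]
    table[cols + extra].to_csv(path, sep="\t", index_label="gene", float_format="%.6g")
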