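"""Signature mapping, hypergeometric gene-set enrichment, injury overlap.

Signature sets (M1/M2 macrophage polarization programs, interferon-regulated
genes) arrive as GMT files. Enrichment of a DEG query against a collection
of sets uses the exact hypergeometric upper tail with BH adjustment across
sets (q < 0.05 by default). The injury-timecourse comparison counts the
overlap of tumor DEGs with per-day nerve-injury DEG sets and reports the
maximally overlapping day (raw counts decide; Jaccard and the
hypergeometric p ride along).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_fdr
from .errors import DataError


@dataclass(frozen=True)
class SignatureSet:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self):
        if not self.genes:
            raise DataError(f"signature set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


def signatures_from_gmt(sets: dict[str, set[str]], source: str = "gmt") -> list[SignatureSet]:
    return [SignatureSet(name, frozenset(genes), source) for name, genes in sorted(sets.items())]


def signature_table(deg_table: pd.DataFrame, signatures: list[SignatureSet]) -> pd.DataFrame:
    """Rows (gene, signature, log2fc, fold, direction) for called DEGs that are
    signature members; a gene in two signatures yields two rows."""
    if deg_table.empty:
        raise DataError("empty DEG table")
    if not signatures:
        raise DataError("no signature sets supplied")
    called = deg_table[deg_table["called"]] if "called" in deg_table.columns else deg_table
    rows = []
    for sig in signatures:
        for gene in sorted(set(called.index) & sig.genes):
            log2fc = float(called.loc[gene, "log2fc"])
            rows.append(
                {
                    "gene": gene,
                    "signature": sig.name,
                    "log2fc": log2fc,
                    "fold": 2.0**log2fc,
                    "direction": "up" if log2fc > 0 else ("down" if log2fc < 0 else "flat"),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "signature", "log2fc", "fold", "direction"])


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for overlap k between a size-n query and a
    size-K set drawn from a size-N universe."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise DataError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    sets: list[SignatureSet],
    universe: set[str],
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene query against each signature set.

    Query genes outside the universe are dropped with a warning column in the
    result attrs; set genes are intersected with the universe before testing.
    Rows are sorted by ascending p (ties by set name); `significant` flags
    q < q_cut.
    """
    if not universe:
        raise DataError("empty universe")
    universe = {g.upper() for g in universe}
    query = {g.upper() for g in query}
    dropped = sorted(query - universe)
    query &= universe
    n, N = len(query), len(universe)
    rows = []
    for sig in sets:
        genes = sig.genes & universe
        K = len(genes)
        k = len(query & genes)
        p = hypergeom_p(k, K, n, N) if K > 0 else 1.0
        rows.append({"set_name": sig.name, "k": k, "K": K, "n": n, "N": N, "p": p})
    frame = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    frame["q"] = bh_fdr(frame["p"].to_numpy()) if len(frame) else []
    frame["significant"] = frame["q"] < q_cut
    frame = frame.sort_values(by=["p", "set_name"], kind="mergesort").reset_index(drop=True)
    frame.attrs["dropped_query_genes"] = dropped
    return frame


def timecourse_overlap(
    tumor_degs: set[str],
    injury_sets: dict[int, set[str]],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Per-day overlap of tumor DEGs with injury-day DEG sets.

    Returns one row per day with overlap count, Jaccard index and
    hypergeometric p (when a universe is given); attrs carry `argmax_days`
    (all days attaining the maximal count — ties are all reported) and
    `argmax_defined` (False when every overlap is zero).
    """
    tumor = {g.upper() for g in tumor_degs}
    if not tumor:
        raise DataError("empty tumor DEG set")
    rows = []
    for day in sorted(injury_sets):
        day_set = {g.upper() for g in injury_sets[day]}
        k = len(tumor & day_set)
        union = len(tumor | day_set)
        row = {
            "day": day,
            "overlap": k,
            "set_size": len(day_set),
            "jaccard": (k / union) if union else 0.0,
        }
        if universe:
            uni = {g.upper() for g in universe}
            row["p"] = hypergeom_p(
                len(tumor & day_set & uni), len(day_set & uni), len(tumor & uni), len(uni)
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    best = int(frame["overlap"].max()) if len(frame) else 0
    frame.attrs["argmax_defined"] = best > 0
    frame.attrs["argmax_days"] = (
        [int(d) for d in frame.loc[frame["overlap"] == best, "day"]] if best > 0 else []
    )
    return frame
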