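"""Core in-memory containers.

The pipeline's substrate is a log2-scale expression matrix (genes x samples)
with per-sample metadata describing cell type (``SC`` or ``MAC``), group
(``wt-1mo`` / ``mut-1mo`` / ``mut-7mo``), hybridization batch and replicate.
Both pieces are pandas objects so that downstream statistics can rely on
label alignment rather than positional bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

META_COLUMNS = ("cell_type", "group", "batch", "replicate")


@dataclass
class ExpressionMatrix:
    """Log2 intensities (genes x samples) plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, one column per sample ID.
    sample_meta
        DataFrame indexed by sample ID with columns ``cell_type``, ``group``,
        ``batch``, ``replicate``. Must cover exactly the columns of `values`.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DataError(f"duplicate gene ids: {list(dups[:5])}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataError("expression values must be finite")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise DataError(f"samples without metadata: {sorted(missing)[:5]}")
        lacking = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if lacking:
            raise DataError(f"sample_meta missing columns: {lacking}")
        if self.sample_meta.loc[list(self.values.columns), list(META_COLUMNS)].isna().any().any():
            raise DataError("incomplete sample metadata")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_where(self, cell_type: str | None = None, group: str | None = None) -> list[str]:
        """Sample IDs matching the given cell type and/or group label."""
        meta = self.sample_meta.loc[list(self.values.columns)]
        mask = pd.Series(True, index=meta.index)
        if cell_type is not None:
            mask &= meta["cell_type"] == cell_type
        if group is not None:
            mask &= meta["group"] == group
        return list(meta.index[mask])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Row subset preserving the order of `self.genes`."""
        keep = self.values.index[self.values.index.isin(set(genes))]
        return ExpressionMatrix(self.values.loc[keep], self.sample_meta.copy())

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[samples], self.sample_meta.loc[samples].copy())

    def group_means(self, cell_type: str, group: str) -> pd.Series:
        """Per-gene mean over replicates of one (cell type, group)."""
        cols = self.samples_where(cell_type, group)
        if not cols:
            raise DataError(f"no samples for cell_type={cell_type!r}, group={group!r}")
        return self.values[cols].mean(axis=1)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.sample_meta.copy())


@dataclass
class LRPair:
    """One directional ligand -> receptor relation with source provenance."""

    ligand: str
    receptor: str
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.ligand = self.ligand.strip().upper()
        self.receptor = self.receptor.strip().upper()
        if not self.ligand or not self.receptor:
            raise DataError("ligand and receptor symbols must be non-empty")
        self.sources = frozenset(self.sources)

    @property
    def key(self) -> tuple[str, str]:
        return (self.ligand, self.receptor)


@dataclass
class LRCatalog:
    """Deduplicated set of directional ligand->receptor pairs.

    ``(A, B)`` and ``(B, A)`` are distinct records: the relation is oriented
    from the secreted factor to the membrane receptor.
    """

    pairs: dict[tuple[str, str], LRPair]

    @classmethod
    def from_pairs(cls, pairs) -> "LRCatalog":
        merged: dict[tuple[str, str], LRPair] = {}
        for p in pairs:
            if p.key in merged:
                old = merged[p.key]
                merged[p.key] = LRPair(p.ligand, p.receptor, old.sources | p.sources)
            else:
                merged[p.key] = p
        return cls(merged)

    @property
    def ligand_set(self) -> set[str]:
        return {l for l, _ in self.pairs}

    @property
    def receptor_set(self) -> set[str]:
        return {r for _, r in self.pairs}

    def sorted_pairs(self) -> list[LRPair]:
        """Pairs in bit-stable (ligand, receptor) lexicographic order."""
        return [self.pairs[k] for k in sorted(self.pairs)]

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self.pairs
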