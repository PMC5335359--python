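"""Expression-conditioned autocrine/paracrine interaction calling.

The tumor-state ligand-receptor map: for every catalog pair and every ordered
(sender, receiver) combination of the two cell types, a call is emitted when
the ligand is expressed in the sender, the receptor is expressed in the
receiver, and at least one side is differentially expressed. "Expressed"
means the group-mean log2 intensity clears the presence cutoff — the first
quartile of pooled intensities (~3.1 on the arrays this emulates), below
which a transcript is treated as absent. Relative expression is reported as
quartile bins (1 lowest .. 4 highest) of the group-mean distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, LRCatalog
from .errors import ConfigError, DataError

CELLS = ("SC", "MAC")


@dataclass(frozen=True)
class PresenceCutoff:
    """Log2-intensity threshold below which a gene is treated as absent."""

    value: float
    method: str = "pooled-Q1"


@dataclass(frozen=True)
class InteractionCall:
    ligand: str
    receptor: str
    sender: str
    receiver: str
    mode: str  # "autocrine" | "paracrine"
    ligand_quartile: int
    receptor_quartile: int
    ligand_de: bool
    receptor_de: bool
    ligand_fold: float  # signed: 2^log2fc of the sender-cell contrast
    receptor_fold: float

    def __post_init__(self):
        expected = "autocrine" if self.sender == self.receiver else "paracrine"
        if self.mode != expected:
            raise DataError(f"mode {self.mode!r} inconsistent with sender/receiver")


def compute_presence_cutoff(matrix: ExpressionMatrix, per_cell: str | None = None) -> PresenceCutoff:
    """First quartile of all pooled gene x sample intensities.

    Linear-interpolation percentile (the convention giving 2.75 for values
    1..8). `per_cell` restricts pooling to one cell type's samples.
    """
    if matrix.values.size == 0:
        raise DataError("cannot compute a presence cutoff on an empty matrix")
    if per_cell is None:
        pooled = matrix.values.to_numpy(dtype=float).ravel()
        method = "pooled-Q1"
    else:
        cols = matrix.samples_where(cell_type=per_cell)
        if not cols:
            raise DataError(f"no samples for cell type {per_cell!r}")
        pooled = matrix.values[cols].to_numpy(dtype=float).ravel()
        method = f"{per_cell}-Q1"
    return PresenceCutoff(value=float(np.percentile(pooled, 25)), method=method)


def assign_quartiles(group_means: pd.Series | dict) -> pd.Series:
    """Bin values into quartiles 1..4 of their pooled distribution.

    Breakpoints are the linear-interpolation Q1/Q2/Q3 of all supplied values;
    ties at a breakpoint go to the lower bin (value <= Q1 -> bin 1, etc.).
    """
    series = pd.Series(group_means, dtype=float)
    if series.empty:
        return pd.Series(dtype=int)
    q1, q2, q3 = np.percentile(series.to_numpy(), [25, 50, 75])
    bins = np.select(
        [series <= q1, series <= q2, series <= q3],
        [1, 2, 3],
        default=4,
    )
    return pd.Series(bins, index=series.index, dtype=int)


def call_interactions(
    catalog: LRCatalog,
    group_means: dict[str, pd.Series],
    degs: dict[str, pd.DataFrame],
    cutoff: PresenceCutoff,
    require_de: str = "any",
    cells: tuple[str, str] = CELLS,
) -> tuple[list[InteractionCall], list[tuple[str, str]]]:
    """Emit autocrine/paracrine calls for every pair and cell direction.

    Parameters
    ----------
    group_means
        Per cell type, the per-gene mean log2 intensity of the tumor-state
        group being mapped.
    degs
        Per cell type, a called DEG table (columns ``called``, ``log2fc``).
    require_de
        "any" (default: at least one side differentially expressed — the
        red-box convention), "both", or "none".

    Returns
    -------
    (calls, skipped)
        `skipped` lists (gene, reason) for catalog genes absent from the
        expression input; missing genes are recorded, never fatal.
    """
    if require_de not in ("any", "both", "none"):
        raise ConfigError(f"require_de must be any|both|none, got {require_de!r}")
    quartiles = {cell: assign_quartiles(group_means[cell]) for cell in cells}
    called = {cell: set(degs[cell].index[degs[cell]["called"]]) for cell in cells}
    calls: list[InteractionCall] = []
    skipped: list[tuple[str, str]] = []
    seen_missing: set[str] = set()

    def note_missing(gene: str, cell: str) -> None:
        if (gene, cell) not in seen_missing:
            seen_missing.add((gene, cell))
            skipped.append((gene, f"absent from {cell} expression input"))

    for pair in catalog.sorted_pairs():
        for sender in cells:
            for receiver in cells:
                means_s, means_r = group_means[sender], group_means[receiver]
                if pair.ligand not in means_s.index:
                    note_missing(pair.ligand, sender)
                    continue
                if pair.receptor not in means_r.index:
                    note_missing(pair.receptor, receiver)
                    continue
                if means_s[pair.ligand] <= cutoff.value:
                    continue
                if means_r[pair.receptor] <= cutoff.value:
                    continue
                lig_de = pair.ligand in called[sender]
                rec_de = pair.receptor in called[receiver]
                if require_de == "any" and not (lig_de or rec_de):
                    continue
                if require_de == "both" and not (lig_de and rec_de):
                    continue
                lig_fold = _signed_fold(degs[sender], pair.ligand)
                rec_fold = _signed_fold(degs[receiver], pair.receptor)
                calls.append(
                    InteractionCall(
                        ligand=pair.ligand,
                        receptor=pair.receptor,
                        sender=sender,
                        receiver=receiver,
                        mode="autocrine" if sender == receiver else "paracrine",
                        ligand_quartile=int(quartiles[sender][pair.ligand]),
                        receptor_quartile=int(quartiles[receiver][pair.receptor]),
                        ligand_de=lig_de,
                        receptor_de=rec_de,
                        ligand_fold=lig_fold,
                        receptor_fold=rec_fold,
                    )
                )
    return calls, skipped


def _signed_fold(deg_table: pd.DataFrame, gene: str) -> float:
    """Fold change carrying direction: 2^log2fc (so 0.5 means halved)."""
    if gene not in deg_table.index:
        return float("nan")
    return float(2.0 ** deg_table.loc[gene, "log2fc"])


def calls_to_frame(calls: list[InteractionCall]) -> pd.DataFrame:
    rows = [
        {
            "ligand": c.ligand,
            "receptor": c.receptor,
            "sender": c.sender,
            "receiver": c.receiver,
            "mode": c.mode,
            "ligand_quartile": c.ligand_quartile,
            "receptor_quartile": c.receptor_quartile,
            "ligand_de": c.ligand_de,
            "receptor_de": c.receptor_de,
            "ligand_fold": c.ligand_fold,
            "receptor_fold": c.receptor_fold,
        }
        for c in sorted(calls, key=lambda c: (c.ligand, c.receptor, c.sender, c.receiver))
    ]
    columns = [
        "ligand", "receptor", "sender", "receiver", "mode",
        "ligand_quartile", "receptor_quartile", "ligand_de", "receptor_de",
        "ligand_fold", "receptor_fold",
    ]
    return pd.DataFrame(rows, columns=columns)


def export_map(calls: list[InteractionCall], dot_path, tsv_path, cells: tuple[str, str] = CELLS) -> None:
    """Write the interaction map as a Graphviz DOT file plus a TSV twin.

    The DOT graph clusters nodes per cell type; differentially expressed
    genes carry a highlight attribute (the red-box convention). Ordering is
    deterministic.
    """
    frame = calls_to_frame(calls)
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.4g")

    de_nodes: set[tuple[str, str]] = set()
    nodes: dict[str, set[str]] = {cell: set() for cell in cells}
    for c in calls:
        nodes[c.sender].add(c.ligand)
        nodes[c.receiver].add(c.receptor)
        if c.ligand_de:
            de_nodes.add((c.sender, c.ligand))
        if c.receptor_de:
            de_nodes.add((c.receiver, c.receptor))
    lines = ["digraph interactome {", "  rankdir=LR;"]
    for cell in cells:
        lines.append(f"  subgraph cluster_{cell} {{")
        lines.append(f'    label="{cell}";')
        for gene in sorted(nodes[cell]):
            attrs = 'style=filled, fillcolor=red' if (cell, gene) in de_nodes else "style=solid"
            lines.append(f'    "{cell}:{gene}" [label="{gene}", {attrs}];')
        lines.append("  }")
    for c in sorted(calls, key=lambda c: (c.ligand, c.receptor, c.sender, c.receiver)):
        style = "solid" if c.mode == "paracrine" else "dashed"
        lines.append(
            f'  "{c.sender}:{c.ligand}" -> "{c.receiver}:{c.receptor}" [style={style}];'
        )
    lines.append("}")
    with open(dot_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
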