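"""Bi-cellular network propagation and edge-flux scoring.

The intra-cell functional network is duplicated once per cell type; the two
copies are joined by ligand->receptor edges for every catalog pair and every
ordered (sender, receiver) cell combination, including within-cell autocrine
copies. Node weights come from the two contrasts' t-statistics after joint
quantile normalization and a strictly positive order-preserving transform.
A random walk with restart, biased toward heavy neighbors, yields a
stationary distribution p; each edge is scored by the stationary probability
flow across it ("flux"), and the top-k flux edges form the reported
subnetwork (the published setting uses k = 500).

The walk runs on the undirected skeleton (recurrence needs both directions);
flux reporting respects the ligand->receptor direction labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import LRCatalog
from .errors import ConfigError, ConvergenceError, DataError

Node = tuple[str, str]  # (gene, cell_type)

INTRA, INTER = "intra", "inter"


@dataclass(frozen=True)
class BicellEdge:
    a: Node
    b: Node
    kind: str  # INTRA (undirected) | INTER (directed a->b, ligand->receptor)

    @property
    def key(self) -> tuple:
        return (self.kind, self.a, self.b)


@dataclass
class BicellularNetwork:
    nodes: list[Node]
    edges: list[BicellEdge]
    index: dict[Node, int] = field(default_factory=dict)
    neighbors: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.nodes:
            raise DataError("empty bi-cellular network")
        self.index = {node: i for i, node in enumerate(self.nodes)}
        adj: list[set[int]] = [set() for _ in self.nodes]
        for e in self.edges:
            i, j = self.index[e.a], self.index[e.b]
            if i == j:
                raise DataError(f"self-loop at {e.a}")
            adj[i].add(j)
            adj[j].add(i)
        self.neighbors = [sorted(s) for s in adj]

    @property
    def n(self) -> int:
        return len(self.nodes)


def build_bicellular_network(
    intra_edges: list[tuple[str, str]],
    catalog: LRCatalog,
    cells: tuple[str, str] = ("SC", "MAC"),
) -> BicellularNetwork:
    """Duplicate the intra-cell network per cell type and join by LR edges.

    The node set is exactly the genes appearing on some edge; duplicate input
    edges are stored once.
    """
    intra: list[BicellEdge] = []
    seen: set[frozenset] = set()
    for a, b in intra_edges:
        a, b = a.strip().upper(), b.strip().upper()
        if a == b:
            continue
        for cell in cells:
            key = frozenset(((a, cell), (b, cell)))
            if key in seen:
                continue
            seen.add(key)
            intra.append(BicellEdge((a, cell), (b, cell), INTRA))
    inter: list[BicellEdge] = []
    seen_inter: set[tuple] = set()
    for pair in catalog.sorted_pairs():
        for sender in cells:
            for receiver in cells:
                a, b = (pair.ligand, sender), (pair.receptor, receiver)
                if a == b:
                    continue  # a self-pair within one cell has no edge
                if (a, b) in seen_inter:
                    continue
                seen_inter.add((a, b))
                inter.append(BicellEdge(a, b, INTER))
    edges = intra + inter
    if not edges:
        raise DataError("no edges: need an intra-cell network or LR catalog")
    node_set = {n for e in edges for n in (e.a, e.b)}
    nodes = sorted(node_set, key=lambda n: (n[1], n[0]))
    return BicellularNetwork(nodes=nodes, edges=edges)


# -- node weights --------------------------------------------------------------

def _joint_quantile_normalize(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Force two vectors onto their common mean quantile function.

    For equal lengths this is ordinary two-column quantile normalization
    (ties averaged); unequal lengths interpolate the two empirical quantile
    functions on [0, 1].
    """

    def qfun(v: np.ndarray, p: np.ndarray) -> np.ndarray:
        s = np.sort(v)
        if s.size == 1:
            return np.full_like(p, s[0])
        grid = np.linspace(0.0, 1.0, s.size)
        return np.interp(p, grid, s)

    def positions(n: int) -> np.ndarray:
        return np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])

    out = []
    for v in (x, y):
        p = positions(v.size)
        ref = 0.5 * (qfun(x, p) + qfun(y, p))
        order = np.argsort(v, kind="mergesort")
        dest = np.empty(v.size)
        dest[order] = ref
        dest = pd.Series(dest).groupby(v).transform("mean").to_numpy()
        out.append(dest)
    return out[0], out[1]


def weights_from_t(
    t_by_cell: dict[str, pd.Series],
    network: BicellularNetwork,
    transform: str = "exp2",
) -> np.ndarray:
    """Node weights from per-cell t-vectors after joint quantile normalization.

    transform: "exp2" (w = 2^qn_t, strictly positive, order-preserving) or
    "shift" (min-shift to 0 plus a small epsilon). Genes in the network but
    missing from a cell's t-vector receive that cell's median weight.
    """
    cells = sorted(t_by_cell)
    if len(cells) != 2:
        raise ConfigError("weights_from_t expects exactly two cell types")
    t0 = pd.Series(t_by_cell[cells[0]], dtype=float).dropna()
    t1 = pd.Series(t_by_cell[cells[1]], dtype=float).dropna()
    if t0.empty or t1.empty:
        raise DataError("both t-vectors must be non-empty")
    q0, q1 = _joint_quantile_normalize(t0.to_numpy(), t1.to_numpy())
    if transform == "exp2":
        w0, w1 = 2.0**q0, 2.0**q1
    elif transform == "shift":
        low = min(q0.min(), q1.min())
        eps = 1e-6 + 0.0
        w0, w1 = q0 - low + eps, q1 - low + eps
    else:
        raise ConfigError(f"unknown transform {transform!r}")
    per_cell = {
        cells[0]: pd.Series(w0, index=t0.index),
        cells[1]: pd.Series(w1, index=t1.index),
    }
    medians = {c: float(np.median(s.to_numpy())) for c, s in per_cell.items()}
    weights = np.empty(network.n)
    for i, (gene, cell) in enumerate(network.nodes):
        series = per_cell.get(cell)
        if series is None:
            raise DataError(f"network cell type {cell!r} has no t-vector")
        weights[i] = float(series.get(gene, medians[cell]))
    return weights


# -- random walk with restart --------------------------------------------------

def _transition_rows(network: BicellularNetwork, weights: np.ndarray):
    """Row-stochastic transition structure T_ij = w_j / sum_{k in N(i)} w_k.

    Returns (neighbor index lists, per-row probability arrays, dangling mask).
    Dangling nodes (no neighbors) restart with probability 1.
    """
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise DataError("node weights must be finite and strictly positive")
    probs: list[np.ndarray] = []
    dangling = np.zeros(network.n, dtype=bool)
    for i, nbrs in enumerate(network.neighbors):
        if not nbrs:
            dangling[i] = True
            probs.append(np.empty(0))
            continue
        wn = weights[nbrs]
        probs.append(wn / wn.sum())
    return probs, dangling


def rwr_stationary(
    network: BicellularNetwork,
    weights: np.ndarray,
    restart: float = 0.15,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Stationary distribution of the weight-biased walk with restart.

    Fixed point of p <- (1-r) T'p + r q with restart vector q = w / sum(w);
    converged when the L1 change drops below `tol`; p is renormalized each
    iteration so that sum(p) = 1 exactly (within 1e-9).
    """
    if not (0.0 < restart < 1.0):
        raise ConfigError(f"restart must lie in (0, 1), got {restart}")
    probs, dangling = _transition_rows(network, weights)
    n = network.n
    q = weights / weights.sum()
    # sparse propagation: build flat arrays once
    rows, cols, vals = [], [], []
    for i, nbrs in enumerate(network.neighbors):
        for j, pij in zip(nbrs, probs[i]):
            rows.append(i)
            cols.append(j)
            vals.append(pij)
    from scipy import sparse

    T = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    p = q.copy()
    r = restart
    for _ in range(max_iter):
        dangling_mass = p[dangling].sum() if dangling.any() else 0.0
        p_new = (1.0 - r) * (T.T @ p + dangling_mass * q) + r * q
        p_new /= p_new.sum()
        residual = np.abs(p_new - p).sum()
        p = p_new
        if residual < tol:
            return p
    raise ConvergenceError(
        f"random walk did not converge in {max_iter} iterations", residual=float(residual)
    )


@dataclass
class EdgeFluxTable:
    """Per-edge stationary probability flow plus the walk's parameters."""

    p: np.ndarray
    flux: pd.DataFrame  # columns: gene_a, cell_a, gene_b, cell_b, edge_type, flux
    restart: float
    tol: float


def edge_flux(
    p: np.ndarray,
    network: BicellularNetwork,
    weights: np.ndarray,
    restart: float = 0.15,
    tol: float = 1e-10,
) -> EdgeFluxTable:
    """Score each edge by stationary flow.

    Undirected intra edges: flux = (1-r) (p_i T_ij + p_j T_ji). Directed
    ligand->receptor edges: the single direction term (1-r) p_i T_ij.
    """
    probs, _ = _transition_rows(network, weights)
    tmap: list[dict[int, float]] = [
        dict(zip(nbrs, pr)) for nbrs, pr in zip(network.neighbors, probs)
    ]
    r = restart
    records = []
    for e in network.edges:
        i, j = network.index[e.a], network.index[e.b]
        forward = p[i] * tmap[i].get(j, 0.0)
        if e.kind == INTRA:
            f = (1.0 - r) * (forward + p[j] * tmap[j].get(i, 0.0))
        else:
            f = (1.0 - r) * forward
        records.append(
            {
                "gene_a": e.a[0], "cell_a": e.a[1],
                "gene_b": e.b[0], "cell_b": e.b[1],
                "edge_type": e.kind, "flux": f,
            }
        )
    frame = pd.DataFrame(records,
                         columns=["gene_a", "cell_a", "gene_b", "cell_b", "edge_type", "flux"])
    return EdgeFluxTable(p=p, flux=frame, restart=restart, tol=tol)


def top_subnetwork(table: EdgeFluxTable, k: int) -> pd.DataFrame:
    """The k highest-flux edges (deterministic tie-break by edge labels)."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    frame = table.flux
    if k > len(frame):
        warnings.warn(f"k={k} exceeds edge count {len(frame)}; returning all edges")
        k = len(frame)
    ordered = frame.sort_values(
        by=["flux", "gene_a", "cell_a", "gene_b", "cell_b", "edge_type"],
        ascending=[False, True, True, True, True, True],
        kind="mergesort",
    )
    return ordered.head(k).reset_index(drop=True)


def run_netwalk(
    intra_edges: list[tuple[str, str]],
    catalog: LRCatalog,
    t_by_cell: dict[str, pd.Series],
    restart: float = 0.15,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    transform: str = "exp2",
) -> tuple[BicellularNetwork, np.ndarray, EdgeFluxTable]:
    """Convenience wrapper: build network, weights, walk, and flux table."""
    network = build_bicellular_network(intra_edges, catalog)
    weights = weights_from_t(t_by_cell, network, transform=transform)
    p = rwr_stationary(network, weights, restart=restart, tol=tol, max_iter=max_iter)
    table = edge_flux(p, network, weights, restart=restart, tol=tol)
    return network, weights, table


def write_flux_table(table: EdgeFluxTable, path) -> None:
    frame = table.flux.sort_values(
        by=["flux", "gene_a", "cell_a", "gene_b", "cell_b"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def subnetwork_to_dot(subnetwork: pd.DataFrame, path) -> None:
    """DOT export of a flux subnetwork, one cluster per cell type."""
    cells = sorted(set(subnetwork["cell_a"]) | set(subnetwork["cell_b"]))
    lines = ["graph flux_subnetwork {"]
    for cell in cells:
        lines.append(f"  subgraph cluster_{cell} {{")
        lines.append(f'    label="{cell}";')
        genes = sorted(
            set(subnetwork.loc[subnetwork["cell_a"] == cell, "gene_a"])
            | set(subnetwork.loc[subnetwork["cell_b"] == cell, "gene_b"])
        )
        for g in genes:
            lines.append(f'    "{cell}:{g}" [label="{g}"];')
        lines.append("  }")
    for row in subnetwork.itertuples():
        style = "dashed" if row.edge_type == INTER else "solid"
        lines.append(f'  "{row.cell_a}:{row.gene_a}" -- "{row.cell_b}:{row.gene_b}" [style={style}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
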