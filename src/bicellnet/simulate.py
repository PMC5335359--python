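"""Synthetic inputs with the statistical structure the analysis assumes.

Everything downstream is exercised on data from this module: a two-cell-type
(SC / MAC), three-group (wt-1mo, mut-1mo, mut-7mo), three-replicate,
two-batch log2 expression matrix with planted differentially expressed
genes; ligand-receptor source files in the three catalog dialects with a
known merged truth; subtype profiles with planted factor/cluster structure;
injury-day DEG sets with exact planted overlaps; signature GMTs; an
intra-cell functional network; and an ortholog table. Each generator returns
its piece of the ground truth so recovery is checkable without downloads.

Baseline log2 intensities are drawn from a two-component mixture — an
"absent" low mode and an "expressed" high mode — sized so the pooled first
quartile lands near 3.1 under the defaults, which keeps the presence cutoff
meaningful. Batch effects are gene-specific additive shifts plus
multiplicative residual scale, the model the empirical-Bayes batch adjuster
estimates. A fixed seed fixes every output bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, LRCatalog, LRPair
from .errors import ConfigError

DEFAULT_GROUPS = (
    ("SC", "wt-1mo"), ("SC", "mut-1mo"), ("SC", "mut-7mo"),
    ("MAC", "wt-1mo"), ("MAC", "mut-1mo"), ("MAC", "mut-7mo"),
)
TUMOR_GROUP = "mut-7mo"
CONTRAST_GROUP = "mut-1mo"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the emulated two-cell-type experiment."""

    n_genes: int = 2000
    groups: tuple = DEFAULT_GROUPS
    n_replicates: int = 3
    n_batches: int = 2
    baseline_mean: float = 6.5   # expressed-mode mean, log2 units
    baseline_sd: float = 1.5
    absent_fraction: float = 0.30
    absent_mean: float = 2.6     # absence regime: pooled Q1 lands near 3.1
    absent_sd: float = 0.4
    noise_sd: float = 0.5        # within-group replicate noise, log2 units
    de_fraction: float = 0.05
    de_log2fc_magnitude: float = 2.0
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    n_lr_pairs_planted: int = 8
    n_factors_planted: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if not (0.0 <= self.de_fraction < 1.0):
            raise ConfigError("de_fraction must lie in [0, 1)")
        if self.de_fraction > 0 and self.de_log2fc_magnitude < 1.0:
            raise ConfigError("de_log2fc_magnitude must be >= 1 log2 unit")
        for name in ("baseline_sd", "absent_sd", "noise_sd", "batch_shift_sd", "batch_scale_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.absent_fraction < 1.0):
            raise ConfigError("absent_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks downstream."""

    de_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_interactions: list[tuple[str, str, str, str]] = field(default_factory=list)
    planted_factor_loadings: pd.DataFrame | None = None
    injury_day_sets: dict[int, set[str]] = field(default_factory=dict)
    catalog_source_truth: set[tuple[str, str]] = field(default_factory=set)

    def de_genes_for(self, cell_type: str) -> set[str]:
        return {g for g, (contrast, _) in self.de_genes.items()
                if contrast.startswith(f"{cell_type}:")}

    def to_json(self, path) -> None:
        payload = {
            "de_genes": {g: [c, fc] for g, (c, fc) in sorted(self.de_genes.items())},
            "planted_interactions": sorted(self.planted_interactions),
            "injury_day_sets": {str(d): sorted(s) for d, s in sorted(self.injury_day_sets.items())},
            "catalog_source_truth": sorted(list(p) for p in self.catalog_source_truth),
            "planted_factor_loadings": (
                None if self.planted_factor_loadings is None
                else self.planted_factor_loadings.round(6).to_dict(orient="split")
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        loadings = payload.get("planted_factor_loadings")
        return cls(
            de_genes={g: (c, fc) for g, (c, fc) in payload["de_genes"].items()},
            planted_interactions=[tuple(t) for t in payload["planted_interactions"]],
            injury_day_sets={int(d): set(s) for d, s in payload["injury_day_sets"].items()},
            catalog_source_truth={tuple(p) for p in payload["catalog_source_truth"]},
            planted_factor_loadings=(
                None if loadings is None
                else pd.DataFrame(loadings["data"], index=loadings["index"],
                                  columns=loadings["columns"])
            ),
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the log2 expression matrix plus its ground truth.

    Per gene: a baseline drawn from the absent/expressed mixture, shared
    across cell types; per (gene, batch): an additive shift and a residual
    scale; per sample: N(0, noise_sd) replicate noise scaled by the batch
    factor. Planted DE genes get +/- de_log2fc_magnitude added to the tumor
    (mut-7mo) samples of their assigned cell type, so their expected contrast
    against either 1-month group is exactly the planted value.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)

    expressed = rng.random(config.n_genes) >= config.absent_fraction
    baseline = np.where(
        expressed,
        rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes),
        rng.normal(config.absent_mean, config.absent_sd, config.n_genes),
    )

    samples, meta_rows = [], []
    for cell, group in config.groups:
        for rep in range(1, config.n_replicates + 1):
            samples.append(f"{cell}_{group}_r{rep}")
            meta_rows.append(
                {
                    "cell_type": cell,
                    "group": group,
                    "batch": f"b{(rep - 1) % config.n_batches + 1}",
                    "replicate": rep,
                }
            )
    meta = pd.DataFrame(meta_rows, index=pd.Index(samples, name="sample"))

    batch_ids = sorted(meta["batch"].unique())
    shift = {b: rng.normal(0.0, config.batch_shift_sd, config.n_genes) for b in batch_ids}
    scale = {b: np.exp(rng.normal(0.0, config.batch_scale_sd, config.n_genes))
             for b in batch_ids}

    # plant DE genes among the expressed mode, alternating cell types
    n_de = int(round(config.n_genes * config.de_fraction))
    expressed_idx = np.flatnonzero(expressed)
    if n_de > expressed_idx.size:
        raise ConfigError("de_fraction requests more DE genes than expressed genes exist")
    de_idx = rng.choice(expressed_idx, size=n_de, replace=False) if n_de else np.array([], int)
    truth = GroundTruth()
    cells = sorted({cell for cell, _ in config.groups})
    effect = np.zeros((config.n_genes, len(samples)))
    tumor_cols = {
        cell: [s for s, r in meta.iterrows() if r["cell_type"] == cell and r["group"] == TUMOR_GROUP]
        for cell in cells
    }
    col_pos = {s: i for i, s in enumerate(samples)}
    for j, gi in enumerate(sorted(de_idx)):
        cell = cells[j % len(cells)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        fc = sign * config.de_log2fc_magnitude
        for s in tumor_cols.get(cell, []):
            effect[gi, col_pos[s]] = fc
        truth.de_genes[genes[gi]] = (f"{cell}:{TUMOR_GROUP}_vs_{CONTRAST_GROUP}", fc)

    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples)))
    values = np.empty((config.n_genes, len(samples)))
    for i, s in enumerate(samples):
        b = meta.loc[s, "batch"]
        values[:, i] = baseline + effect[:, i] + shift[b] + scale[b] * noise[:, i]

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)

    # plant ligand-receptor loops: ligands are up-regulated DE genes of the
    # sender cell; receptors are well-expressed non-DE genes
    if config.n_lr_pairs_planted:
        directions = [("SC", "SC"), ("SC", "MAC"), ("MAC", "SC"), ("MAC", "MAC")]
        up_by_cell = {
            cell: [g for g, (c, fc) in truth.de_genes.items()
                   if c.startswith(f"{cell}:") and fc > 0]
            for cell in cells
        }
        high = [genes[i] for i in expressed_idx
                if baseline[i] > config.baseline_mean and genes[i] not in truth.de_genes]
        rng.shuffle(high)
        used: set[str] = set()
        for k in range(config.n_lr_pairs_planted):
            sender, receiver = directions[k % len(directions)]
            pool = [g for g in up_by_cell.get(sender, []) if g not in used]
            lig_pool = pool if pool else [g for g in high if g not in used]
            if not lig_pool or len(high) == 0:
                break
            ligand = lig_pool[0]
            used.add(ligand)
            rec_pool = [g for g in high if g not in used]
            if not rec_pool:
                break
            receptor = rec_pool[0]
            used.add(receptor)
            truth.planted_interactions.append((ligand, receptor, sender, receiver))
    return matrix, truth


# -- ortholog table ------------------------------------------------------------

def simulate_ortholog_table(
    genes: list[str],
    protected: set[str] | None = None,
    weak_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Mouse-symbol -> human-symbol table with a support flag.

    Every gene gets a 1:1 flagged human partner ("H" + symbol) except a
    `weak_fraction` of unprotected genes, which are written as ambiguous
    (two targets) or unflagged rows and therefore fail the strong-ortholog
    rule. `protected` genes (planted truth) always survive.
    """
    rng = np.random.default_rng(seed)
    protected = {g.upper() for g in (protected or set())}
    rows = []
    for g in genes:
        gu = g.upper()
        if gu not in protected and rng.random() < weak_fraction:
            if rng.random() < 0.5:  # one-to-many
                rows.append({"source_symbol": gu, "target_symbol": f"H{gu}", "support_flag": "1"})
                rows.append({"source_symbol": gu, "target_symbol": f"H{gu}X", "support_flag": "1"})
            else:  # unsupported
                rows.append({"source_symbol": gu, "target_symbol": f"H{gu}", "support_flag": "0"})
        else:
            rows.append({"source_symbol": gu, "target_symbol": f"H{gu}", "support_flag": "1"})
    return pd.DataFrame(rows, columns=["source_symbol", "target_symbol", "support_flag"])


# -- catalog source files ------------------------------------------------------

@dataclass(frozen=True)
class CatalogSourceConfig:
    """Sizes and pairwise overlaps of the three ligand-receptor sources."""

    n_dlrp: int = 20
    n_biogrid: int = 15
    n_kegg: int = 12
    overlap_dlrp_biogrid: int = 5
    overlap_dlrp_kegg: int = 4
    overlap_biogrid_kegg: int = 3
    seed: int = 0

    def __post_init__(self):
        sizes = {"DLRP": self.n_dlrp, "BIOGRID": self.n_biogrid, "KEGG": self.n_kegg}
        pairings = {
            ("DLRP", "BIOGRID"): self.overlap_dlrp_biogrid,
            ("DLRP", "KEGG"): self.overlap_dlrp_kegg,
            ("BIOGRID", "KEGG"): self.overlap_biogrid_kegg,
        }
        for (a, b), o in pairings.items():
            if o < 0 or o > min(sizes[a], sizes[b]):
                raise ConfigError(f"overlap {a}/{b}={o} exceeds a source size")
        if self.overlap_dlrp_biogrid + self.overlap_dlrp_kegg > self.n_dlrp:
            raise ConfigError("DLRP overlaps exceed its size")
        if self.overlap_dlrp_biogrid + self.overlap_biogrid_kegg > self.n_biogrid:
            raise ConfigError("BioGrid overlaps exceed its size")
        if self.overlap_dlrp_kegg + self.overlap_biogrid_kegg > self.n_kegg:
            raise ConfigError("KEGG overlaps exceed its size")


def simulate_catalog_sources(
    config: CatalogSourceConfig,
    out_dir,
    include_pairs: list[tuple[str, str]] | None = None,
) -> tuple[dict[str, Path], LRCatalog, dict[str, set[str]]]:
    """Write DLRP-style, BioGrid TAB2 and KGML files with a known union.

    Overlapping blocks are disjoint (no triple overlap), so the expected
    merged size is exactly n1+n2+n3 - o12 - o13 - o23. `include_pairs`
    (e.g. planted interaction pairs) are placed at the front of the DLRP
    exclusive block. Also writes the GO annotation table assigning ligand /
    receptor roles to every symbol used.

    Returns (paths, expected merged catalog, GO annotation map).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    include_pairs = [(l.upper(), r.upper()) for l, r in (include_pairs or [])]

    o12, o13, o23 = (config.overlap_dlrp_biogrid, config.overlap_dlrp_kegg,
                     config.overlap_biogrid_kegg)
    n_excl = {
        "DLRP": config.n_dlrp - o12 - o13,
        "BIOGRID": config.n_biogrid - o12 - o23,
        "KEGG": config.n_kegg - o13 - o23,
    }
    total = sum(n_excl.values()) + o12 + o13 + o23

    fillers_needed = max(0, total - len(include_pairs))
    filler = [(f"LIG{i:03d}", f"REC{i:03d}") for i in range(1, fillers_needed + 1)]
    pool = (include_pairs + filler)[:total]

    cursor = 0

    def take(n: int) -> list[tuple[str, str]]:
        nonlocal cursor
        chunk = pool[cursor:cursor + n]
        cursor += n
        return chunk

    blocks = {
        "DLRP": take(n_excl["DLRP"]),
        "BIOGRID": take(n_excl["BIOGRID"]),
        "KEGG": take(n_excl["KEGG"]),
    }
    shared12, shared13, shared23 = take(o12), take(o13), take(o23)
    membership = {
        "DLRP": blocks["DLRP"] + shared12 + shared13,
        "BIOGRID": blocks["BIOGRID"] + shared12 + shared23,
        "KEGG": blocks["KEGG"] + shared13 + shared23,
    }

    paths = {
        "dlrp": out_dir / "dlrp_pairs.txt",
        "biogrid": out_dir / "biogrid_tab2.tsv",
        "kgml": out_dir / "kegg_pathway.xml",
        "go": out_dir / "go_annotations.tsv",
    }
    _write_dlrp(membership["DLRP"], paths["dlrp"])
    ligands = {l for src in membership.values() for l, _ in src}
    receptors = {r for src in membership.values() for _, r in src}
    _write_tab2(membership["BIOGRID"], paths["biogrid"], seed=config.seed)
    _write_kgml(membership["KEGG"], paths["kgml"])

    annotations: dict[str, set[str]] = {}
    for g in sorted(ligands):
        annotations.setdefault(g, set()).update({"extracellular region", "cytokine activity"})
    for g in sorted(receptors):
        annotations.setdefault(g, set()).update({"receptor activity", "plasma membrane"})
    term_ids = {t: f"GO:{i + 1:07d}" for i, t in enumerate(
        sorted({t for terms in annotations.values() for t in terms}))}
    rows = [{"gene": g, "go_id": term_ids[t], "go_name": t}
            for g in sorted(annotations) for t in sorted(annotations[g])]
    pd.DataFrame(rows).to_csv(paths["go"], sep="\t", index=False)

    truth_pairs = {p for src in membership.values() for p in src}
    truth = LRCatalog.from_pairs(
        [LRPair(l, r, frozenset(src for src, pairs in membership.items() if (l, r) in pairs))
         for l, r in truth_pairs]
    )
    return paths, truth, annotations


def _write_dlrp(pairs: list[tuple[str, str]], path: Path) -> None:
    lines = []
    for lig, rec in pairs:
        lines.append(f"LIGAND\t{lig}")
        lines.append(f"RECEPTOR\t{rec}")
        lines.append("")
    path.write_text("\n".join(lines))


def _write_tab2(pairs: list[tuple[str, str]], path: Path, seed: int = 0) -> None:
    """TAB2 rows with physical evidence; alternate orientation of the two
    interactor columns, plus genetic-evidence decoy rows that must be ignored."""
    rng = np.random.default_rng(seed + 1)
    rows = []
    for i, (lig, rec) in enumerate(pairs):
        a, b = (lig, rec) if i % 2 == 0 else (rec, lig)
        rows.append(
            {
                "#BioGRID Interaction ID": str(100000 + i),
                "Official Symbol Interactor A": a,
                "Official Symbol Interactor B": b,
                "Experimental System": "Reconstituted Complex",
                "Experimental System Type": "physical",
            }
        )
    for i in range(max(2, len(pairs) // 4)):  # decoys: genetic evidence
        rows.append(
            {
                "#BioGRID Interaction ID": str(200000 + i),
                "Official Symbol Interactor A": f"DECOYA{i}",
                "Official Symbol Interactor B": f"DECOYB{i}",
                "Experimental System": "Synthetic Lethality",
                "Experimental System Type": "genetic",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_kgml(pairs: list[tuple[str, str]], path: Path) -> None:
    symbols = sorted({s for p in pairs for s in p})
    sym_id = {s: str(i + 1) for i, s in enumerate(symbols)}
    lines = ['<?xml version="1.0"?>', '<pathway name="path:synthetic" org="mmu" number="04062">']
    for s in symbols:
        lines.append(f'  <entry id="{sym_id[s]}" name="mmu:{s}" type="gene"/>')
    for lig, rec in pairs:
        lines.append(f'  <relation entry1="{sym_id[lig]}" entry2="{sym_id[rec]}" type="PPrel">')
        lines.append('    <subtype name="activation" value="--&gt;"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    path.write_text("\n".join(lines))


# -- subtype / factor-structure profiles ---------------------------------------

def simulate_subtype_profiles(
    n_clusters: int,
    n_samples_per_cluster: int,
    n_genes: int,
    separation: float,
    seed: int = 0,
    loading: float = 0.8,
    noise_sd: float = 0.6,
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Expression profiles with planted factor/cluster structure.

    Genes are split into `n_clusters` blocks; block k loads `loading` on
    factor k. Each sample's factor position is its cluster centroid
    (`separation` along the cluster's own factor, 0 elsewhere) plus unit
    factor jitter; separation=0 leaves pure factor structure with
    uninformative labels. Returns (matrix, labels, planted loadings).
    """
    if n_clusters < 1:
        raise ConfigError("n_clusters must be >= 1")
    if n_genes < n_clusters:
        raise ConfigError("need at least one gene per cluster block")
    rng = np.random.default_rng(seed)
    genes = [f"S{i:04d}" for i in range(1, n_genes + 1)]
    loadings = np.zeros((n_genes, n_clusters))
    for gi in range(n_genes):
        loadings[gi, gi % n_clusters] = loading

    n_samples = n_clusters * n_samples_per_cluster
    labels, factor_pos = [], np.zeros((n_samples, n_clusters))
    for s in range(n_samples):
        c = s // n_samples_per_cluster
        labels.append(f"cluster{c + 1}")
        factor_pos[s, c] = separation
    factor_pos += rng.normal(0.0, 1.0, size=factor_pos.shape)

    base = 7.0
    values = base + factor_pos @ loadings.T + rng.normal(0.0, noise_sd, (n_samples, n_genes))
    sample_ids = [f"subtype_s{i:03d}" for i in range(1, n_samples + 1)]
    meta = pd.DataFrame(
        {
            "cell_type": "MAC",
            "group": labels,
            "batch": "b1",
            "replicate": [s % n_samples_per_cluster + 1 for s in range(n_samples)],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values.T, index=genes, columns=sample_ids), meta
    )
    label_series = pd.Series(labels, index=sample_ids, name="cluster")
    loading_frame = pd.DataFrame(
        loadings, index=genes, columns=[f"F{i+1}" for i in range(n_clusters)]
    )
    return matrix, label_series, loading_frame


# -- injury-day DEG sets -------------------------------------------------------

def simulate_injury_sets(
    days: list[int],
    set_sizes: list[int],
    overlaps_with_tumor: list[int],
    tumor_degs: set[str],
    universe: set[str],
    seed: int = 0,
) -> dict[int, set[str]]:
    """Per-day injury DEG sets with exact planted tumor overlaps.

    Each day's set draws exactly `overlap` genes from the tumor DEG set and
    fills the remainder from universe \\ tumor, so the realized overlap
    equals the request by construction.
    """
    if not (len(days) == len(set_sizes) == len(overlaps_with_tumor)):
        raise ConfigError("days, set_sizes and overlaps must have equal length")
    tumor = sorted({g.upper() for g in tumor_degs})
    rest = sorted({g.upper() for g in universe} - set(tumor))
    rng = np.random.default_rng(seed)
    out: dict[int, set[str]] = {}
    for day, size, overlap in zip(days, set_sizes, overlaps_with_tumor):
        if overlap > min(size, len(tumor)):
            raise ConfigError(
                f"day {day}: overlap {overlap} exceeds min(set size {size}, tumor {len(tumor)})"
            )
        n_fill = size - overlap
        if n_fill > len(rest):
            raise ConfigError(f"day {day}: universe too small for {n_fill} non-tumor genes")
        chosen = list(rng.choice(tumor, size=overlap, replace=False)) if overlap else []
        fill = list(rng.choice(rest, size=n_fill, replace=False)) if n_fill else []
        out[int(day)] = set(chosen) | set(fill)
    return out


# -- signature gene sets -------------------------------------------------------

def simulate_signatures(
    genes: list[str],
    de_genes: set[str],
    seed: int = 0,
    n_per_set: int = 30,
    de_share: float = 0.5,
) -> dict[str, set[str]]:
    """M1 / M2 / IRG signature lists enriched for planted DE genes.

    Each set draws `de_share` of its members from the DE pool (planted
    enrichment signal) and the rest from the remaining genes.
    """
    rng = np.random.default_rng(seed)
    de_pool = sorted({g.upper() for g in de_genes})
    other = sorted({g.upper() for g in genes} - set(de_pool))
    out: dict[str, set[str]] = {}
    for name in ("M1_signature", "M2_signature", "IRG_signature"):
        n_de = min(int(round(n_per_set * de_share)), len(de_pool))
        n_other = min(n_per_set - n_de, len(other))
        members = set(rng.choice(de_pool, n_de, replace=False)) if n_de else set()
        members |= set(rng.choice(other, n_other, replace=False)) if n_other else set()
        if not members:
            raise ConfigError("cannot build an empty signature set")
        out[name] = members
    return out


# -- intra-cell functional network ---------------------------------------------

def simulate_intra_network(
    genes: list[str],
    n_extra_edges: int = 200,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Connected random functional network: a chain backbone over all genes
    plus `n_extra_edges` random chords (duplicates skipped)."""
    rng = np.random.default_rng(seed)
    genes = [g.upper() for g in genes]
    edges = [(genes[i], genes[i + 1]) for i in range(len(genes) - 1)]
    seen = {frozenset(e) for e in edges}
    attempts = 0
    while len(edges) < len(genes) - 1 + n_extra_edges and attempts < 50 * n_extra_edges:
        attempts += 1
        i, j = rng.integers(0, len(genes), size=2)
        if i == j:
            continue
        key = frozenset((genes[i], genes[j]))
        if key in seen:
            continue
        seen.add(key)
        edges.append((genes[i], genes[j]))
    return edges


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["groups"] = [list(g) for g in config.groups]
    return d
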