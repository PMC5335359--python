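"""Stage orchestration: reproducible end-to-end runs with a manifest.

A run is driven by one `RunConfig` (YAML-serializable). Stages write their
outputs under the run directory; `run_all` executes every stage in
dependency order and finishes with a SHA-256 manifest of every produced
file, the resolved configuration, and a human-readable summary. Identical
config + seed give byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import catalog as cat
from . import deg as deg_mod
from . import efa as efa_mod
from . import enrichment as enr
from . import interactome as inter
from . import netwalk as nw
from . import preprocess as prep
from . import simulate as sim
from .datatypes import ExpressionMatrix
from .errors import ConfigError, DataError
from .io import (read_catalog, read_expression, read_gmt, read_ortholog_table,
                 read_sif, write_catalog, write_expression, write_gmt,
                 write_ortholog_table, write_sif)

STAGE_ORDER = (
    "simulate", "preprocess", "deg", "catalog", "interactome",
    "netwalk", "efa", "enrich", "overlap",
)
DEPENDENCIES = {
    "simulate": (),
    "preprocess": ("simulate",),
    "deg": ("preprocess",),
    "catalog": ("simulate",),
    "interactome": ("deg", "catalog"),
    "netwalk": ("deg", "catalog"),
    "efa": ("deg",),
    "enrich": ("deg", "simulate"),
    "overlap": ("deg", "simulate"),
}


@dataclass
class RunConfig:
    """Single source of all run parameters; CLI flags override these fields."""

    out_dir: str = "bicellnet_run"
    seed: int = 0
    # synthetic study design
    n_genes: int = 2000
    n_replicates: int = 3
    n_batches: int = 2
    de_fraction: float = 0.05
    de_log2fc_magnitude: float = 2.0
    noise_sd: float = 0.5
    n_lr_pairs_planted: int = 8
    # catalog sources
    n_dlrp: int = 20
    n_biogrid: int = 15
    n_kegg: int = 12
    overlap_dlrp_biogrid: int = 5
    overlap_dlrp_kegg: int = 4
    overlap_biogrid_kegg: int = 3
    # DE calling
    fold_cut: float = 2.0
    q_cut: float = 0.05
    injury_fold_cut: float = 3.0
    # interactome
    require_de: str = "any"
    cutoff_per_cell: bool = False
    # netwalk
    restart: float = 0.15
    rwr_tol: float = 1e-10
    rwr_max_iter: int = 100_000
    top_k: int = 500
    n_intra_extra_edges: int = 200
    # efa
    efa_mode: str = "all_degs"
    max_m: int | None = None
    # injury timecourse
    injury_days: tuple = (1, 4, 7, 14)
    injury_set_sizes: tuple = (40, 40, 40, 40)
    injury_overlaps: tuple = (10, 30, 15, 5)

    def __post_init__(self) -> None:
        self.injury_days = tuple(self.injury_days)
        self.injury_set_sizes = tuple(self.injury_set_sizes)
        self.injury_overlaps = tuple(self.injury_overlaps)

    def validate(self) -> None:
        if not (0.0 < self.restart < 1.0):
            raise ConfigError("restart must lie in (0, 1)")
        if self.fold_cut <= 0 or self.injury_fold_cut <= 0:
            raise ConfigError("fold cuts must be positive")
        if not (0.0 < self.q_cut <= 1.0):
            raise ConfigError("q_cut must lie in (0, 1]")
        if self.require_de not in ("any", "both", "none"):
            raise ConfigError("require_de must be any|both|none")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if not (len(self.injury_days) == len(self.injury_set_sizes) == len(self.injury_overlaps)):
            raise ConfigError("injury day/size/overlap lists must have equal length")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["injury_days"] = list(self.injury_days)
        payload["injury_set_sizes"] = list(self.injury_set_sizes)
        payload["injury_overlaps"] = list(self.injury_overlaps)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


# -- helpers -------------------------------------------------------------------

def _paths(config: RunConfig) -> dict[str, Path]:
    root = Path(config.out_dir)
    return {
        "root": root,
        "expression": root / "expression.tsv",
        "sample_meta": root / "sample_meta.tsv",
        "ortholog": root / "ortholog_table.tsv",
        "signatures": root / "signatures.gmt",
        "intra_sif": root / "intra_network.sif",
        "injury_json": root / "injury_sets.json",
        "ground_truth": root / "ground_truth.json",
        "pre_expression": root / "expression_preprocessed.tsv",
        "pre_meta": root / "sample_meta_preprocessed.tsv",
        "deg_sc": root / "deg_SC.tsv",
        "deg_mac": root / "deg_MAC.tsv",
        "catalog": root / "catalog.tsv",
        "calls_tsv": root / "interaction_calls.tsv",
        "calls_dot": root / "interaction_map.dot",
        "skipped": root / "interaction_skipped.tsv",
        "flux": root / "edge_flux.tsv",
        "subnet_dot": root / "top_subnetwork.dot",
        "subnet_tsv": root / "top_subnetwork.tsv",
        "map_criterion": root / "efa_map_criterion.tsv",
        "loadings": root / "efa_loadings.tsv",
        "scores": root / "efa_scores.tsv",
        "enrichment": root / "enrichment.tsv",
        "overlap": root / "injury_overlap.tsv",
        "config": root / "config_resolved.yaml",
        "manifest": root / "manifest.json",
        "summary": root / "summary.txt",
        "log": root / "run_log.txt",
    }


def _require(stage: str, paths: dict[str, Path], files: list[str]) -> None:
    for key in files:
        if not paths[key].exists():
            prereq = [s for s in STAGE_ORDER if key in _STAGE_OUTPUTS.get(s, ())]
            hint = f" (run stage {prereq[0]!r} first)" if prereq else ""
            raise DataError(f"stage {stage!r} needs missing input {paths[key].name}{hint}")


def _read_matrix(paths: dict[str, Path], preprocessed: bool) -> ExpressionMatrix:
    if preprocessed:
        return read_expression(paths["pre_expression"], paths["pre_meta"])
    return read_expression(paths["expression"], paths["sample_meta"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


_STAGE_OUTPUTS = {
    "simulate": ("expression", "sample_meta", "ortholog", "signatures", "intra_sif",
                 "injury_json", "ground_truth", "dlrp", "biogrid", "kgml", "go"),
    "preprocess": ("pre_expression", "pre_meta"),
    "deg": ("deg_sc", "deg_mac"),
    "catalog": ("catalog",),
    "interactome": ("calls_tsv", "calls_dot", "skipped"),
    "netwalk": ("flux", "subnet_dot", "subnet_tsv"),
    "efa": ("map_criterion", "loadings", "scores"),
    "enrich": ("enrichment",),
    "overlap": ("overlap",),
}


# -- stages --------------------------------------------------------------------

def _stage_simulate(config: RunConfig, paths: dict[str, Path]) -> list[Path]:
    sim_config = sim.SimulationConfig(
        n_genes=config.n_genes,
        n_replicates=config.n_replicates,
        n_batches=config.n_batches,
        de_fraction=config.de_fraction,
        de_log2fc_magnitude=config.de_log2fc_magnitude,
        noise_sd=config.noise_sd,
        n_lr_pairs_planted=config.n_lr_pairs_planted,
        seed=config.seed,
    )
    matrix, truth = sim.simulate_expression(sim_config)
    write_expression(matrix, paths["expression"], paths["sample_meta"])

    protected = set(truth.de_genes) | {
        g for pair in truth.planted_interactions for g in pair[:2]
    }
    ortho = sim.simulate_ortholog_table(list(matrix.genes), protected=protected,
                                        seed=config.seed + 1)
    write_ortholog_table(ortho, paths["ortholog"])

    source_config = sim.CatalogSourceConfig(
        n_dlrp=config.n_dlrp, n_biogrid=config.n_biogrid, n_kegg=config.n_kegg,
        overlap_dlrp_biogrid=config.overlap_dlrp_biogrid,
        overlap_dlrp_kegg=config.overlap_dlrp_kegg,
        overlap_biogrid_kegg=config.overlap_biogrid_kegg,
        seed=config.seed,
    )
    include = [(l, r) for l, r, _, _ in truth.planted_interactions]
    src_paths, source_truth, _ = sim.simulate_catalog_sources(
        source_config, paths["root"], include_pairs=include
    )
    truth.catalog_source_truth = set(source_truth.pairs)
    paths.update({"dlrp": src_paths["dlrp"], "biogrid": src_paths["biogrid"],
                  "kgml": src_paths["kgml"], "go": src_paths["go"]})

    signatures = sim.simulate_signatures(list(matrix.genes), set(truth.de_genes),
                                         seed=config.seed + 2)
    write_gmt(signatures, paths["signatures"])

    intra = sim.simulate_intra_network(list(matrix.genes),
                                       n_extra_edges=config.n_intra_extra_edges,
                                       seed=config.seed + 3)
    write_sif(intra, paths["intra_sif"])

    sc_de = truth.de_genes_for("SC")
    overlaps = list(config.injury_overlaps)
    if overlaps and max(overlaps) > len(sc_de):
        # fewer planted tumor DEGs than requested: scale proportionally so
        # the planted day ordering (and argmax) is preserved
        factor = len(sc_de) / max(overlaps)
        overlaps = [int(o * factor) for o in overlaps]
    truth.injury_day_sets = sim.simulate_injury_sets(
        list(config.injury_days), list(config.injury_set_sizes), overlaps,
        tumor_degs=sc_de, universe=set(matrix.genes), seed=config.seed + 4,
    )
    paths["injury_json"].write_text(json.dumps(
        {str(d): sorted(s) for d, s in sorted(truth.injury_day_sets.items())}, indent=1))
    truth.to_json(paths["ground_truth"])
    return [paths[k] for k in _STAGE_OUTPUTS["simulate"]]


def _stage_preprocess(config: RunConfig, paths: dict[str, Path]) -> list[Path]:
    _require("preprocess", paths, ["expression", "sample_meta", "ortholog"])
    matrix = _read_matrix(paths, preprocessed=False)
    matrix = prep.filter_orthologs(matrix, read_ortholog_table(paths["ortholog"]))
    if matrix.sample_meta["batch"].nunique() > 1:
        matrix = prep.combat_adjust(matrix)
    write_expression(matrix, paths["pre_expression"], paths["pre_meta"])
    return [paths["pre_expression"], paths["pre_meta"]]


def _stage_deg(config: RunConfig, paths: dict[str, Path]) -> list[Path]:
    _require("deg", paths, ["pre_expression", "pre_meta"])
    matrix = _read_matrix(paths, preprocessed=True)
    for cell, out_key in (("SC", "deg_sc"), ("MAC", "deg_mac")):
        table = deg_mod.deg_table(
            matrix, (cell, sim.TUMOR_GROUP), (cell, sim.CONTRAST_GROUP)
        )
        table = deg_mod.call_degs(table, fold_cut=config.fold_cut, q_cut=config.q_cut)
        deg_mod.write_deg_table(table, paths[out_key])
    return [paths["deg_sc"], paths["deg_mac"]]


def _stage_catalog(config: RunConfig, paths: dict[str, Path]) -> list[Path]:
    for key, name in (("dlrp", "dlrp_pairs.txt"), ("biogrid", "biogrid_tab2.tsv"),
                      ("kgml", "kegg_pathway.xml"), ("go", "go_annotations.tsv")):
        paths.setdefault(key, paths["root"] / name)
    _require("catalog", paths, ["dlrp", "biogrid", "kgml", "go"])
    annotations = cat.read_go_annotations(paths["go"])
    ligands, receptors = cat.classify_by_go(
        annotations,
        ligand_terms=("extracellular region", "cytokine activity"),
        receptor_terms=("receptor activity", "plasma membrane"),
    )
    merged = cat.merge_dedup([
        cat.parse_dlrp(paths["dlrp"]),
        cat.parse_biogrid_tab2(paths["biogrid"], ligands, receptors),
        cat.parse_kgml(paths["kgml"]),
    ])
    write_catalog(merged, paths["catalog"])
    return [paths["catalog"]]


def _stage_interactome(config: RunConfig, paths: dict[str, Path]) -> list[Path]:
    _require("interactome", paths, ["pre_expression", "deg_sc", "deg_mac", "catalog"])
    matrix = _read_matrix(paths, preprocessed=True)
    catalog = read_catalog(paths["catalog"])
    cutoff = inter.compute_presence_cutoff(matrix)
    group_means = {cell: matrix.group_means(cell, sim.TUMOR_GROUP) for cell in ("SC", "MAC")}
    degs = {
        "SC": pd.read_csv(paths["deg_sc"], sep="\t", index_col=0),
        "MAC": pd.read_csv(paths["deg_mac"], sep="\t", index_col=0),
    }
    calls, skipped = inter.call_interactions(
        catalog, group_means, degs, cutoff, require_de=config.require_de
    )
    inter.export_map(calls, paths["calls_dot"], paths["calls_tsv"])
    pd.DataFrame(skipped, columns=["gene", "reason"]).to_csv(
        paths["skipped"], sep="\t", index=False)
    return [paths["calls_tsv"], paths["calls_dot"], paths["skipped"]]


def _stage_netwalk(config: RunConfig, paths: dict[str, Path]) -> list[Path]:
    _require("netwalk", paths, ["deg_sc", "deg_mac", "catalog", "intra_sif"])
    catalog = read_catalog(paths["catalog"])
    intra = read_sif(paths["intra_sif"])
    t_by_cell = {}
    for cell, key in (("SC", "deg_sc"), ("MAC", "deg_mac")):
        table = pd.read_csv(paths[key], sep="\t", index_col=0)
        t_by_cell[cell] = table["t_mod"]
    network, weights, flux_table = nw.run_netwalk(
        intra, catalog, t_by_cell,
        restart=config.restart, tol=config.rwr_tol, max_iter=config.rwr_max_iter,
    )
    nw.write_flux_table(flux_table, paths["flux"])
    top = nw.top_subnetwork(flux_table, min(config.top_k, len(flux_table.flux)))
    top.to_csv(paths["subnet_tsv"], sep="\t", index=False, float_format="%.8g")
    nw.subnetwork_to_dot(top, paths["subnet_dot"])
    return [paths["flux"], paths["subnet_dot"], paths["subnet_tsv"]]


def _stage_efa(config: RunConfig, paths: dict[str, Path]) -> list[Path]:
    _require("efa", paths, ["pre_expression", "deg_sc", "deg_mac"])
    matrix = _read_matrix(paths, preprocessed=True)
    deg_sets = {}
    for cell, key in (("SC", "deg_sc"), ("MAC", "deg_mac")):
        table = pd.read_csv(paths[key], sep="\t", index_col=0)
        deg_sets[cell] = set(table.index[table["called"]])
    if not (deg_sets["SC"] | deg_sets["MAC"]):
        # nothing differentially expressed: factor clustering has no feature
        # set; write empty outputs so the bundle stays complete
        for key, header in (("map_criterion", "m\tavg_sq_partial"),
                            ("loadings", "gene"), ("scores", "sample\tcell_type\tgroup")):
            paths[key].write_text(header + "\n")
        return [paths["map_criterion"], paths["loadings"], paths["scores"]]
    catalog = read_catalog(paths["catalog"]) if paths["catalog"].exists() else None
    signatures = (
        {n: s for n, s in read_gmt(paths["signatures"]).items()}
        if paths["signatures"].exists() else None
    )
    map_result, model, scores = efa_mod.efa_cluster(
        matrix, config.efa_mode, deg_sets, catalog=catalog, signatures=signatures,
        max_m=config.max_m, min_factors=2,
    )
    map_result.as_series().to_csv(paths["map_criterion"], sep="\t",
                                  index_label="m", float_format="%.8g")
    model.loadings.to_csv(paths["loadings"], sep="\t", index_label="gene",
                          float_format="%.6g")
    out_scores = scores.copy()
    out_scores.insert(0, "group", matrix.sample_meta.loc[scores.index, "group"].to_numpy())
    out_scores.insert(0, "cell_type",
                      matrix.sample_meta.loc[scores.index, "cell_type"].to_numpy())
    out_scores.to_csv(paths["scores"], sep="\t", index_label="sample", float_format="%.6g")
    return [paths["map_criterion"], paths["loadings"], paths["scores"]]


def _stage_enrich(config: RunConfig, paths: dict[str, Path]) -> list[Path]:
    _require("enrich", paths, ["deg_sc", "signatures", "pre_expression"])
    matrix = _read_matrix(paths, preprocessed=True)
    table = pd.read_csv(paths["deg_sc"], sep="\t", index_col=0)
    query = set(table.index[table["called"]])
    sets = enr.signatures_from_gmt(read_gmt(paths["signatures"]))
    if not query:
        frame = pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p", "q", "significant"])
    else:
        frame = enr.enrich(query, sets, universe=set(matrix.genes), q_cut=config.q_cut)
    frame.to_csv(paths["enrichment"], sep="\t", index=False, float_format="%.6g")
    return [paths["enrichment"]]


def _stage_overlap(config: RunConfig, paths: dict[str, Path]) -> list[Path]:
    _require("overlap", paths, ["deg_sc", "injury_json", "pre_expression"])
    matrix = _read_matrix(paths, preprocessed=True)
    table = pd.read_csv(paths["deg_sc"], sep="\t", index_col=0)
    recalled = deg_mod.call_degs(table, fold_cut=config.injury_fold_cut, q_cut=config.q_cut)
    tumor = set(recalled.index[recalled["called"]])
    injury = {int(d): set(s)
              for d, s in json.loads(paths["injury_json"].read_text()).items()}
    if not tumor:
        frame = pd.DataFrame(columns=["day", "overlap", "set_size", "jaccard", "p"])
        frame.attrs["argmax_days"] = []
        frame.attrs["argmax_defined"] = False
    else:
        frame = enr.timecourse_overlap(tumor, injury, universe=set(matrix.genes))
    frame.to_csv(paths["overlap"], sep="\t", index=False, float_format="%.6g")
    argmax_path = paths["overlap"]
    with open(argmax_path, "a") as fh:
        days = ",".join(str(d) for d in frame.attrs.get("argmax_days", []))
        fh.write(f"# argmax_days\t{days or 'undefined'}\n")
    return [paths["overlap"]]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "deg": _stage_deg,
    "catalog": _stage_catalog,
    "interactome": _stage_interactome,
    "netwalk": _stage_netwalk,
    "efa": _stage_efa,
    "enrich": _stage_enrich,
    "overlap": _stage_overlap,
}


def run_stage(name: str, config: RunConfig, log: list[str] | None = None) -> list[Path]:
    """Run one stage; outputs land under `config.out_dir`.

    Dependency checking is file-based: a missing prerequisite output raises a
    DataError naming the stage to run first.
    """
    if name not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {name!r} (choose from {list(STAGE_ORDER)})")
    config.validate()
    paths = _paths(config)
    paths["root"].mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    outputs = _STAGE_FUNCS[name](config, paths)
    elapsed = time.perf_counter() - t0
    line = (f"stage={name} seed={config.seed} wall_s={elapsed:.2f} "
            f"outputs={[p.name for p in outputs]}")
    if log is not None:
        log.append(line)
    return outputs


def run_all(config: RunConfig) -> dict:
    """Execute every stage, then write manifest, resolved config and summary.

    Returns the manifest dictionary. The manifest holds only content
    checksums (no timings), so reruns with identical config and seed are
    byte-identical.
    """
    config.validate()
    paths = _paths(config)
    paths["root"].mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    produced: dict[str, list[Path]] = {}
    for name in STAGE_ORDER:
        produced[name] = run_stage(name, config, log=log)
    config.to_yaml(paths["config"])

    manifest = {"stages": {}, "config_file": paths["config"].name}
    for name in STAGE_ORDER:
        manifest["stages"][name] = {
            p.name: _sha256(p) for p in sorted(produced[name])
        }
    manifest["stages"]["config"] = {paths["config"].name: _sha256(paths["config"])}
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["log"].write_text("\n".join(log) + "\n")
    _write_summary(config, paths)
    return manifest


def _write_summary(config: RunConfig, paths: dict[str, Path]) -> None:
    lines = ["bicellnet run summary", "====================="]
    truth = sim.GroundTruth.from_json(paths["ground_truth"])
    for cell, key in (("SC", "deg_sc"), ("MAC", "deg_mac")):
        table = pd.read_csv(paths[key], sep="\t", index_col=0)
        called = set(table.index[table["called"]])
        planted = truth.de_genes_for(cell)
        recovered = len(called & planted)
        lines.append(
            f"DEG {cell}: {len(called)} called; planted {len(planted)}, recovered {recovered}"
        )
    calls = pd.read_csv(paths["calls_tsv"], sep="\t")
    lines.append(f"Interaction calls: {len(calls)} "
                 f"({(calls['mode'] == 'autocrine').sum()} autocrine, "
                 f"{(calls['mode'] == 'paracrine').sum()} paracrine)")
    call_keys = {(r.ligand, r.receptor, r.sender, r.receiver) for r in calls.itertuples()}
    hits = [t for t in truth.planted_interactions if tuple(t) in call_keys]
    lines.append(f"Planted LR loops recovered as calls: {len(hits)}/{len(truth.planted_interactions)}")
    for t in hits:
        lines.append(f"  planted+called: {t[0]}->{t[1]} ({t[2]}->{t[3]})")
    top = pd.read_csv(paths["subnet_tsv"], sep="\t")
    lines.append(f"NetWalk: top subnetwork holds {len(top)} edges "
                 f"({(top['edge_type'] == 'inter').sum()} ligand-receptor)")
    overlap = pd.read_csv(paths["overlap"], sep="\t", comment="#")
    if len(overlap):
        best = overlap.loc[overlap["overlap"].idxmax()]
        lines.append(f"Injury overlap: max at day {int(best['day'])} "
                     f"({int(best['overlap'])} genes)")
    enrich_table = pd.read_csv(paths["enrichment"], sep="\t")
    if len(enrich_table):
        topset = enrich_table.iloc[0]
        lines.append(f"Top enriched set: {topset['set_name']} (p={topset['p']:.3g})")
    paths["summary"].write_text("\n".join(lines) + "\n")
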