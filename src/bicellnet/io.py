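"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression TSV: genes x samples with a header row of sample IDs and the gene
symbol in the first column. Sample metadata TSV: sample, cell_type, group,
batch, replicate. GMT: one gene set per line (name, source/description,
genes...). SIF: ``node<TAB>relation<TAB>node`` edge list. Ortholog TSV:
source_symbol, target_symbol, support_flag.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import ExpressionMatrix, LRCatalog, LRPair
from .errors import DataError, ParseError


# -- expression matrices -------------------------------------------------------

def read_expression(values_path, meta_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"batch": str})
    return ExpressionMatrix(values, meta)


def write_expression(matrix: ExpressionMatrix, values_path, meta_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene", float_format="%.6f")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


# -- gene sets (GMT) -----------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set name: gene set}`` (descriptions dropped)."""
    sets: dict[str, set[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError("GMT line needs name, description and >=1 gene", line=i)
        genes = {g.strip().upper() for g in fields[2:] if g.strip()}
        if not genes:
            raise ParseError(f"gene set {fields[0]!r} is empty", line=i)
        sets[fields[0]] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path, source: str = "bicellnet") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{source}\t{genes}\n")


# -- SIF edge lists ------------------------------------------------------------

def read_sif(path) -> list[tuple[str, str]]:
    """Read a SIF edge list; returns unique undirected edges, symbols uppercased."""
    edges: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError("SIF line needs source, relation, target", line=i)
        a, b = fields[0].strip().upper(), fields[2].strip().upper()
        if a == b:
            continue  # self-loops are dropped: the walk forbids them
        key = frozenset((a, b))
        if key not in seen:
            seen.add(key)
            edges.append((a, b))
    return edges


def write_sif(edges, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{relation}\t{b}\n")


# -- ortholog tables -----------------------------------------------------------

def read_ortholog_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_symbol", "target_symbol", "support_flag"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"ortholog table missing columns: {sorted(missing)}")
    return table


def write_ortholog_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- ligand-receptor catalogs --------------------------------------------------

def write_catalog(catalog: LRCatalog, path) -> None:
    """Catalog TSV in bit-stable (ligand, receptor) lexicographic order."""
    with open(path, "w") as fh:
        fh.write("ligand\treceptor\tsources\n")
        for pair in catalog.sorted_pairs():
            fh.write(f"{pair.ligand}\t{pair.receptor}\t{','.join(sorted(pair.sources))}\n")


def read_catalog(path) -> LRCatalog:
    table = pd.read_csv(path, sep="\t", dtype=str)
    pairs = [
        LRPair(row.ligand, row.receptor,
               frozenset(str(row.sources).split(",")) if pd.notna(row.sources) else frozenset())
        for row in table.itertuples()
    ]
    return LRCatalog.from_pairs(pairs)
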