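"""Compilation of a directional ligand->receptor catalog from three sources.

Sources arrive in three dialects — a DLRP-style flat text of ligand/receptor
blocks, a BioGrid TAB2 interaction table, and a KEGG KGML pathway XML — and
are merged into one deduplicated catalog with per-source provenance. Gene
roles (secreted ligand vs membrane receptor) come from configurable GO term
lists; orthology translation uses the same strong (one-to-one, flagged)
mapping rule as the expression filter.

Pairs are directional: (A, B) and (B, A) are distinct records.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from lxml import etree

from .datatypes import LRCatalog, LRPair
from .errors import ConfigError, DataError, ParseError
from .preprocess import one_to_one_map

DLRP, BIOGRID, KEGG = "DLRP", "BIOGRID", "KEGG"

#: BioGrid TAB2 columns the parser requires.
TAB2_REQUIRED = (
    "Official Symbol Interactor A",
    "Official Symbol Interactor B",
    "Experimental System Type",
)


# -- GO-based role classification ----------------------------------------------

def classify_by_go(
    annotations: dict[str, set[str]],
    ligand_terms: Iterable[str],
    receptor_terms: Iterable[str],
) -> tuple[set[str], set[str]]:
    """Split genes into ligand and receptor candidates by GO annotation.

    A gene lands in the ligand set iff it carries any configured ligand term
    (e.g. "extracellular region", "cytokine activity"), in the receptor set
    iff it carries any receptor term; membership in both is allowed.
    """
    ligand_terms = {t.strip().lower() for t in ligand_terms if t and t.strip()}
    receptor_terms = {t.strip().lower() for t in receptor_terms if t and t.strip()}
    if not ligand_terms or not receptor_terms:
        raise ConfigError("both ligand and receptor GO term lists must be non-empty")
    ligands, receptors = set(), set()
    for gene, terms in annotations.items():
        lowered = {t.strip().lower() for t in terms}
        g = gene.strip().upper()
        if lowered & ligand_terms:
            ligands.add(g)
        if lowered & receptor_terms:
            receptors.add(g)
    return ligands, receptors


def read_go_annotations(path) -> dict[str, set[str]]:
    """GO annotation TSV (columns: gene, go_id, go_name) -> gene -> term names."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "go_name"} - set(table.columns)
    if missing:
        raise DataError(f"GO annotation table missing columns: {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for row in table.itertuples():
        out.setdefault(str(row.gene).strip().upper(), set()).add(str(row.go_name))
    return out


# -- DLRP-style flat text ------------------------------------------------------

def parse_dlrp(source) -> list[LRPair]:
    """Parse DLRP-style blocks into directional pairs.

    Dialect: blank-line-separated blocks of two tab-separated records,
    ``LIGAND<TAB>sym...`` and ``RECEPTOR<TAB>sym...``; every ligand x receptor
    combination within a block is one pair.
    """
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    pairs: list[LRPair] = []
    block_ligands: list[str] = []
    block_receptors: list[str] = []
    block_start: int | None = None

    def flush(line_no: int) -> None:
        nonlocal block_ligands, block_receptors, block_start
        if not block_ligands and not block_receptors:
            return
        if not block_ligands:
            raise ParseError("block has no LIGAND record", line=block_start)
        if not block_receptors:
            raise ParseError("block has no RECEPTOR record", line=block_start)
        for lig in block_ligands:
            for rec in block_receptors:
                pairs.append(LRPair(lig, rec, frozenset({DLRP})))
        block_ligands, block_receptors, block_start = [], [], None

    lines = text.splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            flush(i)
            continue
        fields = [f.strip() for f in line.split("\t")]
        tag, symbols = fields[0].upper(), [s for s in fields[1:] if s]
        if tag not in ("LIGAND", "RECEPTOR"):
            raise ParseError(f"expected LIGAND or RECEPTOR record, got {fields[0]!r}", line=i)
        if not symbols:
            raise ParseError(f"{tag} record lists no gene symbols", line=i)
        if block_start is None:
            block_start = i
        (block_ligands if tag == "LIGAND" else block_receptors).extend(symbols)
    flush(len(lines) + 1)
    return pairs


# -- BioGrid TAB2 --------------------------------------------------------------

def parse_biogrid_tab2(
    source,
    ligand_set: set[str],
    receptor_set: set[str],
    evidence_filter: Iterable[str] = ("physical",),
) -> list[LRPair]:
    """Extract experimentally supported ligand->receptor rows from TAB2.

    A row is kept iff its "Experimental System Type" is in `evidence_filter`
    (default: physical evidence only, excluding genetic screens) and one
    interactor is a known ligand while the other is a known receptor; the
    pair is oriented ligand -> receptor. Records orientable both ways emit
    both directions.
    """
    table = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in TAB2_REQUIRED if c not in table.columns]
    if missing:
        raise ParseError(f"TAB2 file missing required columns: {missing}")
    ligand_set = {g.upper() for g in ligand_set}
    receptor_set = {g.upper() for g in receptor_set}
    evidence = {e.strip().lower() for e in evidence_filter}
    pairs: list[LRPair] = []
    sys_types = table["Experimental System Type"].astype(str).str.strip().str.lower()
    col_a = table["Official Symbol Interactor A"].astype(str).str.strip().str.upper()
    col_b = table["Official Symbol Interactor B"].astype(str).str.strip().str.upper()
    for sys_type, a, b in zip(sys_types, col_a, col_b):
        if sys_type not in evidence:
            continue
        if a in ligand_set and b in receptor_set:
            pairs.append(LRPair(a, b, frozenset({BIOGRID})))
        if b in ligand_set and a in receptor_set:
            pairs.append(LRPair(b, a, frozenset({BIOGRID})))
    return pairs


# -- KEGG KGML -----------------------------------------------------------------

def parse_kgml(source) -> list[LRPair]:
    """Parse KGML gene-gene relations as ligand->receptor pairs.

    entry1 of each relation is read as the ligand side, entry2 as the
    receptor side; entries naming several genes are expanded combinatorially.
    Entry ``name`` attributes may carry organism prefixes (``mmu:Csf1``),
    which are stripped.
    """
    try:
        if hasattr(source, "read"):
            tree = etree.parse(source)
        else:
            tree = etree.parse(str(source))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"invalid KGML XML: {exc}") from exc
    root = tree.getroot()
    entries: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        if entry.get("type") != "gene":
            continue
        names = []
        for token in (entry.get("name") or "").split():
            sym = token.split(":", 1)[-1].strip()
            if sym:
                names.append(sym.upper())
        entries[entry.get("id")] = names
    pairs: list[LRPair] = []
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 not in entries or e2 not in entries:
            raise ParseError(f"relation references unknown entry id {e1 if e1 not in entries else e2!r}")
        for lig in entries[e1]:
            for rec in entries[e2]:
                pairs.append(LRPair(lig, rec, frozenset({KEGG})))
    return pairs


# -- merging and orthology -----------------------------------------------------

def merge_dedup(catalogs: Iterable[Iterable[LRPair]]) -> LRCatalog:
    """Union over ordered (ligand, receptor) keys, accumulating provenance."""
    catalogs = list(catalogs)
    if not catalogs:
        raise DataError("merge_dedup needs at least one input list")
    all_pairs: list[LRPair] = [p for cat in catalogs for p in cat]
    return LRCatalog.from_pairs(all_pairs)


def orthology_map(catalog: LRCatalog, ortholog_table: pd.DataFrame) -> LRCatalog:
    """Translate both members through the strong-ortholog map; drop pairs with
    an unmappable member and re-deduplicate (collisions merge provenance)."""
    mapping = one_to_one_map(ortholog_table)
    translated = []
    for pair in catalog.sorted_pairs():
        lig, rec = mapping.get(pair.ligand), mapping.get(pair.receptor)
        if lig is None or rec is None:
            continue
        translated.append(LRPair(lig, rec, pair.sources))
    return LRCatalog.from_pairs(translated)


def catalog_summary(catalog: LRCatalog) -> dict[str, int]:
    return {
        "pairs": len(catalog),
        "ligands": len(catalog.ligand_set),
        "receptors": len(catalog.receptor_set),
    }
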