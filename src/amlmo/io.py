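"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain tab-separated text with the literal token
``NA`` for missing values.  Trees are standard Newick with branch
lengths; gene sets are GMT; ontology edges are two-column child/parent
TSV.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import Phylo

from .model import (
    AnnotationCatalog,
    Dendrogram,
    ExpressionMatrix,
    FormatError,
    IdMap,
    ProteinQuantTable,
    SampleDesign,
)

MISSING_TOKEN = "NA"


def _read_rectangular_tsv(path: str | Path, missing_token: str) -> pd.DataFrame:
    """Parse a TSV with row/column headers, rejecting ragged rows and
    duplicate identifiers with actionable messages."""
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not rec:
                continue
            if rows and len(rec) != len(rows[0]):
                raise FormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(rec)} fields, expected {len(rows[0])})"
                )
            rows.append(rec)
    if len(rows) < 2:
        raise FormatError(f"{path}: expected a header row and at least one data row")
    header = rows[0][1:]
    index = [r[0] for r in rows[1:]]
    for ids, axis in ((header, "column"), (index, "row")):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise FormatError(f"{path}: duplicate {axis} identifier {x!r}")
            seen.add(x)
    data = np.array(
        [[np.nan if v == missing_token else float(v) for v in r[1:]] for r in rows[1:]],
        dtype=float,
    ).reshape(len(index), len(header))
    return pd.DataFrame(data, index=index, columns=header)


def read_expression_matrix(
    path: str | Path, missing_token: str = MISSING_TOKEN, dataset_label: str | None = None
) -> ExpressionMatrix:
    """Read a features x samples log2 intensity TSV (first row sample ids,
    first column feature ids)."""
    df = _read_rectangular_tsv(path, missing_token)
    return ExpressionMatrix(df, dataset_label=dataset_label or Path(path).stem)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, missing_token: str = MISSING_TOKEN
) -> None:
    df = matrix.values
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(df.columns) + "\n")
        for fid, row in zip(df.index, df.to_numpy()):
            cells = [missing_token if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def read_sample_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "replicate_index" in df.columns:
        df["replicate_index"] = df["replicate_index"].astype(int)
    return SampleDesign(df)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_protein_table(path: str | Path, missing_token: str = MISSING_TOKEN) -> ProteinQuantTable:
    """Read a proteins x conditions SLR TSV (NA = not detected)."""
    df = _read_rectangular_tsv(path, missing_token)
    return ProteinQuantTable(df)


def write_protein_table(
    table: ProteinQuantTable, path: str | Path, missing_token: str = MISSING_TOKEN
) -> None:
    df = table.slr
    with open(path, "w") as fh:
        fh.write("protein_id\t" + "\t".join(df.columns) + "\n")
        for pid, row in zip(df.index, df.to_numpy()):
            cells = [missing_token if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def read_id_map(path: str | Path) -> IdMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return IdMap(df)


def write_id_map(idmap: IdMap, path: str | Path) -> None:
    idmap.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a GMT file: term <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    term_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line {lineno} has fewer than 3 columns")
            term, desc, genes = parts[0], parts[1], parts[2:]
            if term in term_genes:
                raise FormatError(f"{path}: duplicate term {term!r} at line {lineno}")
            term_genes[term] = {g for g in genes if g}
            term_names[term] = desc
    return term_genes, term_names


def read_ontology_edges(path: str | Path) -> dict[str, set[str]]:
    """Read child <TAB> parent edges."""
    parents: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: edge line {lineno} must have 2 columns")
            parents.setdefault(parts[0], set()).add(parts[1])
    return parents


def read_annotation_catalog(gmt_path: str | Path, edges_path: str | Path | None = None) -> AnnotationCatalog:
    term_genes, term_names = read_gmt(gmt_path)
    parents = read_ontology_edges(edges_path) if edges_path else {}
    return AnnotationCatalog(term_genes, parents, term_names)


# --- Newick -----------------------------------------------------------------

def newick_string(tree: Dendrogram) -> str:
    """Serialise so that every leaf-to-root path length equals the root
    height (ultrametric branch lengths)."""
    n = tree.n_leaves

    def render(node: int, parent_height: float) -> str:
        h = tree.node_height(node)
        branch = parent_height - h
        if node < n:
            return f"{tree.leaf_labels[node]}:{branch:.10g}"
        left, right, _ = tree.merges[node - n]
        return f"({render(left, h)},{render(right, h)}):{branch:.10g}"

    root = n + len(tree.merges) - 1
    root_h = tree.node_height(root)
    left, right, _ = tree.merges[-1]
    return f"({render(left, root_h)},{render(right, root_h)});"


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def read_newick(path_or_text: str | Path) -> Dendrogram:
    """Parse an ultrametric binary Newick tree back into merge-list form."""
    text = str(path_or_text)
    if "(" not in text:
        text = Path(path_or_text).read_text()
    phylo = Phylo.read(_stdio.StringIO(text), "newick")
    leaves = sorted(phylo.get_terminals(), key=lambda c: str(c.name))
    labels = [str(c.name) for c in leaves]
    index = {c: i for i, c in enumerate(leaves)}

    entries: list[tuple[float, object, object, object]] = []

    def height(clade) -> float:
        if clade.is_terminal():
            return 0.0
        child = clade.clades[0]
        return height(child) + (child.branch_length or 0.0)

    def walk(clade):
        if not clade.is_terminal():
            if len(clade.clades) != 2:
                raise FormatError("only binary trees round-trip to a merge list")
            for ch in clade.clades:
                walk(ch)
            entries.append((height(clade), clade, clade.clades[0], clade.clades[1]))

    walk(phylo.root)
    entries.sort(key=lambda e: e[0])
    node_of: dict[object, int] = dict(index)
    merges: list[tuple[int, int, float]] = []
    for h, clade, left, right in entries:
        node_of[clade] = len(labels) + len(merges)
        merges.append((node_of[left], node_of[right], float(h)))
    return Dendrogram(labels, merges)


# --- Deregulation sets and JSON reports -------------------------------------

def write_feature_set(features: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{f}\n" for f in sorted(features)))


def read_feature_set(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_json_report(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o: object):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


# --- Packaged fixtures ------------------------------------------------------

def load_cell_line_slr_table() -> tuple[ProteinQuantTable, IdMap]:
    """The 55 proteins commonly deregulated in the three AML cell lines
    versus control HPSCs, with their mean SLR per cell line, as printed in
    the study this pipeline models; plus the protein-to-gene id map."""
    ref = resources.files("amlmo.data").joinpath("table2_slr.tsv")
    df = pd.read_csv(_stdio.StringIO(ref.read_text()), sep="\t", dtype=str)
    slr = df[["MLP3-cl", "RF12-cl", "RF26-cl"]].astype(float)
    slr.index = df["protein_id"]
    idmap = IdMap(df[["protein_id", "gene_id", "gene_symbol"]].copy())
    return ProteinQuantTable(slr), idmap
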