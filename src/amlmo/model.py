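"""Domain types shared across the multi-omic AML analysis pipeline.

The pipeline integrates bulk transcriptome intensities (log2 scale,
features x samples) with label-based proteome quantifications expressed as
signal log2 ratios (SLR) versus a healthy haematopoietic progenitor/stem
cell (HPSC) control.  The study design distinguishes three material
classes besides the control: AML cell lines, primary AMLs, and an in-vivo
passaged cell line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MATERIAL_CLASSES = ("control", "primary", "cell_line", "ivp")
LINES = ("MLP3", "RF12", "RF26", "none")

#: The six experimental materials of the reference study design, in the
#: canonical order used throughout: three cell lines, two primaries, one
#: in-vivo passage.
DEFAULT_MATERIALS = (
    "MLP3-cl",
    "RF12-cl",
    "RF26-cl",
    "RF12-p",
    "RF26-p",
    "MLP3-ivp",
)

SIGNATURE_PATTERNS = (
    "concordant_up",
    "concordant_down",
    "discordant_gene_up",
    "discordant_gene_down",
)


class FormatError(ValueError):
    """An on-disk artefact violates its declared format."""


class ValidationError(ValueError):
    """An in-memory object violates a type invariant."""


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {axis} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log2 intensity matrix, features in rows, samples in columns.

    ``values`` is a pandas DataFrame indexed by feature id with sample ids
    as columns; missing measurements are NaN (never a sentinel number).
    """

    values: pd.DataFrame
    dataset_label: str = "default"

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "feature")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValidationError("expression matrix contains infinite values")
        self.values = pd.DataFrame(
            arr, index=self.values.index.astype(str), columns=self.values.columns.astype(str)
        )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in feature_ids if f in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], dataset_label=self.dataset_label)


@dataclass
class SampleDesign:
    """Per-sample annotation: material class, AML line, dataset, replicate."""

    table: pd.DataFrame  # columns: sample_id, material_class, line, dataset_label, replicate_index

    REQUIRED = ("sample_id", "material_class", "line", "dataset_label", "replicate_index")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample design missing columns: {missing}")
        t = self.table
        _check_unique(list(t["sample_id"]), "sample")
        bad = sorted(set(t["material_class"]) - set(MATERIAL_CLASSES))
        if bad:
            raise ValidationError(
                f"unknown material_class {bad}; allowed: {list(MATERIAL_CLASSES)}"
            )
        bad = sorted(set(t["line"].astype(str)) - set(LINES))
        if bad:
            raise ValidationError(f"unknown line {bad}; allowed: {list(LINES)}")
        ctrl = t[t["material_class"] == "control"]
        if (ctrl["line"] != "none").any():
            offender = ctrl[ctrl["line"] != "none"]["sample_id"].iloc[0]
            raise ValidationError(
                f"control sample {offender!r} must have line='none'"
            )
        if (t["replicate_index"].astype(int) < 1).any():
            raise ValidationError("replicate_index must be >= 1")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_where(self, **conditions: str) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.loc[mask, "sample_id"])

    def material_of(self, sample_id: str) -> str:
        """Group label: 'control' for controls, else '<line>-<class tag>'."""
        row = self.table.set_index("sample_id").loc[sample_id]
        return material_label(row["material_class"], row["line"])

    def group_labels(self) -> pd.Series:
        """Material group label per sample, indexed by sample id."""
        return pd.Series(
            [
                material_label(mc, ln)
                for mc, ln in zip(self.table["material_class"], self.table["line"])
            ],
            index=self.table["sample_id"].to_numpy(),
            name="group",
        )

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(matrix.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"samples without design rows: {sorted(missing)}")


_CLASS_TAG = {"cell_line": "cl", "primary": "p", "ivp": "ivp"}


def material_label(material_class: str, line: str) -> str:
    if material_class == "control":
        return "control"
    return f"{line}-{_CLASS_TAG[material_class]}"


@dataclass
class ProteinQuantTable:
    """Mean protein SLR (log2 ratio vs control) per experimental material.

    ``slr`` is proteins x conditions with NaN marking non-detection;
    ``imputed`` optionally flags cells filled in by imputation.
    """

    slr: pd.DataFrame
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(list(self.slr.index), "protein")
        _check_unique(list(self.slr.columns), "condition")
        if self.slr.shape[1] < 1:
            raise ValidationError("protein table needs at least one condition")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.slr.index, columns=self.slr.columns
            )
        elif self.imputed.shape != self.slr.shape:
            raise ValidationError("imputation flag matrix must match slr shape")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.slr.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.slr.columns)

    @property
    def detected_count(self) -> pd.Series:
        return self.slr.notna().sum(axis=1)


@dataclass
class IdMap:
    """Protein id -> (gene id, gene symbol) mapping."""

    table: pd.DataFrame  # columns protein_id, gene_id, gene_symbol

    def __post_init__(self) -> None:
        missing = [c for c in ("protein_id", "gene_id", "gene_symbol") if c not in self.table.columns]
        if missing:
            raise FormatError(f"id map missing columns: {missing}")
        _check_unique(list(self.table["protein_id"]), "protein")
        for col in ("protein_id", "gene_id", "gene_symbol"):
            vals = self.table[col].astype(str)
            if (vals.str.len() == 0).any() or vals.isna().any():
                raise ValidationError(f"id map has empty values in column {col!r}")
        self.table = self.table.reset_index(drop=True)

    def gene_of(self, protein_id: str) -> str | None:
        hits = self.table.loc[self.table["protein_id"] == protein_id, "gene_id"]
        return None if hits.empty else str(hits.iloc[0])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DeregulationSet:
    """Directional altered-feature sets for one experimental material."""

    material_label: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValidationError(
                f"features both up and down in {self.material_label}: {sorted(overlap)[:5]}"
            )

    @property
    def all(self) -> set[str]:
        return self.up | self.down

    def direction_of(self, feature: str) -> str:
        if feature in self.up:
            return "up"
        if feature in self.down:
            return "down"
        return "none"


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    Nodes are integers: leaves ``0..n-1`` (in ``leaf_labels`` order),
    internal nodes ``n, n+1, ...`` in merge order.  ``merges`` lists
    ``(left, right, height)`` with non-decreasing heights, scipy-linkage
    style.
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        _check_unique(self.leaf_labels, "leaf")
        if any(not lbl for lbl in self.leaf_labels):
            raise ValidationError("leaf labels must be non-empty")
        if len(self.merges) != n - 1:
            raise ValidationError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        prev = -np.inf
        for left, right, h in self.merges:
            if h < 0:
                raise ValidationError("merge heights must be non-negative")
            if h < prev - 1e-9:
                raise ValidationError("merge heights must be non-decreasing")
            prev = max(prev, h)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else self.merges[node - n][2]

    def leaves_under(self, node: int) -> set[int]:
        n = self.n_leaves
        if node < n:
            return {node}
        left, right, _ = self.merges[node - n]
        return self.leaves_under(left) | self.leaves_under(right)

    def cophenetic(self, label_a: str, label_b: str) -> float:
        """Merge height at which two leaves first join."""
        ia, ib = self.leaf_labels.index(label_a), self.leaf_labels.index(label_b)
        if ia == ib:
            return 0.0
        for node_offset, (_, _, h) in enumerate(self.merges):
            under = self.leaves_under(self.n_leaves + node_offset)
            if ia in under and ib in under:
                return h
        raise ValidationError("tree does not connect all leaves")

    def cut_two(self) -> tuple[set[str], set[str]]:
        """Partition induced by removing the final (root) merge."""
        left, right, _ = self.merges[-1]
        la = {self.leaf_labels[i] for i in self.leaves_under(left)}
        lb = {self.leaf_labels[i] for i in self.leaves_under(right)}
        return la, lb

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf ordering of the merge tree (heatmap order)."""
        root = self.n_leaves + len(self.merges) - 1

        def walk(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            left, right, _ = self.merges[node - self.n_leaves]
            return walk(left) + walk(right)

        return [self.leaf_labels[i] for i in walk(root)]


@dataclass
class AnnotationCatalog:
    """Gene-set annotations plus the child -> parents relation of the ontology."""

    term_genes: dict[str, set[str]]
    parents: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.term_genes:
                    raise ValidationError(
                        f"edge references unknown parent term {p!r}"
                    )
            if child not in self.term_genes:
                raise ValidationError(f"edge references unknown child term {child!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.term_genes)
        for child, ps in self.parents.items():
            g.add_edges_from((child, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("ontology parent graph contains a cycle")
        self._graph = g

    @property
    def terms(self) -> list[str]:
        return list(self.term_genes)

    def parents_of(self, term: str) -> set[str]:
        return set(self.parents.get(term, set()))

    def propagate_up(self) -> "AnnotationCatalog":
        """Annotate every gene to all ancestors of its terms (GO semantics)."""
        order = list(nx.topological_sort(self._graph))  # children before parents
        genes = {t: set(g) for t, g in self.term_genes.items()}
        for term in order:
            for parent in self.parents.get(term, set()):
                genes[parent] |= genes[term]
        return AnnotationCatalog(genes, {c: set(p) for c, p in self.parents.items()}, dict(self.term_names))


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic multi-omic generator."""

    seed: int
    planted_up: dict[str, set[str]]
    planted_down: dict[str, set[str]]
    planted_signature: list[tuple[str, str, str]]  # (gene_id, protein_id, pattern)
    noise_features: set[str]
    noise_floor_mean: float
    expressed_mean: float
    platform_transforms: dict[str, tuple[float, float]] = field(default_factory=dict)

    def signature_genes(self) -> set[str]:
        return {g for g, _, _ in self.planted_signature}
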