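"""Cross-dataset signature validation.

Expression of the signature genes measured on different platforms is not
directly comparable; each dataset is therefore transformed into z-scores
against its own healthy controls, which makes the representation exactly
invariant to per-dataset affine intensity distortions x -> a*x + b
(a > 0).  Group-averaged z profiles from all datasets are then pooled
and clustered with UPGMA (average linkage, standardized Euclidean
metric); a validating signature separates every case group from every
control group at the two-cluster cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .io import newick_string
from .model import Dendrogram, ExpressionMatrix, SampleDesign


@dataclass
class ZScoredMatrix:
    values: pd.DataFrame
    reference_samples: list[str]
    unscorable: list[str] = field(default_factory=list)
    dataset_label: str = "default"


def zscore_against_controls(
    matrix: ExpressionMatrix, design: SampleDesign
) -> ZScoredMatrix:
    """z = (x - mean(controls)) / sd(controls) per feature, within the
    dataset; features with zero control variance are excluded with a
    notice in ``unscorable``."""
    design.validate_against(matrix)
    controls = [
        s
        for s in matrix.sample_ids
        if design.table.set_index("sample_id").loc[s, "material_class"] == "control"
    ]
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples to z-score")
    ctrl = matrix.values[controls]
    mu = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    scorable = sd > 0
    z = matrix.values.loc[scorable].sub(mu[scorable], axis=0).div(sd[scorable], axis=0)
    return ZScoredMatrix(
        values=z,
        reference_samples=controls,
        unscorable=list(matrix.values.index[~scorable]),
        dataset_label=matrix.dataset_label,
    )


def average_groups(
    values: pd.DataFrame, design: SampleDesign, by_dataset: bool = True
) -> pd.DataFrame:
    """Missing-aware arithmetic mean per feature per material group; one
    column per group (prefixed by dataset label when ``by_dataset``)."""
    groups = design.group_labels().loc[values.columns]
    if by_dataset:
        ds = design.table.set_index("sample_id").loc[values.columns, "dataset_label"]
        # '|' keeps the label Newick-safe (':' delimits branch lengths)
        groups = pd.Series(
            [f"{d}|{g}" for d, g in zip(ds, groups)], index=values.columns
        )
    return values.T.groupby(groups).mean().T


def upgma(
    matrix: pd.DataFrame, metric: str = "standardized_euclidean"
) -> Dendrogram:
    """Average-linkage agglomerative clustering of the matrix columns.

    The distance between clusters is the unweighted mean of all
    cross-pair distances; equal merge distances break by the
    lexicographically smallest cluster-label pair, so the result does not
    depend on column order.  ``standardized_euclidean`` standardizes each
    feature to unit variance within this matrix before the Euclidean
    metric.
    """
    items = list(matrix.columns)
    if len(items) < 2:
        raise ValueError("need at least 2 items to cluster")
    X = matrix.to_numpy(dtype=float).T  # items x features
    if metric == "standardized_euclidean":
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        d = squareform(pdist(X / sd, metric="euclidean"))
    elif metric == "euclidean":
        d = squareform(pdist(X, metric="euclidean"))
    else:
        raise ValueError("metric must be 'standardized_euclidean' or 'euclidean'")
    return upgma_from_distance(pd.DataFrame(d, index=items, columns=items))


def upgma_from_distance(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA on a precomputed symmetric distance matrix (labels on both
    axes)."""
    labels = list(dist.columns)
    n = len(labels)
    order = sorted(range(n), key=lambda i: labels[i])
    leaf_labels = [labels[i] for i in order]
    d = dist.to_numpy(dtype=float)[np.ix_(order, order)]

    # active clusters: node id -> (member leaf indices, representative label)
    clusters: dict[int, tuple[list[int], str]] = {
        i: ([i], leaf_labels[i]) for i in range(n)
    }
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(clusters) > 1:
        best: tuple[float, str, str, int, int] | None = None
        ids = list(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                u, v = ids[ai], ids[bi]
                mu, lu = clusters[u]
                mv, lv = clusters[v]
                avg = float(np.mean([d[i, j] for i in mu for j in mv]))
                key_pair = tuple(sorted((lu, lv)))
                cand = (avg, key_pair[0], key_pair[1], *sorted((u, v)))
                if best is None or cand < best:
                    best = cand
        avg, _, _, u, v = best
        mu, lu = clusters.pop(u)
        mv, lv = clusters.pop(v)
        if lv < lu:  # orient: smaller representative label on the left
            u, v, mu, mv, lu, lv = v, u, mv, mu, lv, lu
        merges.append((u, v, avg))
        clusters[next_node] = (mu + mv, lu)
        next_node += 1
    return Dendrogram(leaf_labels, merges)


@dataclass
class ValidationReport:
    tree: Dendrogram
    newick: str
    partition: dict[str, int]
    case_control: dict[str, int]
    adjusted_rand: float
    genes_used: list[str]
    missing_by_dataset: dict[str, list[str]]
    group_profiles: pd.DataFrame


def validate_signature(
    signature_genes: list[str],
    datasets: list[tuple[ExpressionMatrix, SampleDesign]],
    min_fraction: float = 0.5,
    metric: str = "standardized_euclidean",
) -> ValidationReport:
    """z-score each dataset against its controls, average replicate
    samples within material groups, pool the group profiles over all
    datasets and cluster them with UPGMA.

    Reports the dendrogram, its two-cluster cut, and the adjusted Rand
    index of that cut against the case/control labelling.  Validation
    proceeds on the gene intersection when at least ``min_fraction`` of
    signature members are present in every dataset, otherwise aborts.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    missing: dict[str, list[str]] = {}
    common = set(signature_genes)
    for mat, _ in datasets:
        absent = [g for g in signature_genes if g not in mat.values.index]
        missing[mat.dataset_label] = absent
        common -= set(absent)
    if len(common) < min_fraction * len(signature_genes):
        raise ValueError(
            f"only {len(common)}/{len(signature_genes)} signature genes shared "
            f"across datasets (need >= {min_fraction:.0%})"
        )
    genes = sorted(common)

    profiles = []
    labels_case: dict[str, int] = {}
    for mat, des in datasets:
        z = zscore_against_controls(mat.restrict_features(genes), des)
        grp = average_groups(z.values.loc[genes], des, by_dataset=True)
        profiles.append(grp)
        for col in grp.columns:
            labels_case[col] = 0 if col.endswith("|control") else 1
    pooled = pd.concat(profiles, axis=1)

    tree = upgma(pooled, metric=metric)
    part_a, part_b = tree.cut_two()
    partition = {lbl: (0 if lbl in part_a else 1) for lbl in pooled.columns}
    order = list(pooled.columns)
    ari = float(
        adjusted_rand_score(
            [labels_case[c] for c in order], [partition[c] for c in order]
        )
    )
    return ValidationReport(
        tree=tree,
        newick=newick_string(tree),
        partition=partition,
        case_control=labels_case,
        adjusted_rand=ari,
        genes_used=genes,
        missing_by_dataset=missing,
        group_profiles=pooled,
    )
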