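"""Detection filtering, imputation and fold-change deregulation calling
for protein SLR tables.

SLR (signal log2 ratio) values are per-material means versus the HPSC
control; a protein is deregulated when its fold change exceeds 2 (or is
below 0.5), i.e. |SLR| > 1, and the per-cell significance criterion
holds.  Only proteins detected in at least four of the six experimental
materials are analysed; proteins with one or two missing measurements
are completed by k-nearest-neighbour imputation combined with linear
regression on the neighbour profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DeregulationSet, ProteinQuantTable

REQUIRED_CONDITIONS = 6
MIN_DETECTED = 4


def detection_filter(table: ProteinQuantTable) -> ProteinQuantTable:
    """Keep proteins detected in at least four of the six conditions."""
    if len(table.condition_ids) != REQUIRED_CONDITIONS:
        raise ValueError(
            f"detection filter expects {REQUIRED_CONDITIONS} conditions, "
            f"got {len(table.condition_ids)}"
        )
    keep = table.detected_count >= MIN_DETECTED
    return ProteinQuantTable(
        table.slr.loc[keep].copy(), table.imputed.loc[keep].copy()
    )


def impute_knn_regression(table: ProteinQuantTable, k: int = 5) -> ProteinQuantTable:
    """Fill missing SLR cells from the k nearest complete proteins.

    For each incomplete protein: the k complete proteins closest in
    Euclidean distance over the target's observed conditions are
    averaged into a neighbour profile; an ordinary least-squares line is
    fitted from that profile to the target over the observed conditions
    and evaluated at each missing condition.  Ties in distance break by
    protein id, so the result does not depend on input row order.
    """
    if len(table.condition_ids) != REQUIRED_CONDITIONS:
        raise ValueError(f"imputation expects {REQUIRED_CONDITIONS} conditions")
    if k < 1:
        raise ValueError("k must be >= 1")
    slr = table.slr
    n_missing = slr.isna().sum(axis=1)
    too_sparse = n_missing[n_missing > 2]
    if not too_sparse.empty:
        raise ValueError(
            f"proteins missing >2 values should have been detection-filtered: "
            f"{list(too_sparse.index[:5])}"
        )
    complete = slr.dropna()
    if len(complete) <= k:
        raise ValueError(
            f"need more than k={k} complete proteins, have {len(complete)}"
        )

    filled = slr.copy()
    flags = table.imputed.copy()
    comp_ids = np.array(complete.index)
    comp_vals = complete.to_numpy()
    lex = np.argsort(comp_ids)  # tie-break order

    for pid in slr.index[n_missing > 0]:
        y = slr.loc[pid].to_numpy()
        obs = ~np.isnan(y)
        pool_mask = comp_ids != pid
        pool_ids, pool_vals = comp_ids[pool_mask], comp_vals[pool_mask]
        d = np.sqrt(((pool_vals[:, obs] - y[obs]) ** 2).sum(axis=1))
        order = np.lexsort((pool_ids, d))
        neighbours = pool_vals[order[:k]]
        profile = neighbours.mean(axis=0)
        # least-squares y_obs ~ b0 + b1 * profile_obs
        A = np.column_stack([np.ones(obs.sum()), profile[obs]])
        coef, *_ = np.linalg.lstsq(A, y[obs], rcond=None)
        pred = coef[0] + coef[1] * profile[~obs]
        vals = filled.loc[pid].to_numpy()
        vals[~obs] = pred
        filled.loc[pid] = vals
        flags.loc[pid, np.array(slr.columns)[~obs]] = True
    return ProteinQuantTable(filled, flags)


@dataclass
class ProteinDeregulation:
    """Per-protein, per-material deregulation calls."""

    slr: pd.DataFrame
    deregulated: pd.DataFrame  # boolean
    direction: pd.DataFrame  # 'up' | 'down' | 'none'
    imputed: pd.DataFrame
    fold_threshold: float

    def direction_of(self, protein_id: str, condition: str) -> str:
        return str(self.direction.loc[protein_id, condition])


def call_deregulated_proteins(
    table: ProteinQuantTable,
    significance: pd.DataFrame | None = None,
    alpha: float = 0.05,
    fold_threshold: float = 2.0,
) -> tuple[dict[str, DeregulationSet], ProteinDeregulation]:
    """Call deregulation where |SLR| strictly exceeds log2(fold_threshold)
    and the significance criterion is met.

    ``significance`` is either per-cell p-values (compared against
    ``alpha``), a boolean pass-flag table, or None — the pass-flag mode
    for tables that print fold changes only.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if fold_threshold <= 1.0:
        raise ValueError("fold_threshold must exceed 1")
    slr = table.slr
    cut = float(np.log2(fold_threshold))
    exceeds = slr.abs() > cut
    if significance is None:
        passes = pd.DataFrame(True, index=slr.index, columns=slr.columns)
    else:
        significance = significance.reindex(index=slr.index, columns=slr.columns)
        if significance.dtypes.apply(lambda t: t == bool).all():
            passes = significance.fillna(False)
        else:
            passes = significance.astype(float) < alpha
    dereg = exceeds & passes & slr.notna()
    direction = pd.DataFrame("none", index=slr.index, columns=slr.columns)
    direction = direction.mask(dereg & (slr > 0), "up").mask(dereg & (slr < 0), "down")

    sets = {
        str(cond): DeregulationSet(
            str(cond),
            set(slr.index[direction[cond] == "up"]),
            set(slr.index[direction[cond] == "down"]),
        )
        for cond in slr.columns
    }
    return sets, ProteinDeregulation(
        slr.copy(), dereg, direction, table.imputed.copy(), fold_threshold
    )


def common_deregulated(sets: list[DeregulationSet]) -> DeregulationSet:
    """Proteins deregulated in the same direction in every material."""
    if len(sets) < 2:
        raise ValueError("need at least two deregulation sets")
    up = set.intersection(*(s.up for s in sets))
    down = set.intersection(*(s.down for s in sets))
    label = "common(" + ",".join(s.material_label for s in sets) + ")"
    return DeregulationSet(label, up, down)
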