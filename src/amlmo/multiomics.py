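"""Four-step transcript-protein integration producing the
concordance/discordance signature.

(i) map the quantified proteins to their transcripts; (ii) keep the
mapped genes whose expression differentiates cell lines from
primary/in-vivo passaged material (Bonferroni-corrected two-sample
test); (iii) keep the pairs whose protein is at least two-fold
deregulated; (iv) keep the pairs whose transcript/protein direction
pattern is consistent in every material — either concordant (same sign)
or discordant (opposite signs) throughout.  Discordant pairs are kept
deliberately: primary AMLs show negative transcript-protein correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    DeregulationSet,
    ExpressionMatrix,
    IdMap,
    ProteinQuantTable,
    SampleDesign,
)
from .proteome import ProteinDeregulation

log = logging.getLogger(__name__)


@dataclass
class MappingResult:
    pairs: pd.DataFrame  # protein_id, gene_id, gene_symbol
    unmatched: list[str]
    duplicate_genes: list[str]


def map_proteins_to_genes(table: ProteinQuantTable, idmap: IdMap) -> MappingResult:
    """Step (i): pair quantified proteins with their transcripts.

    Unmatched proteins are reported, never silently dropped; distinct
    proteins mapping to the same gene are allowed but flagged.
    """
    lookup = idmap.table.set_index("protein_id")
    rows, unmatched = [], []
    for pid in table.protein_ids:
        if pid in lookup.index:
            rec = lookup.loc[pid]
            rows.append((pid, str(rec["gene_id"]), str(rec["gene_symbol"])))
        else:
            unmatched.append(pid)
    pairs = pd.DataFrame(rows, columns=["protein_id", "gene_id", "gene_symbol"])
    counts = pairs["gene_id"].value_counts()
    dupes = sorted(counts[counts > 1].index)
    if dupes:
        log.warning("multiple proteins map to the same gene: %s", dupes[:10])
    if unmatched:
        log.info("%d proteins had no gene mapping", len(unmatched))
    return MappingResult(pairs, unmatched, dupes)


def separation_test(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Step (ii): per-gene two-sample pooled-variance comparison of
    cell-line samples against primary/in-vivo passaged samples, Bonferroni
    corrected over the tested genes.

    Returns a frame indexed by gene with columns ``t``, ``p``,
    ``p_bonferroni`` and ``separates``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    design.validate_against(matrix)
    cls = design.table.set_index("sample_id")["material_class"]
    cl_samples = [s for s in matrix.sample_ids if cls[s] == "cell_line"]
    pi_samples = [s for s in matrix.sample_ids if cls[s] in ("primary", "ivp")]
    if len(cl_samples) < 2 or len(pi_samples) < 2:
        raise ValueError(
            f"both groups need >=2 samples (cell_line={len(cl_samples)}, "
            f"primary/ivp={len(pi_samples)})"
        )
    a = matrix.values[cl_samples].to_numpy()
    b = matrix.values[pi_samples].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    m = matrix.shape[0]
    p_bonf = np.minimum(p * m, 1.0)
    return pd.DataFrame(
        {"t": t, "p": p, "p_bonferroni": p_bonf, "separates": p_bonf <= alpha},
        index=matrix.feature_ids,
    )


def bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(p, dtype=float) * len(np.atleast_1d(p)), 1.0)


@dataclass
class SignatureSet:
    """Gene/protein signature members with their concordance pattern."""

    members: pd.DataFrame  # gene_id, gene_symbol, protein_id, pattern
    separation_alpha: float
    fold_threshold: float
    funnel: dict[str, int] = field(default_factory=dict)
    excluded_missing_direction: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.members["gene_id"].duplicated().any():
            raise ValueError("signature gene ids must be unique")

    @property
    def gene_ids(self) -> set[str]:
        return set(self.members["gene_id"])

    def __len__(self) -> int:
        return len(self.members)


def derive_signature(
    mapping: MappingResult,
    separation: pd.DataFrame,
    transcript_dirs: dict[str, DeregulationSet],
    protein_dirs: ProteinDeregulation,
    fold_threshold: float = 2.0,
    separation_alpha: float = 0.05,
) -> SignatureSet:
    """Steps (iii)-(iv): protein two-fold deregulation plus all-material
    direction-pattern consistency.

    A pair enters the signature iff its gene separates cell lines from
    primary/in-vivo material, its protein SLR strictly exceeds
    log2(fold_threshold) in magnitude in every material, and the
    transcript and protein directions are consistently concordant or
    consistently discordant — with a single gene direction — across all
    materials.  Pairs missing a direction call anywhere are excluded and
    logged.
    """
    cut = float(np.log2(fold_threshold))
    materials = list(protein_dirs.slr.columns)
    separating = set(separation.index[separation["separates"]]) if "separates" in separation else set(separation.index)

    n_mapped = len(mapping.pairs)
    survivors_ii = mapping.pairs[mapping.pairs["gene_id"].isin(separating)]

    rows = []
    excluded: list[str] = []
    n_fold = 0
    for _, rec in survivors_ii.iterrows():
        gid, pid, sym = rec["gene_id"], rec["protein_id"], rec["gene_symbol"]
        if pid not in protein_dirs.slr.index:
            continue
        slr = protein_dirs.slr.loc[pid]
        if not (slr.abs() > cut).all():
            continue
        n_fold += 1
        gdirs, pdirs = [], []
        ok = True
        for m in materials:
            gd = transcript_dirs[m].direction_of(gid) if m in transcript_dirs else "none"
            pdir = protein_dirs.direction_of(pid, m)
            if gd == "none" or pdir == "none":
                ok = False
                break
            gdirs.append(gd)
            pdirs.append(pdir)
        if not ok:
            excluded.append(pid)
            continue
        if len(set(gdirs)) != 1:
            continue  # gene direction flips between materials
        gdir = gdirs[0]
        if all(p == g for p, g in zip(pdirs, gdirs)):
            pattern = f"concordant_{gdir}"
        elif all(p != g for p, g in zip(pdirs, gdirs)):
            pattern = f"discordant_gene_{gdir}"
        else:
            continue  # mixed concordance pattern
        rows.append((gid, sym, pid, pattern))

    rows.sort()
    members = pd.DataFrame(rows, columns=["gene_id", "gene_symbol", "protein_id", "pattern"])
    if excluded:
        log.info("pairs excluded for missing direction calls: %s", excluded[:10])
    return SignatureSet(
        members=members,
        separation_alpha=separation_alpha,
        fold_threshold=fold_threshold,
        funnel={
            "i_mapped_pairs": n_mapped,
            "ii_separating": len(survivors_ii),
            "iii_fold_deregulated": n_fold,
            "iv_consistent_pattern": len(members),
        },
        excluded_missing_direction=excluded,
    )


def gene_protein_spearman(
    gene_expr: pd.Series | np.ndarray, protein_slr: pd.Series | np.ndarray
) -> float:
    """Spearman rank correlation (average ranks on ties) between paired
    per-material transcript summaries and protein SLRs; NaN when either
    vector is constant."""
    x = np.asarray(gene_expr, dtype=float)
    y = np.asarray(protein_slr, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >=3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
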