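"""Synthetic multi-omic data with planted ground truth.

The generator emulates the reference study design: one healthy HPSC
control group and six AML materials (three cell lines, two primary AMLs,
one in-vivo passaged line) measured on ~20k transcript features, of which
a sizeable fraction is non-expressed array noise near a low intensity
floor; a ~1k-protein SLR table with limited missingness; and a planted
gene/protein signature whose members are directionally deregulated in
every material, separate cell lines from primary/in-vivo material, and
carry a concordant or discordant transcript-protein pattern.

Defaults mirror the study scale: 20,000 transcripts, 1,000 proteins,
4 replicates per group, and a 17-member signature.  All randomness comes
from a single explicitly seeded generator; identical seeds give
bitwise-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_MATERIALS,
    ExpressionMatrix,
    IdMap,
    ProteinQuantTable,
    SampleDesign,
    SIGNATURE_PATTERNS,
    SyntheticTruth,
    material_label,
)

CELL_LINE_MATERIALS = ("MLP3-cl", "RF12-cl", "RF26-cl")
PRIMARY_IVP_MATERIALS = ("RF12-p", "RF26-p", "MLP3-ivp")

_MATERIAL_DESIGN = {
    "MLP3-cl": ("cell_line", "MLP3"),
    "RF12-cl": ("cell_line", "RF12"),
    "RF26-cl": ("cell_line", "RF26"),
    "RF12-p": ("primary", "RF12"),
    "RF26-p": ("primary", "RF26"),
    "MLP3-ivp": ("ivp", "MLP3"),
}


def _build_design(n_replicates: int, dataset_label: str) -> SampleDesign:
    rows = []
    for r in range(1, n_replicates + 1):
        rows.append(("control_%d" % r, "control", "none", dataset_label, r))
    for m in DEFAULT_MATERIALS:
        cls, line = _MATERIAL_DESIGN[m]
        for r in range(1, n_replicates + 1):
            rows.append((f"{m}_{r}", cls, line, dataset_label, r))
    return SampleDesign(
        pd.DataFrame(
            rows,
            columns=["sample_id", "material_class", "line", "dataset_label", "replicate_index"],
        )
    )


def generate_multiomic(
    n_transcripts: int = 20_000,
    n_proteins: int = 1_000,
    n_replicates: int = 4,
    effect_log2: float = 3.0,
    noise_sd: float = 0.25,
    missing_max: int = 2,
    seed: int = 0,
    *,
    noise_fraction: float = 0.30,
    noise_floor_mean: float = 3.0,
    expressed_mean: float = 9.0,
    n_signature: int = 17,
    de_fraction: float = 0.05,
    missing_protein_fraction: float = 0.20,
    dataset_label: str = "mouse",
) -> tuple[ExpressionMatrix, SampleDesign, ProteinQuantTable, IdMap, SyntheticTruth]:
    """Generate one complete synthetic multi-omic dataset.

    Transcript intensities are two-component: non-expressed features near
    ``noise_floor_mean`` and expressed features near ``expressed_mean``,
    both with additive Gaussian noise of ``noise_sd``.  Planted DE
    features are shifted by ±``effect_log2``; planted signature genes get
    an additional same-sign shift of ``effect_log2`` in the cell-line
    materials so that they also separate cell lines from primary/in-vivo
    material.  Protein SLRs equal the transcript group effect (concordant
    members) or its negation (discordant members) plus Gaussian noise of
    ``noise_sd``; decoy proteins failing exactly one signature criterion
    are planted so that signature recovery is a two-sided test.
    """
    if missing_max > 2:
        raise ValueError(
            "missing_max > 2 would violate the >=4-of-6 detection rule by construction"
        )
    if missing_max < 0:
        raise ValueError("missing_max must be in 0..2")
    if n_proteins > n_transcripts:
        raise ValueError("n_proteins must not exceed n_transcripts")
    if effect_log2 < 0 or noise_sd <= 0:
        raise ValueError("effect_log2 must be >= 0 and noise_sd > 0")

    rng = np.random.default_rng(seed)
    design = _build_design(n_replicates, dataset_label)
    samples = design.sample_ids
    groups = design.group_labels()

    width = max(5, len(str(n_transcripts)))
    feature_ids = [f"G{i + 1:0{width}d}" for i in range(n_transcripts)]

    n_noise = int(round(noise_fraction * n_transcripts))
    # Mapped (proteome-covered) genes must be expressed: take them from the
    # expressed block, noise features from the tail.
    noise_idx = np.arange(n_transcripts - n_noise, n_transcripts)
    expressed_idx = np.arange(n_transcripts - n_noise)
    mapped_idx = expressed_idx[:n_proteins]

    baseline = np.empty(n_transcripts)
    baseline[expressed_idx] = expressed_mean + rng.normal(0.0, 1.0, size=expressed_idx.size)
    baseline[noise_idx] = noise_floor_mean + rng.normal(0.0, 0.3, size=noise_idx.size)

    # effect[i, m]: log2 shift of feature i in material m relative to control
    effect = np.zeros((n_transcripts, len(DEFAULT_MATERIALS)))
    m_index = {m: j for j, m in enumerate(DEFAULT_MATERIALS)}
    cl_cols = [m_index[m] for m in CELL_LINE_MATERIALS]

    # --- planted signature pairs (and decoys) among mapped genes ----------
    n_signature = min(n_signature, n_proteins)
    special_pool = rng.permutation(mapped_idx)
    sig_idx = special_pool[:n_signature]
    n_decoy = max(2, n_signature // 4) if n_proteins >= n_signature + 6 else 0
    decoy_sep_only = special_pool[n_signature : n_signature + n_decoy]
    decoy_prot_only = special_pool[n_signature + n_decoy : n_signature + 2 * n_decoy]
    n_mixed = max(1, n_decoy // 2) if n_decoy else 0
    decoy_mixed = special_pool[n_signature + 2 * n_decoy : n_signature + 2 * n_decoy + n_mixed]

    protein_ids = [f"P{i + 1:0{width}d}" for i in range(n_proteins)]
    gene_of_protein = {protein_ids[k]: feature_ids[mapped_idx[k]] for k in range(n_proteins)}
    protein_of_gene_idx = {mapped_idx[k]: protein_ids[k] for k in range(n_proteins)}

    slr_effect = np.zeros((n_proteins, len(DEFAULT_MATERIALS)))
    prow = {protein_ids[k]: k for k in range(n_proteins)}

    planted_signature: list[tuple[str, str, str]] = []
    for j, fi in enumerate(sig_idx):
        pattern = SIGNATURE_PATTERNS[j % len(SIGNATURE_PATTERNS)]
        gsign = 1.0 if pattern in ("concordant_up", "discordant_gene_up") else -1.0
        psign = gsign if pattern.startswith("concordant") else -gsign
        effect[fi, :] = gsign * effect_log2
        effect[fi, cl_cols] = gsign * 2.0 * effect_log2  # separates cl vs p/ivp
        pid = protein_of_gene_idx[fi]
        slr_effect[prow[pid], :] = psign * np.abs(effect[fi, :])
        planted_signature.append((feature_ids[fi], pid, pattern))

    # decoys: separate but protein null / protein deregulated but no
    # separation / mixed protein direction
    for fi in decoy_sep_only:
        effect[fi, cl_cols] = effect_log2  # cl-only shift, protein stays null
    for fi in decoy_prot_only:
        effect[fi, :] = effect_log2  # uniform shift: no cl-vs-p separation
        slr_effect[prow[protein_of_gene_idx[fi]], :] = effect_log2
    for fi in np.atleast_1d(decoy_mixed):
        effect[fi, :] = effect_log2
        effect[fi, cl_cols] = 2.0 * effect_log2
        row = prow[protein_of_gene_idx[fi]]
        slr_effect[row, :] = effect_log2
        slr_effect[row, cl_cols] = -2.0 * effect_log2  # direction flips: fails step (iv)

    special = set(sig_idx) | set(decoy_sep_only) | set(decoy_prot_only) | set(np.atleast_1d(decoy_mixed))

    # --- generic planted DE among the remaining expressed features --------
    free_idx = np.array([i for i in expressed_idx if i not in special])
    n_de = int(round(de_fraction * free_idx.size))
    planted_up: dict[str, set[str]] = {m: set() for m in DEFAULT_MATERIALS}
    planted_down: dict[str, set[str]] = {m: set() for m in DEFAULT_MATERIALS}
    if n_de:
        de_pick = rng.choice(free_idx, size=n_de, replace=False)
        half = n_de // 2
        shared, specific = de_pick[:half], de_pick[half:]
        signs = rng.choice([-1.0, 1.0], size=n_de)
        for i, fi in enumerate(shared):  # altered in every material
            effect[fi, :] = signs[i] * effect_log2
            for m in DEFAULT_MATERIALS:
                (planted_up if signs[i] > 0 else planted_down)[m].add(feature_ids[fi])
        for i, fi in enumerate(specific):  # altered in a random subset
            k = rng.integers(1, len(DEFAULT_MATERIALS))
            cols = rng.choice(len(DEFAULT_MATERIALS), size=k, replace=False)
            s = signs[half + i]
            effect[fi, cols] = s * effect_log2
            for c in cols:
                m = DEFAULT_MATERIALS[c]
                (planted_up if s > 0 else planted_down)[m].add(feature_ids[fi])
    for gid, pid, pattern in planted_signature:
        gdir_up = pattern in ("concordant_up", "discordant_gene_up")
        for m in DEFAULT_MATERIALS:
            (planted_up if gdir_up else planted_down)[m].add(gid)
    for fi in decoy_sep_only:
        for m in CELL_LINE_MATERIALS:
            planted_up[m].add(feature_ids[fi])
    for fi in decoy_prot_only:
        for m in DEFAULT_MATERIALS:
            planted_up[m].add(feature_ids[fi])
    for fi in np.atleast_1d(decoy_mixed):
        for m in DEFAULT_MATERIALS:
            planted_up[m].add(feature_ids[fi])

    # --- realise the expression matrix -------------------------------------
    values = np.empty((n_transcripts, len(samples)))
    for c, s in enumerate(samples):
        g = groups[s]
        shift = np.zeros(n_transcripts) if g == "control" else effect[:, m_index[g]]
        values[:, c] = baseline + shift + rng.normal(0.0, noise_sd, size=n_transcripts)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=samples), dataset_label=dataset_label
    )

    # --- proteome SLR table -------------------------------------------------
    slr = slr_effect + rng.normal(0.0, noise_sd, size=slr_effect.shape)
    special_proteins = {protein_of_gene_idx[fi] for fi in special}
    if missing_max > 0 and missing_protein_fraction > 0:
        for k, pid in enumerate(protein_ids):
            if pid in special_proteins:
                continue  # keep planted-truth proteins complete
            if rng.random() < missing_protein_fraction:
                n_miss = int(rng.integers(1, missing_max + 1))
                cols = rng.choice(len(DEFAULT_MATERIALS), size=n_miss, replace=False)
                slr[k, cols] = np.nan
    table = ProteinQuantTable(
        pd.DataFrame(slr, index=protein_ids, columns=list(DEFAULT_MATERIALS))
    )

    idmap = IdMap(
        pd.DataFrame(
            {
                "protein_id": protein_ids,
                "gene_id": [gene_of_protein[p] for p in protein_ids],
                "gene_symbol": ["Sym" + gene_of_protein[p] for p in protein_ids],
            }
        )
    )

    truth = SyntheticTruth(
        seed=seed,
        planted_up=planted_up,
        planted_down=planted_down,
        planted_signature=planted_signature,
        noise_features={feature_ids[i] for i in noise_idx},
        noise_floor_mean=noise_floor_mean,
        expressed_mean=expressed_mean,
    )
    return matrix, design, table, idmap, truth


def generate_validation_datasets(
    base: ExpressionMatrix,
    design: SampleDesign,
    n_datasets: int = 2,
    scale_range: tuple[float, float] = (0.6, 1.8),
    offset_range: tuple[float, float] = (-2.0, 2.0),
    noise_sd: float = 0.25,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[list[tuple[ExpressionMatrix, SampleDesign]], dict[str, tuple[float, float]]]:
    """Emulate the same case/control contrast measured on other platforms.

    Each derived dataset applies a per-dataset affine intensity distortion
    ``x -> scale*x + offset`` to the base per-group mean patterns, adds
    fresh Gaussian noise (scaled so the control-referenced z effect is
    preserved), and carries its own control samples.  Returns the
    datasets and the (scale, offset) transform applied to each.
    """
    if scale_range[0] <= 0:
        raise ValueError("scale_range must be strictly positive (affine scale cannot be 0)")
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    design.validate_against(base)
    rng = np.random.default_rng(seed)

    groups = design.group_labels().loc[base.sample_ids]
    if "control" not in set(groups):
        raise ValueError("base dataset must contain a control group")
    group_means = base.values.T.groupby(groups).mean().T  # features x groups

    info = design.table.drop_duplicates(subset=["material_class", "line"]).set_index(
        design.table.drop_duplicates(subset=["material_class", "line"]).apply(
            lambda r: material_label(r["material_class"], r["line"]), axis=1
        )
    )

    out: list[tuple[ExpressionMatrix, SampleDesign]] = []
    transforms: dict[str, tuple[float, float]] = {}
    for d in range(n_datasets):
        label = f"platform{d + 1}"
        scale = float(rng.uniform(*scale_range))
        offset = float(rng.uniform(*offset_range))
        transforms[label] = (scale, offset)
        cols, rows, data = [], [], []
        for g in group_means.columns:
            for r in range(1, n_replicates + 1):
                sid = f"{label}_{g}_{r}"
                cols.append(sid)
                if g == "control":
                    rows.append((sid, "control", "none", label, r))
                else:
                    rows.append(
                        (sid, info.loc[g, "material_class"], info.loc[g, "line"], label, r)
                    )
                data.append(
                    scale * group_means[g].to_numpy()
                    + offset
                    + rng.normal(0.0, scale * noise_sd, size=group_means.shape[0])
                )
        mat = ExpressionMatrix(
            pd.DataFrame(np.column_stack(data), index=base.feature_ids, columns=cols),
            dataset_label=label,
        )
        des = SampleDesign(
            pd.DataFrame(
                rows,
                columns=["sample_id", "material_class", "line", "dataset_label", "replicate_index"],
            )
        )
        out.append((mat, des))
    return out, transforms
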