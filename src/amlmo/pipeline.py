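"""End-to-end orchestration of the multi-omic analysis.

Stages run in the analysis order of the study design this pipeline
models: noise filtration -> transcript differential expression ->
proteome deregulation -> set-similarity (Venn/Dice) -> multi-omic
signature derivation -> over-representation -> cross-dataset signature
validation.  Every stage writes its artefacts before the next starts,
and a provenance record (thresholds, seed, input paths, survivor counts)
suffices to re-execute the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import io as amio
from .enrichment import enrich_all
from .model import ExpressionMatrix, SampleDesign
from .multiomics import derive_signature, map_proteins_to_genes, separation_test
from .proteome import (
    call_deregulated_proteins,
    common_deregulated,
    detection_filter,
    impute_knn_regression,
)
from .sets import dice_ci, generalized_dice, venn_counts
from .simulate import generate_validation_datasets
from .transcriptome import anova_tukey, directional_calls, filter_features, fit_noise_model
from .validation import validate_signature

log = logging.getLogger(__name__)

STAGES = ("filter", "de", "proteins", "dice", "signature", "enrich", "validate")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    expression: str
    design: str
    proteins: str
    idmap: str
    outdir: str = "amlmo_out"
    gmt: str | None = None
    ontology_edges: str | None = None
    validation_data: list[tuple[str, str]] = field(default_factory=list)
    simulate_validation: int = 0  # number of synthetic validation platforms
    de_alpha: float = 0.05
    protein_fold_threshold: float = 2.0
    separation_alpha: float = 0.05
    variance_quantile: float = 0.25
    dice_bootstrap: int = 1000
    knn_k: int = 5
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        for name in ("de_alpha", "separation_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.protein_fold_threshold <= 1.0:
            raise ValueError("protein_fold_threshold must exceed 1")
        if not (0.0 <= self.variance_quantile < 1.0):
            raise ValueError("variance_quantile must be in [0, 1)")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.stages = {s: self.stages.get(s, True) for s in STAGES}

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the report bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "provenance": _provenance(config)}
    amio.write_json_report(report["provenance"], out / "provenance.json")

    matrix = amio.read_expression_matrix(config.expression)
    design = amio.read_sample_design(config.design)
    design.validate_against(matrix)
    protein_table = amio.read_protein_table(config.proteins)
    idmap = amio.read_id_map(config.idmap)

    filtered = matrix
    de_sets = None
    protein_sets = None
    protein_calls = None
    signature = None

    if config.stages["filter"]:
        model = fit_noise_model(matrix, seed=config.seed)
        filtered, kept = filter_features(
            matrix, model, config.variance_quantile, design=design
        )
        amio.write_feature_set(kept, out / "kept_features.txt")
        report["stages"].append(
            {
                "stage": "filter",
                "n_input": matrix.shape[0],
                "n_kept": len(kept),
                "noise_threshold": model.noise_threshold,
                "n_components": model.n_components,
            }
        )
        log.info("filter: %d -> %d features", matrix.shape[0], len(kept))

    if config.stages["de"]:
        pairwise = anova_tukey(filtered, design)
        de = directional_calls(pairwise, alpha=config.de_alpha)
        de.table.to_csv(out / "de_results.tsv", sep="\t", index=False)
        de_sets = de.sets()
        for m, s in de_sets.items():
            amio.write_feature_set(s.up, out / f"transcripts_{m}_up.txt")
            amio.write_feature_set(s.down, out / f"transcripts_{m}_down.txt")
        report["stages"].append(
            {
                "stage": "de",
                "alpha": config.de_alpha,
                "n_altered": {m: len(s.all) for m, s in de_sets.items()},
            }
        )

    if config.stages["proteins"]:
        try:
            detected = detection_filter(protein_table)
            imputed = impute_knn_regression(detected, k=config.knn_k)
        except ValueError as e:
            raise StageError("proteins", str(e)) from e
        protein_sets, protein_calls = call_deregulated_proteins(
            imputed, fold_threshold=config.protein_fold_threshold
        )
        amio.write_protein_table(imputed, out / "proteins_imputed.tsv")
        protein_calls.direction.to_csv(out / "protein_directions.tsv", sep="\t")
        common = common_deregulated(list(protein_sets.values()))
        amio.write_feature_set(common.all, out / "proteins_common_deregulated.txt")
        report["stages"].append(
            {
                "stage": "proteins",
                "n_input": len(protein_table.protein_ids),
                "n_detected": len(detected.protein_ids),
                "n_deregulated": {m: len(s.all) for m, s in protein_sets.items()},
                "n_common": len(common.all),
            }
        )

    if config.stages["dice"]:
        source = de_sets if de_sets is not None else protein_sets
        if source is None:
            raise StageError("dice", "needs the de or proteins stage output")
        dice_report = {}
        labelled = {m: s.all for m, s in source.items() if s.all}
        for a, b in combinations(sorted(labelled), 2):
            universe = sorted(labelled[a] | labelled[b])
            res = dice_ci(
                universe,
                {a: labelled[a], b: labelled[b]},
                n_bootstrap=config.dice_bootstrap,
                seed=config.seed,
            )
            dice_report[f"{a}|{b}"] = asdict(res)
        if len(labelled) >= 2:
            dice_report["all_sets"] = {
                "k": len(labelled),
                "estimate": generalized_dice(list(labelled.values())),
            }
        for combo in combinations(sorted(labelled), 3):
            counts = venn_counts({m: labelled[m] for m in combo})
            pd.Series(
                {"+".join(sorted(k)): v for k, v in counts.items()}
            ).to_csv(out / ("venn_" + "_".join(combo) + ".tsv"), sep="\t", header=False)
            break  # one illustrative 3-way decomposition
        amio.write_json_report(dice_report, out / "dice.json")
        report["stages"].append({"stage": "dice", "n_comparisons": len(dice_report)})

    if config.stages["signature"]:
        if protein_calls is None or de_sets is None:
            raise StageError("signature", "requires the de and proteins stage outputs")
        mapping = map_proteins_to_genes(protein_table, idmap)
        mapped_genes = [g for g in mapping.pairs["gene_id"] if g in matrix.values.index]
        separation = separation_test(
            matrix.restrict_features(mapped_genes), design, alpha=config.separation_alpha
        )
        signature = derive_signature(
            mapping,
            separation,
            de_sets,
            protein_calls,
            fold_threshold=config.protein_fold_threshold,
            separation_alpha=config.separation_alpha,
        )
        signature.members.to_csv(out / "signature.tsv", sep="\t", index=False)
        amio.write_json_report(signature.funnel, out / "signature_funnel.json")
        report["stages"].append({"stage": "signature", "funnel": signature.funnel})

    if config.stages["enrich"]:
        if config.gmt is None:
            report["stages"].append({"stage": "enrich", "skipped": "no annotation catalog"})
        else:
            if de_sets is None:
                raise StageError("enrich", "requires the de stage output")
            catalog = amio.read_annotation_catalog(config.gmt, config.ontology_edges)
            study = set.intersection(*(s.all for s in de_sets.values()))
            population = set(filtered.feature_ids)
            results = enrich_all(
                study & population, catalog, population,
                method="parent_child" if config.ontology_edges else "classic",
            )
            pd.DataFrame([asdict(r) for r in results]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False
            )
            report["stages"].append(
                {
                    "stage": "enrich",
                    "n_terms": len(results),
                    "n_significant": sum(r.q <= 0.05 for r in results),
                }
            )

    if config.stages["validate"]:
        if signature is None or len(signature) == 0:
            report["stages"].append({"stage": "validate", "skipped": "empty signature"})
        else:
            datasets: list[tuple[ExpressionMatrix, SampleDesign]] = [(matrix, design)]
            for expr_path, design_path in config.validation_data:
                datasets.append(
                    (amio.read_expression_matrix(expr_path), amio.read_sample_design(design_path))
                )
            if config.simulate_validation:
                base = matrix.restrict_features(sorted(signature.gene_ids))
                extra, _ = generate_validation_datasets(
                    base, design, n_datasets=config.simulate_validation, seed=config.seed
                )
                datasets.extend(extra)
            rep = validate_signature(sorted(signature.gene_ids), datasets)
            amio.write_newick(rep.tree, out / "validation_tree.nwk")
            rep.group_profiles.to_csv(out / "validation_profiles.tsv", sep="\t")
            amio.write_json_report(
                {
                    "adjusted_rand": rep.adjusted_rand,
                    "partition": rep.partition,
                    "genes_used": rep.genes_used,
                },
                out / "validation.json",
            )
            report["stages"].append(
                {"stage": "validate", "adjusted_rand": rep.adjusted_rand}
            )

    amio.write_json_report(report, out / "report.json")
    return report


def _provenance(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["pipeline_stage_order"] = list(STAGES)
    return d
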