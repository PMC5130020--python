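"""Over-representation analysis: plain hypergeometric and parent-child.

The parent-child variant conditions each term's test on its parents'
annotation: the background becomes the genes annotated to the union (or,
optionally, intersection) of the term's parents, which removes the
inheritance-driven inflation that the classic test suffers on a DAG.
Annotations are propagated up the ontology before testing, following the
usual GO true-path semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import AnnotationCatalog
from .transcriptome import benjamini_hochberg

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term_id: str
    study_hits: int
    study_size: int
    population_hits: int
    population_size: int
    fold_enrichment: float
    p: float
    q: float = float("nan")
    method: str = "classic"

    def __post_init__(self) -> None:
        if self.study_hits > min(self.study_size, self.population_hits):
            raise ValueError("study_hits exceeds study size or annotated population")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be a probability")


def _upper_tail(study_hits: int, population: int, annotated: int, drawn: int) -> float:
    """P(X >= study_hits) for X ~ Hypergeom(population, annotated, drawn)."""
    return float(stats.hypergeom.sf(study_hits - 1, population, annotated, drawn))


def hypergeometric_test(
    study: set[str], population: set[str], term_genes: set[str], term_id: str = ""
) -> EnrichmentResult:
    """Classic one-term over-representation test."""
    if not study or not population:
        raise ValueError("study and population must be non-empty")
    if not study <= population:
        raise ValueError("study must be a subset of the population")
    ann = term_genes & population
    hits = len(study & ann)
    p = _upper_tail(hits, len(population), len(ann), len(study))
    expected = len(study) * len(ann) / len(population)
    return EnrichmentResult(
        term_id=term_id,
        study_hits=hits,
        study_size=len(study),
        population_hits=len(ann),
        population_size=len(population),
        fold_enrichment=hits / expected if expected > 0 else float("nan"),
        p=p,
        method="classic",
    )


def parent_child_test(
    study: set[str],
    catalog: AnnotationCatalog,
    term_id: str,
    population: set[str] | None = None,
    parent_mode: str = "union",
    propagated: bool = False,
) -> EnrichmentResult:
    """Over-representation of a term conditioned on its parents.

    The background is the set of genes annotated to the union (default)
    or intersection of the term's parents; draws are the study genes
    inside that background.  Orphan terms fall back to the classic test
    against ``population`` with a logged notice.
    """
    cat = catalog if propagated else catalog.propagate_up()
    parents = cat.parents_of(term_id)
    if not parents:
        if population is None:
            raise ValueError(f"term {term_id!r} has no parents and no population was given")
        log.info("term %s has no parents; falling back to the classic test", term_id)
        res = hypergeometric_test(study, population, cat.term_genes[term_id], term_id)
        res.method = "classic_fallback"
        return res
    parent_sets = [cat.term_genes[p] for p in sorted(parents)]
    if parent_mode == "union":
        background = set.union(*parent_sets)
    elif parent_mode == "intersection":
        background = set.intersection(*parent_sets)
    else:
        raise ValueError("parent_mode must be 'union' or 'intersection'")
    ann = cat.term_genes[term_id] & background
    drawn = study & background
    hits = len(drawn & ann)
    p = _upper_tail(hits, len(background), len(ann), len(drawn))
    expected = len(drawn) * len(ann) / len(background) if background else 0.0
    return EnrichmentResult(
        term_id=term_id,
        study_hits=hits,
        study_size=len(drawn),
        population_hits=len(ann),
        population_size=len(background),
        fold_enrichment=hits / expected if expected > 0 else float("nan"),
        p=p,
        method=f"parent_child_{parent_mode}",
    )


def enrich_all(
    study: set[str],
    catalog: AnnotationCatalog,
    population: set[str],
    method: str = "classic",
    alpha: float = 0.05,
    parent_mode: str = "union",
) -> list[EnrichmentResult]:
    """Test every catalog term, BH-adjust across terms, rank by p."""
    if method not in ("classic", "parent_child"):
        raise ValueError("method must be 'classic' or 'parent_child'")
    cat = catalog.propagate_up()
    results = []
    for term in cat.terms:
        if method == "classic":
            results.append(
                hypergeometric_test(study & population, population, cat.term_genes[term], term)
            )
        else:
            results.append(
                parent_child_test(
                    study & population, cat, term,
                    population=population, parent_mode=parent_mode, propagated=True,
                )
            )
    q = benjamini_hochberg(np.array([r.p for r in results]))
    for r, qi in zip(results, q):
        r.q = float(qi)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
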