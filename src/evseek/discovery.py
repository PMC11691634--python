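"""Tissue-of-origin EV marker selection workflow.

Four deterministic stages, each recorded per gene in a provenance table:

1. **Specificity** — a gene is tissue-specific when its target-tissue
   expression clears a detection floor and exceeds ``fold_threshold`` times
   its maximum expression in every other tissue (the "tissue enriched"
   convention of public expression atlases, default fold 4).
2. **Membrane filter** — keep genes annotated under a plasma-membrane-like
   ontology term and drop genes annotated under a synaptic-vesicle-like term
   (exclusion wins), so surviving proteins can sit on the EV surface.
3. **Catalog intersection** — keep genes documented in EV compendia
   (default: present in *all* supplied catalogs).
4. **Expression ranking** — order survivors by expression in a chosen cell
   type, descending, ties broken lexicographically by gene id.

No inference happens here: the workflow is deterministic filtering, so no
multiple-testing machinery is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationSet, OntologyGraph, genes_annotated_under

__all__ = [
    "SpecificityParams",
    "DiscoveryConfig",
    "DiscoveryResult",
    "classify_specific",
    "filter_membrane",
    "intersect_catalogs",
    "rank_candidates",
    "run_discovery",
]


@dataclass
class SpecificityParams:
    """Rule for calling a gene specific to ``target_tissue``."""

    target_tissue: str
    fold_threshold: float = 4.0
    detection_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be nonnegative")


@dataclass
class DiscoveryConfig:
    specificity: SpecificityParams
    include_term: str
    exclude_term: str
    propagate: bool = True
    catalog_mode: str = "all"
    cell_type: str = "neurons"


@dataclass
class DiscoveryResult:
    """Per-gene provenance plus the stage-count report."""

    candidates: pd.DataFrame
    stage_counts: dict[str, int]
    config: DiscoveryConfig
    ranked_genes: list[str] = field(default_factory=list)

    @property
    def survivors(self) -> list[str]:
        return list(self.ranked_genes)

    @property
    def top_candidate(self) -> str | None:
        return self.ranked_genes[0] if self.ranked_genes else None


def _validate_atlas(atlas: pd.DataFrame) -> None:
    if atlas.shape[1] < 2:
        raise ValueError("atlas must contain at least two tissues")
    if atlas.columns.duplicated().any():
        raise ValueError("tissue names must be unique")
    if atlas.index.duplicated().any():
        raise ValueError("gene ids must be unique")
    if (atlas.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")


def classify_specific(atlas: pd.DataFrame, params: SpecificityParams) -> pd.DataFrame:
    """Apply the fold rule per gene; returns flags and the specificity fold.

    The fold is ``value(target) / max(other tissues)``; a gene whose
    expression is zero everywhere else gets an ``inf`` sentinel fold.
    """
    _validate_atlas(atlas)
    if params.target_tissue not in atlas.columns:
        raise KeyError(f"unknown target tissue {params.target_tissue!r}")

    target = atlas[params.target_tissue].to_numpy(dtype=float)
    others = atlas.drop(columns=[params.target_tissue]).to_numpy(dtype=float)
    max_other = others.max(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(max_other > 0, target / np.where(max_other > 0, max_other, 1.0), np.inf)
    fold = np.where((max_other == 0) & (target == 0), np.inf, fold)

    passed = (target >= params.detection_floor) & (
        target >= params.fold_threshold * max_other
    )
    return pd.DataFrame(
        {"passed_specificity": passed, "specificity_fold": fold}, index=atlas.index
    )


def filter_membrane(
    candidates: Iterable[str],
    ontology: OntologyGraph,
    annotations: AnnotationSet,
    include_term: str,
    exclude_term: str,
    propagate: bool = True,
) -> set[str]:
    """candidates ∩ genes-under(include) ∖ genes-under(exclude); exclusion wins."""
    included = genes_annotated_under(ontology, annotations, include_term, propagate=propagate)
    excluded = genes_annotated_under(ontology, annotations, exclude_term, propagate=propagate)
    return (set(candidates) & included) - excluded


def intersect_catalogs(
    candidates: Iterable[str],
    catalogs: Sequence[set[str]],
    mode: str = "all",
) -> tuple[set[str], pd.DataFrame]:
    """Keep candidates documented in EV catalogs; also return per-catalog hits."""
    if not catalogs:
        raise ValueError("at least one catalog is required")
    if mode not in {"all", "any"}:
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    candidates = sorted(set(candidates))
    hits = pd.DataFrame(
        {f"catalog_{i+1}": [g in cat for g in candidates] for i, cat in enumerate(catalogs)},
        index=pd.Index(candidates, name="gene_id"),
    )
    combined = hits.all(axis=1) if mode == "all" else hits.any(axis=1)
    return set(hits.index[combined]), hits


def rank_candidates(
    candidates: Iterable[str],
    expression: pd.DataFrame,
    cell_type: str,
) -> pd.DataFrame:
    """Order candidates by descending expression in ``cell_type``.

    Ties break lexicographically on gene id; genes absent from the expression
    table rank last (flagged ``missing_expression``).
    """
    if cell_type not in expression.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    rows = []
    for gene in set(candidates):
        present = gene in expression.index
        value = float(expression.at[gene, cell_type]) if present else float("nan")
        rows.append((gene, value, not present))
    table = pd.DataFrame(rows, columns=["gene_id", "rank_expression", "missing_expression"])
    table = table.sort_values(
        by=["missing_expression", "rank_expression", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).set_index("gene_id")
    table["final_rank"] = np.arange(1, len(table) + 1)
    return table


def run_discovery(
    atlas: pd.DataFrame,
    ontology: OntologyGraph,
    annotations: AnnotationSet,
    catalogs: Sequence[set[str]],
    celltype_expression: pd.DataFrame,
    config: DiscoveryConfig,
) -> DiscoveryResult:
    """Run all four stages, keeping per-gene provenance for every input gene.

    Gene identifiers from every input are harmonized by exact match after
    uppercase normalization. An empty survivor set is a valid outcome, not an
    error. Output is invariant to input row order (the provenance table is
    sorted on gene id).
    """
    atlas = atlas.copy()
    atlas.index = atlas.index.astype(str).str.upper()
    atlas = atlas.sort_index()
    annotations = AnnotationSet(
        pairs={g.upper(): set(ts) for g, ts in annotations.pairs.items()}
    )
    catalogs = [{g.upper() for g in cat} for cat in catalogs]
    expr = celltype_expression.copy()
    expr.index = expr.index.astype(str).str.upper()

    spec = classify_specific(atlas, config.specificity)
    specific = set(spec.index[spec["passed_specificity"]])

    membrane_kept = filter_membrane(
        specific,
        ontology,
        annotations,
        config.include_term,
        config.exclude_term,
        propagate=config.propagate,
    )
    excluded_vesicle = genes_annotated_under(
        ontology, annotations, config.exclude_term, propagate=config.propagate
    )
    included_membrane = genes_annotated_under(
        ontology, annotations, config.include_term, propagate=config.propagate
    )

    catalog_kept, hits = intersect_catalogs(membrane_kept, catalogs, mode=config.catalog_mode)
    ranking = rank_candidates(catalog_kept, expr, config.cell_type)

    table = pd.DataFrame(index=atlas.index)
    table["passed_specificity"] = spec["passed_specificity"]
    table["specificity_fold"] = spec["specificity_fold"]
    table["passed_membrane"] = [g in included_membrane for g in table.index]
    table["excluded_vesicle"] = [g in excluded_vesicle for g in table.index]
    for col in hits.columns:
        table[col] = hits[col].reindex(table.index, fill_value=False).astype(bool)
    table["passed_catalog"] = [g in catalog_kept for g in table.index]
    table["rank_expression"] = ranking["rank_expression"].reindex(table.index)
    table["final_rank"] = ranking["final_rank"].reindex(table.index).astype("Int64")

    ranked_genes = ranking.index.tolist()
    stage_counts = {
        "input": int(len(atlas)),
        "specific": int(len(specific)),
        "membrane": int(len(membrane_kept)),
        "catalog": int(len(catalog_kept)),
        "ranked": int(len(ranked_genes)),
    }
    return DiscoveryResult(
        candidates=table, stage_counts=stage_counts, config=config, ranked_genes=ranked_genes
    )
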