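"""Synthetic inputs with planted ground truth for the full pipeline.

Every generator is a pure function of an explicit integer seed: identical
arguments produce byte-identical output files. Generated objects emulate the
inputs of a tissue-of-origin EV biomarker study —

* an expression atlas with planted tissue-specific genes at a stated fold,
* a small cellular-component ontology with a plasma-membrane-like and a
  synaptic-vesicle-like branch plus gene annotations,
* EV catalog membership lists with stated coverage probabilities,
* a per-cell-type expression table for candidate ranking,
* log-normal particle diameters with Bernoulli fluorescence channels,
* negative-binomial miRNA counts with planted log2 fold changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationSet, OntologyGraph

import networkx as nx

__all__ = [
    "AtlasTruth",
    "CargoTruth",
    "Bundle",
    "generate_atlas",
    "generate_ontology",
    "generate_catalogs",
    "generate_celltype_expression",
    "generate_particles",
    "generate_mirna_counts",
    "generate_bundle",
    "write_atlas_tsv",
    "write_obo_subset",
    "write_annotations_tsv",
    "write_gmt",
    "write_particles_csv",
    "write_counts_tsv",
    "write_truth_json",
]

MEMBRANE_ROOT = "CC:0000002"
VESICLE_ROOT = "CC:0000003"
ONTOLOGY_ROOT = "CC:0000001"

# Bound on |noise| used by the margin construction; Gaussian noise draws are
# clipped to this many standard deviations so planted genes provably pass.
_NOISE_CLIP_SD = 5.0


@dataclass
class AtlasTruth:
    """Ground truth planted into a synthetic expression atlas."""

    planted_marker_ids: list[str]
    fold: float
    detection_floor: float
    seed: int

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("planted fold must exceed 1")


@dataclass
class CargoTruth:
    """Ground truth planted into a synthetic miRNA count matrix."""

    de_mirna_ids: list[str]
    log2_fold_changes: list[float]
    dispersion: float
    library_sizes: list[int]
    seed: int

    def __post_init__(self) -> None:
        if len(self.de_mirna_ids) != len(self.log2_fold_changes):
            raise ValueError("one log2 fold change per planted miRNA is required")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


def _passes_rule(row: np.ndarray, t_idx: int, fold: float, floor: float, margin: float) -> bool:
    """Margin-checked specificity rule used during background rejection."""
    target = row[t_idx]
    others = np.delete(row, t_idx)
    return (target + margin) >= floor and (target + margin) >= fold * max(others.max() - margin, 0.0)


def generate_atlas(
    n_genes: int,
    tissues: Sequence[str],
    target_tissue: str,
    n_planted: int,
    fold: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    detection_floor: float = 1.0,
    log_mu: float = 1.0,
    log_sd: float = 1.0,
) -> tuple[pd.DataFrame, AtlasTruth]:
    """Gene x tissue expression matrix with ``n_planted`` markers of ``target_tissue``.

    Background genes are i.i.d. log-normal across tissues, rejection-resampled
    so that no background gene satisfies the margin-checked fold rule in the
    target tissue. Planted genes have their target-tissue value constructed
    with enough margin that the fold rule holds even after additive Gaussian
    noise (clipped at ±5 sd) is applied to every entry.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if target_tissue not in tissues:
        raise ValueError(f"unknown target tissue {target_tissue!r}")
    if n_planted > n_genes:
        raise ValueError("cannot plant more markers than genes")
    if len(set(tissues)) != len(tissues):
        raise ValueError("tissue names must be unique")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    t_idx = list(tissues).index(target_tissue)
    margin = _NOISE_CLIP_SD * noise_sd

    values = np.empty((n_genes, len(tissues)))
    planted = sorted(rng.choice(genes, size=n_planted, replace=False).tolist())
    planted_set = set(planted)

    for i, gene in enumerate(genes):
        if gene in planted_set:
            row = rng.lognormal(mean=log_mu, sigma=log_sd, size=len(tissues))
            max_other = np.delete(row, t_idx).max()
            # target value with margin: survives clipped noise on both sides;
            # the 1.001 headroom keeps the rule satisfied across the 6-digit
            # text round-trip of the TSV writer
            row[t_idx] = 1.001 * max(
                fold * (max_other + 2 * margin) + 2 * margin, detection_floor + 2 * margin
            )
            values[i] = row
        else:
            while True:
                row = rng.lognormal(mean=log_mu, sigma=log_sd, size=len(tissues))
                if not _passes_rule(row, t_idx, fold, detection_floor, margin):
                    break
            values[i] = row

    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=values.shape)
        np.clip(noise, -margin, margin, out=noise)
        values = np.clip(values + noise, 0.0, None)

    atlas = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=list(tissues))
    truth = AtlasTruth(
        planted_marker_ids=planted, fold=fold, detection_floor=detection_floor, seed=seed
    )
    return atlas, truth


def generate_ontology(
    n_terms: int,
    gene_ids: Sequence[str],
    planted_ids: Sequence[str],
    seed: int = 0,
    max_terms_per_gene: int = 3,
) -> tuple[OntologyGraph, AnnotationSet]:
    """Random acyclic term DAG with a membrane branch and a vesicle branch.

    The first three terms are fixed: a root, a membrane-branch root and a
    vesicle-branch root. Remaining terms attach (1-2 parents) to earlier terms
    within a single branch, which keeps the graph acyclic by construction.
    Every planted gene is annotated to at least one membrane-branch term and
    to no vesicle-branch term; background genes are annotated anywhere.
    """
    if n_terms < 4:
        raise ValueError("need at least 4 terms (root, two branch roots, one leaf)")
    missing = set(planted_ids) - set(gene_ids)
    if missing:
        raise ValueError(f"planted ids not in gene set: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    names = {
        ONTOLOGY_ROOT: "cellular component",
        MEMBRANE_ROOT: "plasma membrane",
        VESICLE_ROOT: "synaptic vesicle",
    }
    graph.add_node(ONTOLOGY_ROOT)
    graph.add_edge(MEMBRANE_ROOT, ONTOLOGY_ROOT)
    graph.add_edge(VESICLE_ROOT, ONTOLOGY_ROOT)

    branch_members: dict[str, list[str]] = {
        MEMBRANE_ROOT: [MEMBRANE_ROOT],
        VESICLE_ROOT: [VESICLE_ROOT],
    }
    for k in range(4, n_terms + 1):
        term = f"CC:{k:07d}"
        branch = MEMBRANE_ROOT if rng.random() < 0.5 else VESICLE_ROOT
        pool = branch_members[branch]
        n_parents = 1 if len(pool) == 1 or rng.random() < 0.7 else 2
        parents = rng.choice(pool, size=n_parents, replace=False)
        for parent in parents:
            graph.add_edge(term, parent)
        branch_members[branch].append(term)
        names[term] = f"synthetic term {k}"

    ontology = OntologyGraph(graph=graph, names=names)
    ontology.validate()  # internal assertion: construction must be acyclic

    membrane_terms = branch_members[MEMBRANE_ROOT]
    all_terms = membrane_terms + branch_members[VESICLE_ROOT]
    planted_set = set(planted_ids)
    pairs: dict[str, set[str]] = {}
    for gene in gene_ids:
        pool = membrane_terms if gene in planted_set else all_terms
        k = int(rng.integers(1, max_terms_per_gene + 1))
        k = min(k, len(pool))
        pairs[gene] = set(rng.choice(pool, size=k, replace=False).tolist())
    return ontology, AnnotationSet(pairs=pairs)


def generate_catalogs(
    gene_ids: Sequence[str],
    coverage_a: float,
    coverage_b: float,
    planted_ids: Sequence[str],
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """Two EV-catalog membership sets; planted ids are forced into both."""
    for cov in (coverage_a, coverage_b):
        if not 0.0 <= cov <= 1.0:
            raise ValueError("coverage must be a probability in [0, 1]")
    missing = set(planted_ids) - set(gene_ids)
    if missing:
        raise ValueError(f"planted ids not in gene set: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    planted = set(planted_ids)
    background = [g for g in gene_ids if g not in planted]
    draws_a = rng.random(len(background)) < coverage_a
    draws_b = rng.random(len(background)) < coverage_b
    cat_a = planted | {g for g, hit in zip(background, draws_a) if hit}
    cat_b = planted | {g for g, hit in zip(background, draws_b) if hit}
    return cat_a, cat_b


def generate_celltype_expression(
    gene_ids: Sequence[str],
    cell_types: Sequence[str] = ("neurons", "astrocytes", "oligodendrocytes", "microglia"),
    seed: int = 0,
    log_mu: float = 2.0,
    log_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-cell-type FPKM-like table used by the ranking stage."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=log_mu, sigma=log_sd, size=(len(gene_ids), len(cell_types)))
    return pd.DataFrame(
        values, index=pd.Index(list(gene_ids), name="gene_id"), columns=list(cell_types)
    )


def generate_particles(
    n: int,
    log_mu: float = np.log(140.0),
    log_sd: float = 0.45,
    channel_probs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-particle table: log-normal diameters plus 0/1 fluorescence channels.

    Defaults put the distribution's density mode near 115 nm with most mass in
    50-400 nm, the range typical of small-EV tracking measurements.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    if log_sd <= 0:
        raise ValueError("log_sd must be positive")
    channel_probs = dict(channel_probs or {})
    for channel, p in channel_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"channel {channel!r} probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({"diameter_nm": rng.lognormal(mean=log_mu, sigma=log_sd, size=n)})
    for channel, p in channel_probs.items():
        table[channel] = (rng.random(n) < p).astype(int)
    return table


def generate_mirna_counts(
    n_mirna: int,
    n_per_group: int,
    truth: CargoTruth,
    baseline_log_mean: float = np.log(100.0),
    baseline_log_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial miRNA x sample count matrix with planted fold changes.

    Counts follow a gamma-Poisson mixture with mean
    ``baseline * library_factor * 2**(lfc * group)`` and variance
    ``mu + dispersion * mu**2``; group A samples come first.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    n_samples = 2 * n_per_group
    if len(truth.library_sizes) != n_samples:
        raise ValueError(f"expected {n_samples} library sizes, got {len(truth.library_sizes)}")

    rng = np.random.default_rng(truth.seed)
    mirnas = [f"mir-{i:04d}" for i in range(1, n_mirna + 1)]
    unknown = set(truth.de_mirna_ids) - set(mirnas)
    if unknown:
        raise ValueError(f"planted miRNA ids outside matrix: {sorted(unknown)}")

    baseline = rng.lognormal(mean=baseline_log_mean, sigma=baseline_log_sd, size=n_mirna)
    lfc = np.zeros(n_mirna)
    idx = {m: i for i, m in enumerate(mirnas)}
    for mid, change in zip(truth.de_mirna_ids, truth.log2_fold_changes):
        lfc[idx[mid]] = change

    lib = np.asarray(truth.library_sizes, dtype=float)
    lib_factor = lib / lib.mean()
    group = np.array([0] * n_per_group + [1] * n_per_group)
    mu = baseline[:, None] * lib_factor[None, :] * np.power(2.0, lfc[:, None] * group[None, :])

    shape = 1.0 / truth.dispersion
    lam = rng.gamma(shape=shape, scale=mu / shape)
    counts = rng.poisson(lam)

    samples = [f"A{i+1}" for i in range(n_per_group)] + [f"B{i+1}" for i in range(n_per_group)]
    matrix = pd.DataFrame(counts, index=pd.Index(mirnas, name="mirna_id"), columns=samples)
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples, name="group")
    return matrix, groups


@dataclass
class Bundle:
    """Everything the discovery pipeline consumes, plus its planted truth."""

    atlas: pd.DataFrame
    atlas_truth: AtlasTruth
    ontology: OntologyGraph
    annotations: AnnotationSet
    catalogs: list[set[str]]
    celltype_expression: pd.DataFrame
    target_tissue: str
    membrane_term: str = MEMBRANE_ROOT
    vesicle_term: str = VESICLE_ROOT


def generate_bundle(
    seed: int,
    n_genes: int = 100,
    tissues: Sequence[str] = (
        "brain",
        "heart",
        "kidney",
        "liver",
        "spleen",
        "lung",
        "muscle",
        "pancreas",
    ),
    target_tissue: str = "brain",
    n_planted: int = 5,
    fold: float = 4.0,
    noise_sd: float = 0.0,
    n_terms: int = 50,
    coverage_a: float = 0.3,
    coverage_b: float = 0.3,
) -> Bundle:
    """One-call synthetic study: atlas, ontology, catalogs and cell-type table.

    Sub-generators receive distinct seeds derived from ``seed`` via numpy's
    seed-sequence spawning, so bundles are deterministic yet the streams are
    independent.
    """
    children = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    atlas, truth = generate_atlas(
        n_genes, tissues, target_tissue, n_planted, fold=fold, noise_sd=noise_sd, seed=seeds[0]
    )
    ontology, annotations = generate_ontology(
        n_terms, gene_ids=list(atlas.index), planted_ids=truth.planted_marker_ids, seed=seeds[1]
    )
    cat_a, cat_b = generate_catalogs(
        list(atlas.index), coverage_a, coverage_b, truth.planted_marker_ids, seed=seeds[2]
    )
    expr = generate_celltype_expression(list(atlas.index), seed=seeds[3])
    return Bundle(
        atlas=atlas,
        atlas_truth=truth,
        ontology=ontology,
        annotations=annotations,
        catalogs=[cat_a, cat_b],
        celltype_expression=expr,
        target_tissue=target_tissue,
    )


# ---------------------------------------------------------------------------
# writers (plain-text formats; deterministic byte output)
# ---------------------------------------------------------------------------

def write_atlas_tsv(atlas: pd.DataFrame, path) -> None:
    atlas.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def write_obo_subset(ontology: OntologyGraph, path) -> None:
    """Write [Term] stanzas (id/name/is_a) in sorted term order."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\n")
        for term in sorted(ontology.graph.nodes):
            handle.write("\n[Term]\n")
            handle.write(f"id: {term}\n")
            name = ontology.names.get(term)
            if name:
                handle.write(f"name: {name}\n")
            for parent in sorted(ontology.graph.successors(term)):
                handle.write(f"is_a: {parent}\n")


def write_annotations_tsv(annotations: AnnotationSet, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene in sorted(annotations.pairs):
            for term in sorted(annotations.pairs[gene]):
                handle.write(f"{gene}\t{term}\n")


def write_gmt(catalog: set[str], name: str, path, description: str = "synthetic") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join([name, description, *sorted(catalog)]) + "\n")


def write_particles_csv(particles: pd.DataFrame, path) -> None:
    particles.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def write_counts_tsv(counts: pd.DataFrame, groups: pd.Series, counts_path, groups_path) -> None:
    counts.to_csv(counts_path, sep="\t", lineterminator="\n")
    groups.rename_axis("sample_id").to_csv(groups_path, sep="\t", lineterminator="\n")


def write_truth_json(truth, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(asdict(truth), handle, indent=2, sort_keys=True)
        handle.write("\n")
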