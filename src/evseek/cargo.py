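"""EV cargo comparison statistics.

Protein-set Venn partitioning with sharing percentages, hypergeometric
over-representation analysis (ORA) with Benjamini–Hochberg correction, and a
small miRNA count stack: CPM normalization, low-expression filtering, a
two-group Welch test on log2(CPM + pseudocount), and a deterministic PCA
projection.

The differential stage is a deliberately simple, transparent test — not a
negative-binomial empirical-Bayes fit — so its numbers are oracle-checkable;
numeric concordance with edgeR-style pipelines is not claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SetPartition",
    "venn_partition",
    "sharing_percentage",
    "hypergeom_enrichment",
    "bh_adjust",
    "cpm_normalize",
    "filter_low_expression",
    "differential_test",
    "pca_projection",
]


@dataclass
class SetPartition:
    """Three-cell Venn partition of two identifier sets."""

    only_a: int
    shared: int
    only_b: int
    ids_only_a: list[str]
    ids_shared: list[str]
    ids_only_b: list[str]


def venn_partition(set_a: Iterable[str], set_b: Iterable[str]) -> SetPartition:
    """Exact two-set partition; id lists are sorted for determinism."""
    a, b = set(set_a), set(set_b)
    only_a = sorted(a - b)
    shared = sorted(a & b)
    only_b = sorted(b - a)
    return SetPartition(
        only_a=len(only_a),
        shared=len(shared),
        only_b=len(only_b),
        ids_only_a=only_a,
        ids_shared=shared,
        ids_only_b=only_b,
    )


def sharing_percentage(partition: SetPartition, side: str) -> float:
    """Percentage of one side's ids that are shared with the other side."""
    if side not in {"a", "b"}:
        raise ValueError(f"side must be 'a' or 'b', got {side!r}")
    only_side = partition.only_a if side == "a" else partition.only_b
    denominator = partition.shared + only_side
    if denominator == 0:
        raise ValueError(f"side {side!r} is empty")
    return 100.0 * partition.shared / denominator


def hypergeom_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, list[str]]:
    """Upper-tail hypergeometric ORA of a study set against term sets.

    Each term set is intersected with the population before testing; terms
    with no population members are skipped and reported in the second return
    value. p = P(X >= k) with N = |population|, K = |term ∩ population|,
    n = |study|; q-values are BH across all tested terms.
    """
    study = set(study)
    population = set(population)
    outside = study - population
    if outside:
        raise ValueError(f"study ids outside the population: {sorted(outside)[:10]}")

    N, n = len(population), len(study)
    rows, skipped = [], []
    for name in sorted(term_sets):
        members = set(term_sets[name]) & population
        K = len(members)
        if K == 0:
            skipped.append(name)
            continue
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))

    result = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "p_value"]
    ).set_index("term")
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].to_numpy())
    else:
        result["q_value"] = pd.Series(dtype=float)
    return result, skipped


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: 1e6 * count / sample library size, per column."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        empty = list(lib.index[lib <= 0])
        raise ValueError(f"samples with zero library size: {empty}")
    return 1e6 * counts / lib


def filter_low_expression(
    counts: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    groups: pd.Series | None = None,
) -> pd.Series:
    """Keep features with CPM >= min_cpm in at least ``min_samples`` samples.

    When ``min_samples`` is omitted it defaults to the smaller group size
    (requires ``groups``), the usual convention for two-group count filters.
    Returns a boolean keep-flag per feature.
    """
    if min_samples is None:
        if groups is None:
            raise ValueError("min_samples or groups must be provided")
        min_samples = int(groups.value_counts().min())
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    cpm = cpm_normalize(counts)
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    keep.name = "passed_filter"
    return keep


def _welch_rowwise(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t on rows; degenerate rows (both groups constant, equal means)
    are mapped to statistic 0, p 1 instead of NaN."""
    with warnings.catch_warnings():
        # near-constant rows trigger scipy's precision warning; those rows are
        # remapped below, so the warning is noise here
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    stat = np.asarray(stat, dtype=float)
    p = np.asarray(p, dtype=float)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    equal_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    degenerate = zero_var & equal_mean
    stat[degenerate] = 0.0
    p[degenerate] = 1.0
    return stat, p


def differential_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group differential expression on log2(CPM + pseudocount).

    Low-expressed features are filtered first and carry no p-value. The
    statistic is a two-sided Welch t-test; log2FC is the mean difference of
    the transformed values (second group minus first, groups ordered by
    label sort); q-values are BH across retained features.
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    group_a, group_b = labels
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    keep = filter_low_expression(counts, min_cpm=min_cpm, min_samples=min_samples, groups=groups)
    log_cpm = np.log2(cpm_normalize(counts) + pseudocount)

    result = pd.DataFrame(index=counts.index)
    result["passed_filter"] = keep
    result["log2_fold_change"] = np.nan
    result["statistic"] = np.nan
    result["p_value"] = np.nan
    result["q_value"] = np.nan

    retained = log_cpm.loc[keep]
    if len(retained):
        a = retained[cols_a].to_numpy(dtype=float)
        b = retained[cols_b].to_numpy(dtype=float)
        stat, p = _welch_rowwise(a, b)
        result.loc[keep, "log2_fold_change"] = b.mean(axis=1) - a.mean(axis=1)
        result.loc[keep, "statistic"] = stat
        result.loc[keep, "p_value"] = p
        result.loc[keep, "q_value"] = bh_adjust(p)
    return result


def pca_projection(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered SVD projection of samples (rows) onto principal axes.

    Returns per-sample scores and the variance fraction per component. The
    sign of each component is fixed by making its largest-magnitude loading
    positive, so outputs are deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    centered = X - X.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("degenerate all-constant input")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U[:, :n_components] * s[:n_components]
    total_var = float((s**2).sum())
    fractions = (s[:n_components] ** 2) / total_var
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    score_df = pd.DataFrame(
        scores, index=index, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    return score_df, fractions
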