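"""Digital expression profiling of miRNAs across libraries.

Counts are normalised to tags per million (TPM) against each library's
putative small-RNA population size; contrasts are log2(treatment/control)
ratios with zeros flagged rather than imputed; detection overlaps are
partitioned Venn-style; and expression profiles are clustered with the
uncentered-Pearson distance under average linkage (UPGMA).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

__all__ = [
    "ExpressionMatrix",
    "Dendrogram",
    "tpm_normalize",
    "log2_fold_change",
    "select_de",
    "venn_partition",
    "uncentered_pearson_distance",
    "cluster_uncentered_average",
]

SCALE = 1_000_000.0


@dataclass
class ExpressionMatrix:
    """TPM values (miRNA x library) with the raw counts and library totals kept."""

    tpm: pd.DataFrame
    counts: pd.DataFrame
    library_totals: pd.Series

    def detected(self, min_count: int = 1) -> pd.DataFrame:
        return self.counts >= min_count


@dataclass
class Dendrogram:
    """Average-linkage merge tree over labelled profiles."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy format: [left, right, height, size]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            # UPGMA ultrametric: a node sits at half its merge height
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height / 2.0:.6g}"
            length = (parent_height - node.dist) / 2.0
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        if tree.is_leaf():
            return f"{self.labels[tree.id]}:0;"
        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def tpm_normalize(
    counts: pd.DataFrame, library_totals: Mapping[str, int] | pd.Series
) -> ExpressionMatrix:
    """TPM[i,j] = counts[i,j] / total[j] * 10^6.

    ``library_totals`` is each library's putative small-RNA population size
    (redundant reads surviving elimination), so summing TPM over the whole
    population returns 10^6 per library.
    """
    totals = pd.Series(library_totals).reindex(counts.columns)
    if totals.isna().any():
        missing = list(totals[totals.isna()].index)
        raise ValueError(f"missing library totals for {missing}")
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    tpm = counts.astype(float).div(totals.astype(float), axis=1) * SCALE
    return ExpressionMatrix(tpm=tpm, counts=counts.copy(), library_totals=totals)


def log2_fold_change(
    tpm: pd.DataFrame, contrasts: Mapping[str, tuple[str, str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log2(treatment/control) per contrast; zero on either side is flagged.

    Returns (fold_change, status): status entries are 'finite' or
    'undefined_zero'; undefined cells hold NaN in the fold-change table.
    """
    fc = pd.DataFrame(index=tpm.index, columns=list(contrasts), dtype=float)
    status = pd.DataFrame("finite", index=tpm.index, columns=list(contrasts))
    for name, (treatment, control) in contrasts.items():
        t = tpm[treatment].to_numpy(dtype=float)
        c = tpm[control].to_numpy(dtype=float)
        defined = (t > 0) & (c > 0)
        vals = np.full(len(t), np.nan)
        vals[defined] = np.log2(t[defined] / c[defined])
        fc[name] = vals
        status.loc[~defined, name] = "undefined_zero"
    return fc, status


def select_de(fold_change: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Rows with |log2FC| >= threshold (boundary inclusive) in any contrast."""
    finite = fold_change.notna()
    hits = (fold_change.abs() >= threshold) & finite
    mask = hits.any(axis=1)
    if not finite.any(axis=1).any():
        warnings.warn("all fold changes undefined (zero TPM on one side)")
    return fold_change.loc[mask]


def venn_partition(
    detected: pd.DataFrame, library_group: Sequence[str]
) -> dict[frozenset, int]:
    """Counts over all 2^k - 1 regions of the k-set detection Venn diagram.

    ``detected`` is a boolean miRNA x library frame; each miRNA detected in
    at least one group member is assigned to exactly one region (the set of
    members it is detected in).
    """
    k = len(library_group)
    if k > 6:
        raise ValueError("Venn partition supports at most 6 sets")
    if k == 0:
        raise ValueError("library group must be non-empty")
    regions: dict[frozenset, int] = {}
    for r in range(1, k + 1):
        for combo in combinations(library_group, r):
            regions[frozenset(combo)] = 0
    sub = detected[list(library_group)]
    for _, row in sub.iterrows():
        members = frozenset(lib for lib in library_group if bool(row[lib]))
        if members:
            regions[members] += 1
    return regions


def uncentered_pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """d(x,y) = 1 - sum(x*y) / sqrt(sum(x^2) * sum(y^2)); rows are profiles."""
    X = matrix.to_numpy(dtype=float)
    norms = np.sqrt((X**2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        bad = matrix.index[zero][0]
        raise ValueError(f"all-zero profile {bad!r} has no uncentered correlation")
    sim = (X @ X.T) / np.outer(norms, norms)
    D = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def cluster_uncentered_average(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """UPGMA over the uncentered-Pearson distance.

    ``axis`` selects whether rows (miRNAs) or columns (libraries) are
    clustered.  Labels are sorted lexicographically beforehand so merge
    tie-breaks are deterministic.
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if len(matrix) < 2:
        raise ValueError("need at least two profiles to cluster")
    matrix = matrix.loc[sorted(matrix.index.astype(str))]
    D = uncentered_pearson_distance(matrix)
    Z = linkage(squareform(D.to_numpy(), checks=False), method="average")
    return Dendrogram(labels=list(matrix.index), linkage_matrix=Z)
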