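"""Normalization, gene filtering, probe reduction and unsupervised clustering.

All operations take and return genes × samples DataFrames (see
:mod:`ssges.io`).  The pipeline mirrors standard microarray practice:
log2 transform, quantile normalization, a median-fold-change variation
filter, replicate averaging, probe-to-gene collapsing by maximal average
intensity, and average-linkage hierarchical clustering of samples under
a one-minus-Pearson-correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

__all__ = [
    "FilterParams",
    "Dendrogram",
    "log2_transform",
    "quantile_normalize",
    "variation_filter",
    "average_replicates",
    "collapse_probes",
    "center_scale_genes",
    "cluster_samples",
]


@dataclass(frozen=True)
class FilterParams:
    """Variation/missingness filter thresholds.

    A gene is kept iff at least ``min_fraction`` of its non-missing
    values differ from the gene median by ``fold_change``-fold or more
    (|v - median| >= log2(fold_change) on the log2 scale) AND its
    missing fraction does not exceed ``max_missing``.
    """

    fold_change: float = 1.5
    min_fraction: float = 0.10
    max_missing: float = 0.60

    def __post_init__(self) -> None:
        if not self.fold_change > 1:
            raise ValueError("fold_change must be > 1")
        if not (0 <= self.min_fraction <= 1):
            raise ValueError("min_fraction must lie in [0, 1]")
        if not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing must lie in [0, 1]")


@dataclass
class Dendrogram:
    """Average-linkage sample tree.

    Attributes
    ----------
    linkage:
        scipy linkage matrix (heights in 1 − correlation units).
    leaf_order:
        sample ids in dendrogram leaf order.
    sample_ids:
        sample ids in input order (leaf index i refers to sample_ids[i]).
    """

    linkage: np.ndarray
    leaf_order: list[str]
    sample_ids: list[str]

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def _fmt(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            left, right = node.get_left(), node.get_right()
            ld = node.dist - left.dist
            rd = node.dist - right.dist
            return f"({_fmt(left)}:{ld:.6g},{_fmt(right)}:{rd:.6g})"

        return _fmt(tree) + ";"


def log2_transform(m: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """log2 of linear-scale intensities, clamping values below ``floor``."""
    if not floor > 0:
        raise ValueError("floor must be positive")
    return np.log2(m.clip(lower=floor))


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common distribution of rank means.

    After normalization every column's sorted value vector equals the
    vector of cross-sample means of order statistics; within-column
    ranks are preserved.  Ties receive the mean of the rank means over
    the tied positions.  Missing values stay missing and are excluded
    from rank computation; a column with k non-missing entries is mapped
    through the reference distribution by quantile interpolation.
    """
    if m.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return m.copy()
    X = m.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    grid = np.linspace(0.0, 1.0, n_genes)

    # reference distribution: mean over columns of each column's
    # empirical quantile function evaluated on a common grid
    ref = np.zeros(n_genes)
    for j in range(n_samples):
        col = X[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            raise ValueError(f"column {m.columns[j]!r} is entirely missing")
        if obs.size == n_genes:
            ref += obs
        else:
            q = np.linspace(0.0, 1.0, obs.size)
            ref += np.interp(grid, q, obs)
    ref /= n_samples

    out = np.full_like(X, np.nan)
    for j in range(n_samples):
        col = X[:, j]
        ok = ~np.isnan(col)
        k = int(ok.sum())
        # average ranks handle ties: tied entries share the mean of the
        # implicated reference positions
        order = np.argsort(col[ok], kind="mergesort")
        ranks = np.empty(k)
        ranks[order] = np.arange(k, dtype=float)
        vals = col[ok]
        # convert ordinal ranks to average ranks over ties
        sorted_vals = vals[order]
        avg = np.arange(k, dtype=float)
        i = 0
        while i < k:
            j2 = i
            while j2 + 1 < k and sorted_vals[j2 + 1] == sorted_vals[i]:
                j2 += 1
            avg[i : j2 + 1] = 0.5 * (i + j2)
            i = j2 + 1
        avg_ranks = np.empty(k)
        avg_ranks[order] = avg
        if k == 1:
            q = np.array([0.5])
        else:
            q = avg_ranks / (k - 1)
        out[ok, j] = np.interp(q, grid, ref)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def variation_filter(m: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Drop flat and mostly-missing genes; preserves gene order.

    On the log2 scale the fold-change criterion reads
    |v − median(gene)| >= log2(fold_change); "at least min_fraction"
    is inclusive, so a gene at exactly the threshold fraction is kept.
    A gene with all values missing counts as 100% missing and is dropped.
    """
    p = params or FilterParams()
    X = m.to_numpy(dtype=float)
    n = X.shape[1]
    if n == 0:
        raise ValueError("matrix has no samples")
    n_missing = np.isnan(X).sum(axis=1)
    frac_missing = n_missing / n
    thresh = np.log2(p.fold_change)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(X, axis=1)
        dev = np.abs(X - med[:, None]) >= thresh
        n_obs = n - n_missing
        frac_var = np.where(n_obs > 0, np.nansum(dev, axis=1) / np.maximum(n_obs, 1), 0.0)
    keep = (frac_var >= p.min_fraction) & (frac_missing <= p.max_missing)
    return m.loc[keep]


def average_replicates(
    m: pd.DataFrame, replicate_groups: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse replicate rows to their per-sample mean (missing ignored).

    ``replicate_groups`` maps gene/probe id to a group key; rows sharing
    a key are averaged into one row labelled with the key.  An empty map
    is the identity.
    """
    if not replicate_groups:
        return m.copy()
    unmapped = [g for g in m.index if g not in replicate_groups]
    if unmapped:
        raise KeyError(f"gene ids without replicate group: {unmapped[:5]}")
    keys = pd.Index([replicate_groups[g] for g in m.index], name=m.index.name)
    grouped = m.groupby(keys, sort=False).mean()
    return grouped


def collapse_probes(m: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Keep, per gene symbol, the probe with maximal average intensity.

    Mean intensity is taken across samples ignoring missing values; exact
    ties keep the probe appearing earlier in input order.  Rows are
    relabelled to the gene symbol, in order of each gene's first probe.
    """
    unmapped = [p for p in m.index if p not in probe_to_gene]
    if unmapped:
        raise KeyError(f"unmapped probe id: {unmapped[0]!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(m.to_numpy(dtype=float), axis=1)
    means = np.where(np.isnan(means), -np.inf, means)
    best: dict[str, tuple[int, float]] = {}
    for i, probe in enumerate(m.index):
        gene = probe_to_gene[probe]
        if gene not in best or means[i] > best[gene][1]:
            best[gene] = (i, means[i])
    rows = [i for i, _ in best.values()]
    out = m.iloc[rows].copy()
    out.index = pd.Index(list(best.keys()), name=m.index.name)
    return out


def center_scale_genes(m: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, SD 1 over non-missing entries."""
    X = m.to_numpy(dtype=float)
    n_obs = (~np.isnan(X)).sum(axis=1)
    if (n_obs < 2).any():
        bad = list(m.index[n_obs < 2])
        raise ValueError(f"genes with <2 non-missing values: {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=1)
        sd = np.nanstd(X, axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(m.index[sd == 0])
        raise ValueError(f"zero-spread genes (filter first): {bad[:5]}")
    return pd.DataFrame((X - mu[:, None]) / sd[:, None], index=m.index, columns=m.columns)


def cluster_samples(m: pd.DataFrame) -> Dendrogram:
    """Average-linkage clustering of samples under 1 − Pearson distance.

    Correlations use pairwise-complete genes; a sample pair sharing
    fewer than 3 genes is an error.  Genes should be centered and scaled
    by the caller beforehand.
    """
    X = m.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if ok.sum() < 3:
                raise ValueError(
                    f"samples {m.columns[i]!r} and {m.columns[j]!r} share "
                    f"fewer than 3 non-missing genes"
                )
            xi, xj = X[ok, i], X[ok, j]
            sxi, sxj = xi.std(), xj.std()
            if sxi == 0 or sxj == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(xi, xj)[0, 1])
            D[i, j] = D[j, i] = 1.0 - r
    condensed = D[np.triu_indices(n, k=1)]
    Z = sch.linkage(condensed, method="average")
    leaves = sch.leaves_list(Z)
    ids = [str(c) for c in m.columns]
    return Dendrogram(linkage=Z, leaf_order=[ids[i] for i in leaves], sample_ids=ids)
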