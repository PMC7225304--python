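"""Per-gene two-class comparison and significance analysis of microarrays (SAM).

Two stages of the signature derivation live here.

**Univariate class comparison** — a pooled-variance two-sample t-test per
gene, with two-sided p-values from the t distribution.  Genes with fewer
than two observations in either group, or zero pooled variance, are
flagged unevaluable rather than silently dropped.

**SAM** — the moderated statistic

    d(i) = (x̄₁(i) − x̄₂(i)) / (s(i) + s₀)

where s(i) is the pooled standard error of the mean difference and s₀ a
small "fudge factor" stabilising the variance of d across the intensity
range.  Significance is assessed against expected null order statistics
d̄(i) obtained by permuting class labels: genes whose sorted d departs
from d̄ by more than a threshold Δ (asymmetric upper/lower cutpoints) are
called, and the false discovery rate is estimated as the median number
of null genes beyond the cutpoints across permutations, divided by the
number called (π₀ fixed at 1, conservative).  Δ is chosen as the
smallest grid value whose estimated FDR meets the target.

The machinery is exposed both as the :class:`SAM` estimator
(``fit(X, y)`` with samples × genes input, sklearn-style) and as
module-level functions operating on genes × samples matrices.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClassComparisonResult",
    "SamResult",
    "ttest_per_gene",
    "select_significant",
    "sam_statistic",
    "choose_s0",
    "sam_permutation_null",
    "sam_call",
    "sam_select_delta",
    "SAM",
]


# ---------------------------------------------------------------------------
# pooled two-sample t machinery (vectorised, missing-aware)
# ---------------------------------------------------------------------------

def _group_masks(groups: Sequence, levels: Sequence | None = None):
    g = np.asarray(groups)
    if levels is None:
        levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {list(levels)}")
    return g == levels[0], g == levels[1], list(levels)


def _pooled_stats(X: np.ndarray, mask1: np.ndarray, mask2: np.ndarray):
    """Means, pooled standard error and group sizes per gene (rows)."""
    X1, X2 = X[:, mask1], X[:, mask2]
    n1 = (~np.isnan(X1)).sum(axis=1)
    n2 = (~np.isnan(X2)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(np.where(n1[:, None] > 0, X1, np.nan), axis=1)
        m2 = np.nanmean(np.where(n2[:, None] > 0, X2, np.nan), axis=1)
        v1 = np.nanvar(X1, axis=1, ddof=1)
        v2 = np.nanvar(X2, axis=1, ddof=1)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.where(df > 0, df, 1)
        se = np.sqrt(pooled_var * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
    return m1, m2, se, n1, n2, df


@dataclass
class ClassComparisonResult:
    """Per-gene pooled t-test results for one two-class comparison."""

    table: pd.DataFrame  # columns: t, p, direction, n1, n2, evaluable
    group_levels: list

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def significant(self, alpha: float) -> list[str]:
        return select_significant(self, alpha)


def ttest_per_gene(
    m: pd.DataFrame, groups: Sequence, levels: Sequence | None = None, welch: bool = False
) -> ClassComparisonResult:
    """Pooled-variance two-sample t-test for every gene row.

    ``groups`` gives a label per sample (matrix column).  The t statistic
    is signed as mean(first level) − mean(second level); ``direction``
    is "up" where the first level has the larger mean.  Set
    ``welch=True`` for the unequal-variance variant.
    """
    mask1, mask2, lv = _group_masks(groups, levels)
    X = m.to_numpy(dtype=float)
    if welch:
        X1, X2 = X[:, mask1], X[:, mask2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(X1, X2, axis=1, equal_var=False, nan_policy="omit")
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        n1 = (~np.isnan(X1)).sum(axis=1)
        n2 = (~np.isnan(X2)).sum(axis=1)
        m1 = np.nanmean(np.where(n1[:, None] > 0, X1, np.nan), axis=1)
        m2 = np.nanmean(np.where(n2[:, None] > 0, X2, np.nan), axis=1)
        evaluable = np.isfinite(t)
    else:
        m1, m2, se, n1, n2, df = _pooled_stats(X, mask1, mask2)
        evaluable = (n1 >= 2) & (n2 >= 2) & (se > 0) & np.isfinite(se)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(evaluable, (m1 - m2) / np.where(se > 0, se, 1.0), np.nan)
            p = np.where(
                evaluable, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan
            )
    direction = np.where(m1 >= m2, "up", "down")
    table = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "direction": direction,
            "n1": n1,
            "n2": n2,
            "evaluable": evaluable,
        },
        index=m.index,
    )
    return ClassComparisonResult(table=table, group_levels=lv)


def select_significant(r: ClassComparisonResult, alpha: float) -> list[str]:
    """Genes with p strictly below ``alpha``, input order preserved."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    t = r.table
    keep = t["evaluable"] & (t["p"] < alpha)
    return list(t.index[keep])


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def sam_statistic(
    m: pd.DataFrame, groups: Sequence, s0: float = 0.0, levels: Sequence | None = None
) -> pd.Series:
    """SAM statistic d(i) = (x̄₁ − x̄₂)/(s(i) + s₀) per gene.

    With s₀ = 0 this equals the pooled-variance t statistic.  Degenerate
    genes (zero spread with s₀ = 0, or <2 samples per group) are NaN.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    mask1, mask2, _ = _group_masks(groups, levels)
    X = m.to_numpy(dtype=float)
    d = _sam_d(X, mask1, mask2, s0)
    return pd.Series(d, index=m.index, name="d")


def _sam_d(X: np.ndarray, mask1: np.ndarray, mask2: np.ndarray, s0: float) -> np.ndarray:
    m1, m2, se, n1, n2, _ = _pooled_stats(X, mask1, mask2)
    denom = se + s0
    ok = (n1 >= 2) & (n2 >= 2) & (denom > 0) & np.isfinite(denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(ok, (m1 - m2) / np.where(denom > 0, denom, 1.0), np.nan)
    return d


def _sam_se(X: np.ndarray, mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    return _pooled_stats(X, mask1, mask2)[2]


def choose_s0(
    m: pd.DataFrame,
    groups: Sequence,
    levels: Sequence | None = None,
    n_windows: int = 10,
) -> float:
    """Pick the fudge factor s₀ stabilising the spread of d across s.

    Candidates are the percentiles {0, 5, …, 95} of the per-gene pooled
    standard errors s(i).  For each candidate the genes are binned into
    ``n_windows`` quantile windows of s, the median absolute deviation
    of d is computed per window, and the candidate minimising the
    coefficient of variation of those spreads wins; ties go to the
    smallest candidate.
    """
    mask1, mask2, _ = _group_masks(groups, levels)
    X = m.to_numpy(dtype=float)
    se = _sam_se(X, mask1, mask2)
    ok = np.isfinite(se) & (se > 0)
    se_ok = se[ok]
    if se_ok.size < 10:
        raise ValueError("need at least 10 evaluable genes to choose s0")
    candidates = np.unique(np.percentile(se_ok, np.arange(0, 100, 5)))
    if np.allclose(se_ok, se_ok[0]):
        return 0.0
    edges = np.quantile(se_ok, np.linspace(0, 1, n_windows + 1))
    bins = np.clip(np.searchsorted(edges, se_ok, side="right") - 1, 0, n_windows - 1)
    best_cv, best_s0 = np.inf, 0.0
    for s0 in np.concatenate(([0.0], candidates)):
        d = _sam_d(X, mask1, mask2, float(s0))[ok]
        mads = np.array(
            [
                np.median(np.abs(d[bins == b] - np.median(d[bins == b])))
                for b in range(n_windows)
                if (bins == b).any()
            ]
        )
        mean_mad = mads.mean()
        cv = mads.std() / mean_mad if mean_mad > 0 else np.inf
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _balanced_assignments(n: int, n1: int, n_perm: int, rng: np.random.Generator):
    """Index sets of size n1 defining permuted group-1 membership.

    If ``n_perm`` meets or exceeds the number of distinct assignments,
    every distinct assignment is used exactly once; otherwise ``n_perm``
    distinct assignments are sampled without replacement.
    """
    total = math.comb(n, n1)
    if n_perm >= total:
        return [np.array(c) for c in itertools.combinations(range(n), n1)]
    seen: set[tuple] = set()
    out = []
    while len(out) < n_perm:
        idx = tuple(sorted(rng.choice(n, size=n1, replace=False).tolist()))
        if idx in seen:
            continue
        seen.add(idx)
        out.append(np.array(idx))
    return out


def sam_permutation_null(
    m: pd.DataFrame,
    groups: Sequence,
    n_perm: int = 100,
    seed: int = 0,
    s0: float = 0.0,
    levels: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of sorted d under balanced label permutation.

    Returns ``(null_sorted, dbar)``: ``null_sorted`` has one row per
    permutation holding the sorted d values over evaluable genes;
    ``dbar[i]`` is the mean i-th order statistic across permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mask1, mask2, _ = _group_masks(groups, levels)
    X = m.to_numpy(dtype=float)[:, mask1 | mask2]
    n = X.shape[1]
    n1 = int(mask1.sum())
    d_obs = _sam_d(m.to_numpy(dtype=float), mask1, mask2, s0)
    ok = np.isfinite(d_obs)
    Xe = X[ok]
    rng = np.random.default_rng(seed)
    assignments = _balanced_assignments(n, n1, n_perm, rng)
    null_rows = []
    for idx in assignments:
        pm1 = np.zeros(n, dtype=bool)
        pm1[idx] = True
        d_perm = _sam_d(Xe, pm1, ~pm1, s0)
        d_perm = np.where(np.isfinite(d_perm), d_perm, 0.0)
        null_rows.append(np.sort(d_perm))
    null_sorted = np.vstack(null_rows)
    dbar = null_sorted.mean(axis=0)
    return null_sorted, dbar


@dataclass
class SamResult:
    """Outcome of a SAM run: per-gene scores and the calling threshold."""

    table: pd.DataFrame  # columns: d, dbar, called (evaluable genes, input order)
    s0: float
    delta: float
    fdr_estimate: float
    n_permutations: int
    seed: int
    cut_up: float = np.inf
    cut_low: float = -np.inf

    @property
    def called_genes(self) -> list[str]:
        return list(self.table.index[self.table["called"]])


def _cutpoints(d_sorted: np.ndarray, dbar: np.ndarray, delta: float):
    """Asymmetric upper/lower cutpoints for a given Δ.

    Moving up from the origin along sorted d, the first gene whose d
    exceeds its expected d̄ by ≥ Δ sets the upper cutpoint (all larger d
    called); symmetrically downward for the lower cutpoint.
    """
    diff = d_sorted - dbar
    cut_up = np.inf
    upper = np.where(d_sorted >= 0)[0]
    for i in upper:  # ascending d
        if diff[i] >= delta:
            cut_up = d_sorted[i]
            break
    cut_low = -np.inf
    lower = np.where(d_sorted < 0)[0]
    for i in lower[::-1]:  # descending |d| from the origin
        if -diff[i] >= delta:
            cut_low = d_sorted[i]
            break
    return cut_up, cut_low


def _false_calls(null_sorted: np.ndarray, cut_up: float, cut_low: float) -> float:
    """Median across permutations of null genes beyond the cutpoints."""
    n_perm, _ = null_sorted.shape
    counts = np.empty(n_perm)
    for r in range(n_perm):
        row = null_sorted[r]
        n_up = row.size - np.searchsorted(row, cut_up, side="left")
        n_dn = np.searchsorted(row, cut_low, side="right")
        counts[r] = n_up + n_dn
    return float(np.median(counts))


def sam_call(
    d: pd.Series,
    dbar: np.ndarray,
    null_sorted: np.ndarray,
    delta: float,
    s0: float = 0.0,
    n_permutations: int | None = None,
    seed: int = 0,
) -> SamResult:
    """Call significant genes at threshold Δ and estimate the FDR.

    ``d`` holds observed statistics over evaluable genes; ``dbar`` and
    ``null_sorted`` come from :func:`sam_permutation_null`.  The FDR is
    the median permutation false-call count divided by the number of
    genes called (0 when nothing is called), with π₀ = 1.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    dv = d.to_numpy(dtype=float)
    ok = np.isfinite(dv)
    d_ok = dv[ok]
    order = np.argsort(d_ok, kind="mergesort")
    d_sorted = d_ok[order]
    if d_sorted.size != dbar.size:
        raise ValueError("d and dbar must align over evaluable genes")
    cut_up, cut_low = _cutpoints(d_sorted, dbar, delta)
    called_ok = (d_ok >= cut_up) | (d_ok <= cut_low)
    n_called = int(called_ok.sum())
    if n_called == 0:
        fdr = 0.0
    else:
        fdr = min(1.0, _false_calls(null_sorted, cut_up, cut_low) / n_called)
    dbar_by_gene = np.empty_like(d_ok)
    dbar_by_gene[order] = dbar
    table = pd.DataFrame(
        {"d": d_ok, "dbar": dbar_by_gene, "called": called_ok},
        index=d.index[ok],
    )
    return SamResult(
        table=table,
        s0=s0,
        delta=float(delta),
        fdr_estimate=fdr,
        n_permutations=n_permutations or null_sorted.shape[0],
        seed=seed,
        cut_up=cut_up,
        cut_low=cut_low,
    )


def sam_select_delta(
    d: pd.Series,
    dbar: np.ndarray,
    null_sorted: np.ndarray,
    target_fdr: float = 0.01,
    n_grid: int = 200,
) -> float:
    """Smallest Δ on a fine grid whose estimated FDR meets the target.

    Only thresholds calling at least one gene qualify; if none does, the
    empty-call Δ (beyond the largest departure) is returned with a
    warning.  ``target_fdr = 1`` returns Δ = 0.
    """
    if not (0 < target_fdr <= 1):
        raise ValueError("target_fdr must lie in (0, 1]")
    dv = d.to_numpy(dtype=float)
    d_ok = np.sort(dv[np.isfinite(dv)])
    max_dep = float(np.max(np.abs(d_ok - dbar))) if d_ok.size else 0.0
    grid = np.linspace(0.0, max_dep + 1e-9, n_grid)
    for delta in grid:
        res = sam_call(d, dbar, null_sorted, float(delta))
        if res.table["called"].sum() >= 1 and res.fdr_estimate <= target_fdr:
            return float(delta)
    warnings.warn(
        "no delta achieves the target FDR with at least one gene called; "
        "returning the empty-call delta"
    )
    return float(max_dep + 1e-6)


class SAM(BaseEstimator):
    """Significance analysis of microarrays as a fit-shaped estimator.

    Parameters
    ----------
    target_fdr:
        Target proportion of false discoveries used to choose Δ.
    n_permutations:
        Balanced label permutations for the null (all distinct
        assignments are enumerated when fewer exist).
    s0:
        Fudge factor; ``None`` selects it automatically from the data.
    delta:
        Fixed calling threshold; ``None`` selects the smallest Δ meeting
        ``target_fdr``.
    random_state:
        Seed for the permutation draw.

    Attributes (after ``fit``)
    --------------------------
    d_ : ndarray — observed statistic per feature (NaN where unevaluable)
    dbar_ : ndarray — expected null order statistics (evaluable features)
    s0_, delta_, fdr_estimate_ : floats of the fitted run
    called_ : boolean mask over input features
    result_ : :class:`SamResult`
    """

    def __init__(
        self,
        target_fdr: float = 0.01,
        n_permutations: int = 100,
        s0: float | None = None,
        delta: float | None = None,
        random_state: int = 0,
    ):
        self.target_fdr = target_fdr
        self.n_permutations = n_permutations
        self.s0 = s0
        self.delta = delta
        self.random_state = random_state

    def fit(self, X, y):
        """Fit on samples × features ``X`` with two-level labels ``y``."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        feat_names = getattr(X, "columns", None)
        m = pd.DataFrame(
            X.T, index=[f"g{i}" for i in range(X.shape[1])]
        )
        mask1, mask2, levels = _group_masks(y)
        s0 = self.s0 if self.s0 is not None else choose_s0(m, y, levels=levels)
        d = sam_statistic(m, y, s0=s0, levels=levels)
        null_sorted, dbar = sam_permutation_null(
            m, y, n_perm=self.n_permutations, seed=self.random_state, s0=s0,
            levels=levels,
        )
        if self.delta is not None:
            delta = float(self.delta)
        else:
            delta = sam_select_delta(d, dbar, null_sorted, self.target_fdr)
        res = sam_call(
            d, dbar, null_sorted, delta, s0=s0,
            n_permutations=null_sorted.shape[0], seed=self.random_state,
        )
        self.d_ = d.to_numpy()
        self.dbar_ = dbar
        self.s0_ = s0
        self.delta_ = delta
        self.fdr_estimate_ = res.fdr_estimate
        called = np.zeros(X.shape[1], dtype=bool)
        idx = {g: i for i, g in enumerate(m.index)}
        for g in res.called_genes:
            called[idx[g]] = True
        self.called_ = called
        self.result_ = res
        self.classes_ = np.asarray(levels)
        return self

    def get_support(self):
        check_is_fitted(self, "called_")
        return self.called_
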