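"""Signature derivation by dual intersection, and TPIS impact ranking.

The SMZL-specific signature is the set of genes uniquely differentially
expressed in SMZL against *both* comparison groups:

1. per-gene pooled t-tests, SMZL vs control spleen (CSP) and SMZL vs
   other tissue B-cell lymphomas (TBCL);
2. keep genes with p < alpha_strict (default 1e−7) in each comparison;
3. intersect the two lists;
4. run SAM (target FDR, permutation null) on the intersected genes for
   each comparison separately;
5. intersect the two SAM-called sets — this is the signature.

Each signature gene then receives a **total percent impact score
(TPIS)**: within each comparison, genes are ranked against the maximal
SAM score of their own direction (up- or down-regulated), the impact
being |d| / |d_max| ∈ [0, 1] so that the top-scoring probe of each
direction gets exactly 1.0; the TPIS is the sum of the two per-
comparison impacts, in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import diffexp

__all__ = [
    "Signature",
    "intersect_gene_lists",
    "tpis_impact",
    "tpis_total",
    "derive_signature",
    "SignatureDeriver",
]


def intersect_gene_lists(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Genes present in both lists, order of ``a`` preserved."""
    bset = set(b)
    return [g for g in a if g in bset]


def tpis_impact(d: float, d_max: float) -> float:
    """Score-proportional percent rank of a SAM score within its direction.

    ``impact = |d| / |d_max|`` where ``d_max`` is the maximal SAM score
    of the same comparison and direction (absolute values for
    down-regulated genes); the top probe gets exactly 1.0.
    """
    if d_max == 0:
        raise ValueError("d_max must be non-zero")
    if (d < 0) != (d_max < 0) and d != 0:
        raise ValueError("d and d_max must share sign convention")
    return abs(d) / abs(d_max)


def tpis_total(impact_a: float, impact_b: float) -> float:
    """Sum of the two per-comparison impacts, in [0, 2]."""
    for v in (impact_a, impact_b):
        if not (0 <= v <= 1):
            raise ValueError("impacts must lie in [0, 1]")
    return impact_a + impact_b


@dataclass
class Signature:
    """Ordered gene set with per-gene direction and TPIS.

    ``entries`` columns: gene_id, direction, impact_csp, impact_tbcl,
    tpis — sorted by tpis descending, ties broken by gene id.
    ``provenance`` records stage counts and thresholds of the
    derivation run.
    """

    entries: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.entries["gene_id"])

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Signature":
        return cls(entries=pd.read_csv(path, sep="\t"))


def _direction_impacts(res: diffexp.SamResult) -> pd.Series:
    """Per-gene impact within the SAM-called set, split by direction."""
    tab = res.table[res.table["called"]]
    d = tab["d"]
    impacts = pd.Series(np.nan, index=tab.index, dtype=float)
    up = d[d > 0]
    if len(up):
        impacts[up.index] = up / up.max()
    down = d[d < 0]
    if len(down):
        impacts[down.index] = down.abs() / down.abs().max()
    impacts[d[d == 0].index] = 0.0
    return impacts


class SignatureDeriver(BaseEstimator):
    """Fit-shaped wrapper around the dual-intersection derivation.

    ``fit(X, y)`` takes samples × genes ``X`` (DataFrame with gene ids
    as columns, or array) and per-sample group labels ``y`` containing
    the target class plus two comparison groups.

    Parameters
    ----------
    target : str — the class whose unique signature is sought.
    reference_a, reference_b : str — the two comparison groups.
    alpha_strict : float — p-value cutoff of the univariate stage.
    target_fdr, n_permutations : SAM parameters.
    random_state : int — permutation seed (split per comparison).

    Attributes
    ----------
    signature_ : :class:`Signature`
    provenance_ : dict of stage counts and thresholds
    """

    def __init__(
        self,
        target: str = "SMZL",
        reference_a: str = "CSP",
        reference_b: str = "TBCL",
        alpha_strict: float = 1e-7,
        target_fdr: float = 0.01,
        n_permutations: int = 100,
        random_state: int = 0,
    ):
        self.target = target
        self.reference_a = reference_a
        self.reference_b = reference_b
        self.alpha_strict = alpha_strict
        self.target_fdr = target_fdr
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            m = X.T
        else:
            X = np.asarray(X, dtype=float)
            m = pd.DataFrame(X.T, index=[f"g{i}" for i in range(X.shape[1])])
        y = np.asarray(y)
        for grp in (self.target, self.reference_a, self.reference_b):
            if (y == grp).sum() == 0:
                raise ValueError(f"group {grp!r} has no samples")

        prov: dict = {
            "n_genes": m.shape[0],
            "n_samples": m.shape[1],
            "alpha_strict": self.alpha_strict,
            "target_fdr": self.target_fdr,
            "n_permutations": self.n_permutations,
            "seed": self.random_state,
        }
        seeds = np.random.SeedSequence(self.random_state).generate_state(2) % (2**31)

        comparisons = {}
        sig_lists = {}
        for key, ref in (("csp", self.reference_a), ("tbcl", self.reference_b)):
            sel = (y == self.target) | (y == ref)
            sub = m.loc[:, sel]
            labels = y[sel]
            res = diffexp.ttest_per_gene(sub, labels, levels=[self.target, ref])
            sig = diffexp.select_significant(res, self.alpha_strict)
            comparisons[key] = (sub, labels, ref)
            sig_lists[key] = sig
            prov[f"n_significant_{key}"] = len(sig)

        inter = intersect_gene_lists(sig_lists["csp"], sig_lists["tbcl"])
        prov["n_intersection"] = len(inter)
        if len(inter) == 0:
            prov["empty_stage"] = "univariate intersection"
            self._finish_empty(prov)
            return self

        sam_results = {}
        called = {}
        for i, key in enumerate(("csp", "tbcl")):
            sub, labels, ref = comparisons[key]
            subm = sub.loc[inter]
            s0 = diffexp.choose_s0(subm, labels, levels=[self.target, ref]) if len(
                inter
            ) >= 10 else 0.0
            d = diffexp.sam_statistic(subm, labels, s0=s0, levels=[self.target, ref])
            null_sorted, dbar = diffexp.sam_permutation_null(
                subm, labels, n_perm=self.n_permutations, seed=int(seeds[i]), s0=s0,
                levels=[self.target, ref],
            )
            delta = diffexp.sam_select_delta(d, dbar, null_sorted, self.target_fdr)
            res = diffexp.sam_call(
                d, dbar, null_sorted, delta, s0=s0,
                n_permutations=null_sorted.shape[0], seed=int(seeds[i]),
            )
            sam_results[key] = res
            called[key] = res.called_genes
            prov[f"n_sam_called_{key}"] = len(res.called_genes)
            prov[f"sam_s0_{key}"] = float(s0)
            prov[f"sam_delta_{key}"] = float(res.delta)
            prov[f"sam_fdr_{key}"] = float(res.fdr_estimate)

        final = intersect_gene_lists(called["csp"], called["tbcl"])
        prov["n_signature"] = len(final)
        if len(final) == 0:
            prov["empty_stage"] = "SAM intersection"
            self._finish_empty(prov)
            return self

        # subset chain: signature ⊆ SAM-called ⊆ p<alpha_strict, per comparison
        for key in ("csp", "tbcl"):
            assert set(final) <= set(called[key]) <= set(sig_lists[key])

        imp_csp = _direction_impacts(sam_results["csp"])
        imp_tbcl = _direction_impacts(sam_results["tbcl"])
        d_csp = sam_results["csp"].table["d"]
        entries = pd.DataFrame(
            {
                "gene_id": final,
                "direction": ["up" if d_csp[g] >= 0 else "down" for g in final],
                "impact_csp": [float(imp_csp[g]) for g in final],
                "impact_tbcl": [float(imp_tbcl[g]) for g in final],
            }
        )
        entries["tpis"] = [
            tpis_total(a, b) for a, b in zip(entries["impact_csp"], entries["impact_tbcl"])
        ]
        entries = entries.sort_values(
            ["tpis", "gene_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        self.signature_ = Signature(entries=entries, provenance=prov)
        self.provenance_ = prov
        return self

    def _finish_empty(self, prov: dict) -> None:
        entries = pd.DataFrame(
            columns=["gene_id", "direction", "impact_csp", "impact_tbcl", "tpis"]
        )
        self.signature_ = Signature(entries=entries, provenance=prov)
        self.provenance_ = prov


def derive_signature(
    m: pd.DataFrame,
    annotations: pd.DataFrame,
    alpha_strict: float = 1e-7,
    target_fdr: float = 0.01,
    n_permutations: int = 100,
    seed: int = 0,
) -> Signature:
    """Derive the target-unique signature from a genes × samples matrix.

    ``annotations`` must carry ``sample_id`` and ``group`` columns
    covering the matrix samples, with all three groups represented.
    """
    groups = annotations.set_index("sample_id")["group"]
    missing = [s for s in m.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    y = groups.loc[m.columns].to_numpy()
    deriver = SignatureDeriver(
        alpha_strict=alpha_strict,
        target_fdr=target_fdr,
        n_permutations=n_permutations,
        random_state=seed,
    )
    deriver.fit(m.T, y)
    return deriver.signature_
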