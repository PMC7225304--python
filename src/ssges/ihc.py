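"""Immunohistochemistry staining-intensity scoring and prognostication.

Slides are scored 1 (no staining) to 5 (diffuse, complete tissue
staining) by up to three raters over five images per sample.  Rater
scores are averaged per image into a staining intensity score (SIS);
the per-image SIS are averaged per sample into an overall staining
intensity score (OSIS).  Group comparisons use the pooled two-sample
t-test; prognostic association with clinical stage uses Pearson
correlation (Spearman available, stage being ordinal).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import diffexp

__all__ = [
    "compute_sis",
    "compute_osis",
    "compare_groups",
    "correlate_stage",
    "osis_table",
    "compare_markers",
    "stage_correlations",
]


def compute_sis(scores: Sequence[float]) -> float:
    """Staining intensity score: mean of the available rater scores."""
    scores = [s for s in scores if s is not None and not np.isnan(s)]
    if len(scores) == 0:
        raise ValueError("SIS requires at least one rater score")
    return float(np.mean(scores))


def compute_osis(sis_values: Sequence[float]) -> float:
    """Overall staining intensity score: mean of the per-image SIS."""
    vals = [s for s in sis_values if s is not None and not np.isnan(s)]
    if len(vals) == 0:
        raise ValueError("OSIS requires at least one SIS")
    if len(vals) < 5:
        warnings.warn(f"OSIS computed from {len(vals)} images (expected 5)")
    return float(np.mean(vals))


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pooled two-sample t-test between two OSIS groups → (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    m = pd.DataFrame([np.concatenate([a, b])], index=["osis"])
    labels = ["a"] * len(a) + ["b"] * len(b)
    res = diffexp.ttest_per_gene(m, labels, levels=["a", "b"])
    row = res.table.iloc[0]
    if not row["evaluable"]:
        warnings.warn("degenerate variance in group comparison")
        return float("nan"), float("nan")
    return float(row["t"]), float(row["p"])


def correlate_stage(
    osis: Sequence[float], stage: Sequence[float], method: str = "pearson"
) -> float:
    """Correlation between per-sample OSIS and clinical stage."""
    osis = np.asarray(osis, dtype=float)
    stage = np.asarray(stage, dtype=float)
    if len(osis) != len(stage) or len(osis) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(osis) == 0 or np.std(stage) == 0:
        raise ValueError("zero variance makes the correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(osis, stage).statistic)
    if method == "spearman":
        return float(stats.spearmanr(osis, stage).statistic)
    raise ValueError(f"unknown method {method!r}")


def osis_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long-format score table to per-sample-marker OSIS.

    Expected columns: sample_id, group, marker, image_index, rater_id,
    score (1–5); any clinical columns (stage, symptomatic) are carried
    through.  Returns one row per (sample_id, marker) with the OSIS and
    an ``n_images`` count.
    """
    bad = scores[(scores["score"] < 1) | (scores["score"] > 5)]
    if len(bad):
        raise ValueError("scores must lie in [1, 5]")
    sis = (
        scores.groupby(["sample_id", "group", "marker", "image_index"], sort=False)[
            "score"
        ]
        .mean()
        .rename("sis")
        .reset_index()
    )
    osis = (
        sis.groupby(["sample_id", "group", "marker"], sort=False)["sis"]
        .agg(osis="mean", n_images="count")
        .reset_index()
    )
    clinical_cols = [
        c for c in ("stage", "symptomatic") if c in scores.columns
    ]
    if clinical_cols:
        clin = scores.drop_duplicates("sample_id")[["sample_id", *clinical_cols]]
        osis = osis.merge(clin, on="sample_id", how="left")
    return osis


def compare_markers(
    osis: pd.DataFrame,
    group_a: str,
    group_b: str,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-marker pooled t-test between two groups of OSIS values.

    ``adjust=True`` appends Benjamini–Hochberg adjusted p-values across
    the markers (off by default, matching single-marker reporting).
    """
    rows = []
    for marker, sub in osis.groupby("marker", sort=False):
        a = sub.loc[sub["group"] == group_a, "osis"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "osis"].to_numpy()
        t, p = compare_groups(a, b)
        rows.append(
            {"marker": marker, "group_a": group_a, "group_b": group_b, "t": t, "p": p}
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        ok = out["p"].notna()
        out["p_adj"] = np.nan
        if ok.any():
            out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def stage_correlations(
    osis: pd.DataFrame, group: str = "SMZL", method: str = "pearson"
) -> pd.DataFrame:
    """Per-marker correlation of OSIS with clinical stage within a group."""
    if "stage" not in osis.columns:
        raise ValueError("osis table has no 'stage' column")
    rows = []
    for marker, sub in osis.groupby("marker", sort=False):
        sel = sub[(sub["group"] == group) & sub["stage"].notna()]
        r = correlate_stage(sel["osis"], sel["stage"].astype(float), method=method)
        rows.append({"marker": marker, "group": group, "r": r, "n": len(sel)})
    return pd.DataFrame(rows)
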