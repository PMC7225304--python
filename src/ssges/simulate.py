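"""Synthetic cohorts with planted signatures, and synthetic IHC tables.

The expression generator emulates the statistical structure of a merged
multi-dataset microarray cohort on the log2 scale:

* per-gene baseline means drawn once (log-normal-style intensities);
* three classes — control spleen (CSP), the target malignancy (SMZL)
  and other B-cell lymphomas (TBCL);
* a planted *signature*: genes shifted in exactly the SMZL class, by
  ``effect_size`` within-gene standard deviations, with random sign so
  both up- and down-regulated members occur;
* *pan-lymphoma* nuisance genes shifted identically in SMZL and TBCL
  (differential versus controls, but not SMZL-unique);
* additive per-dataset batch offsets, with dataset membership balanced
  across classes;
* missing values masked completely at random.

The IHC generator produces the long-format 3-raters × 5-images score
table, with group shifts per marker and a stage-correlated intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import TBCL_SUBTYPES

__all__ = ["SyntheticConfig", "generate_cohort", "generate_ihc_table"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic expression cohort.

    Defaults emulate the merged-cohort analysis setting: tens of samples
    per class across a few source datasets, thousands of genes, a
    135-gene planted signature at a 2-SD shift and 200 pan-lymphoma
    nuisance genes.
    """

    n_per_class: tuple[int, int, int] = (40, 40, 40)  # CSP, SMZL, TBCL
    n_genes: int = 5000
    n_signature: int = 135
    n_pan_lymphoma: int = 200
    effect_size: float = 2.0  # mean shift in within-gene SD units
    noise_sd: float = 0.5  # residual SD, log2 units
    n_datasets: int = 4
    batch_sd: float = 0.3
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature + self.n_pan_lymphoma > self.n_genes:
            raise ValueError("planted gene sets exceed n_genes")
        for r in (self.missing_rate,):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if min(self.n_per_class) < 2:
            raise ValueError("each class needs at least 2 samples")
        if self.noise_sd <= 0 or self.batch_sd < 0:
            raise ValueError("noise_sd must be positive, batch_sd non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a cohort → (matrix genes × samples, annotations, truth).

    ``truth`` lists the planted signature genes (with their shift
    signs) and the pan-lymphoma genes.
    """
    rng = np.random.default_rng(cfg.seed)
    n_csp, n_smzl, n_tbcl = cfg.n_per_class
    n = n_csp + n_smzl + n_tbcl
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    samples = (
        [f"CSP_{i:03d}" for i in range(n_csp)]
        + [f"SMZL_{i:03d}" for i in range(n_smzl)]
        + [f"TBCL_{i:03d}" for i in range(n_tbcl)]
    )
    group = np.array(["CSP"] * n_csp + ["SMZL"] * n_smzl + ["TBCL"] * n_tbcl)

    baseline = rng.normal(8.0, 2.0, size=cfg.n_genes)  # log2 intensities
    sig_idx = np.arange(cfg.n_signature)
    pan_idx = np.arange(cfg.n_signature, cfg.n_signature + cfg.n_pan_lymphoma)
    sig_sign = rng.choice([-1.0, 1.0], size=cfg.n_signature)
    pan_sign = rng.choice([-1.0, 1.0], size=cfg.n_pan_lymphoma)
    shift = cfg.effect_size * cfg.noise_sd

    effect = np.zeros((cfg.n_genes, n))
    is_smzl = group == "SMZL"
    is_malignant = group != "CSP"
    effect[np.ix_(sig_idx, np.where(is_smzl)[0])] = (sig_sign * shift)[:, None]
    effect[np.ix_(pan_idx, np.where(is_malignant)[0])] = (pan_sign * shift)[:, None]

    # balanced dataset membership: round-robin within each class so batch
    # is orthogonal to class
    dataset = np.empty(n, dtype=object)
    for g in ("CSP", "SMZL", "TBCL"):
        idx = np.where(group == g)[0]
        for k, i in enumerate(idx):
            dataset[i] = f"D{k % cfg.n_datasets}"
    batch_offsets = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes, cfg.n_datasets))
    ds_index = np.array([int(d[1:]) for d in dataset])

    X = (
        baseline[:, None]
        + effect
        + batch_offsets[:, ds_index]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    )
    if cfg.missing_rate > 0:
        mask = rng.random(size=X.shape) < cfg.missing_rate
        X = np.where(mask, np.nan, X)

    m = pd.DataFrame(X, index=pd.Index(genes, name="ID"), columns=samples)
    subtype_cycle = list(TBCL_SUBTYPES)
    class_labels = []
    t = 0
    for g in group:
        if g == "TBCL":
            class_labels.append(subtype_cycle[t % len(subtype_cycle)])
            t += 1
        else:
            class_labels.append(g)
    ann = pd.DataFrame(
        {
            "sample_id": samples,
            "class_label": class_labels,
            "tissue": np.where(group == "CSP", "spleen", "secondary lymphoid"),
            "dataset_id": dataset,
            "group": group,
        }
    )
    truth = {
        "signature_genes": [genes[i] for i in sig_idx],
        "signature_signs": {genes[i]: int(s) for i, s in zip(sig_idx, sig_sign)},
        "pan_lymphoma_genes": [genes[i] for i in pan_idx],
        "effect_size": cfg.effect_size,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
    }
    return m, ann, truth


def generate_ihc_table(
    n_per_group: Mapping[str, int] | None = None,
    marker_effects: Mapping[str, Mapping[str, float]] | None = None,
    stage_slope: float = 0.0,
    rater_sd: float = 0.5,
    seed: int = 0,
    n_raters: int = 3,
    n_images: int = 5,
    base_intensity: float = 2.0,
) -> pd.DataFrame:
    """Simulate a long-format IHC score table.

    Per sample-marker true intensity = ``base_intensity`` + group shift
    (from ``marker_effects[marker][group]``) + ``stage_slope`` × stage;
    each rater-image score adds Gaussian(``rater_sd``) noise and is
    clipped to [1, 5].  Stages are drawn uniformly from 1–4; the stage
    slope applies within malignant groups only (controls carry no
    stage).
    """
    rng = np.random.default_rng(seed)
    n_per_group = dict(n_per_group or {"CSP": 6, "SMZL": 6, "TBCL": 5})
    marker_effects = {
        mk: dict(eff) for mk, eff in (marker_effects or {"M1": {"SMZL": 1.0}}).items()
    }
    rows = []
    for grp, n in n_per_group.items():
        for s in range(n):
            sid = f"{grp}_{s:02d}"
            malignant = grp != "CSP"
            stage = int(rng.integers(1, 5)) if malignant else np.nan
            symptomatic = bool(rng.random() < 0.5) if malignant else False
            for mk, eff in marker_effects.items():
                truth = base_intensity + eff.get(grp, 0.0)
                if malignant:
                    truth += stage_slope * stage
                if truth < 1 or truth > 5:
                    warnings.warn(
                        f"true intensity {truth:.2f} out of [1,5] for {sid}/{mk}; clipped"
                    )
                    truth = float(np.clip(truth, 1.0, 5.0))
                for img in range(1, n_images + 1):
                    for r in range(1, n_raters + 1):
                        score = float(
                            np.clip(truth + rng.normal(0.0, rater_sd), 1.0, 5.0)
                        )
                        rows.append(
                            {
                                "sample_id": sid,
                                "group": grp,
                                "marker": mk,
                                "image_index": img,
                                "rater_id": f"R{r}",
                                "score": score,
                                "stage": stage,
                                "symptomatic": symptomatic,
                            }
                        )
    return pd.DataFrame(rows)
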