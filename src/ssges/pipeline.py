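"""End-to-end orchestration of the signature workflow.

``run_derivation`` executes, from a config, the full stage order:
merge → normalize → variation filter → (optional probe collapsing) →
unsupervised clustering (reported only) → signature derivation →
multi-method LOOCV prediction of the target class against each
comparison group — writing the signature, prediction reports,
provenance and a log to the output directory.

``run_replication`` re-evaluates an existing signature on a new cohort
(no re-derivation), mirroring a replication-cohort analysis.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from . import predict as epredict
from . import preprocess, signature as esig
from .simulate import SyntheticConfig, generate_cohort

logger = logging.getLogger("ssges")

__all__ = ["RunConfig", "run_derivation", "run_replication"]


@dataclass
class RunConfig:
    """Run thresholds and inputs for a derivation run.

    Either ``matrix_path``/``annotation_path`` or ``synthetic`` must be
    supplied.  ``input_scale`` declares whether intensities arrive
    linear (then log2-transformed) or already log2.
    """

    matrix_path: str | None = None
    annotation_path: str | None = None
    synthetic: SyntheticConfig | None = None
    input_scale: str = "log2"  # or "linear"
    alpha_initial: float = 0.001
    alpha_strict: float = 1e-7
    target_fdr: float = 0.01
    n_permutations: int = 100
    predict_alpha: float = 0.01
    quantile_normalize: bool = True
    variation_filter: bool = True
    cluster: bool = True
    seed: int = 0
    out_dir: str = "ssges_run"

    def validate(self) -> "RunConfig":
        for name in ("alpha_initial", "alpha_strict", "target_fdr", "predict_alpha"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha_strict > self.alpha_initial:
            raise ValueError("alpha_strict must not exceed alpha_initial")
        if self.input_scale not in ("linear", "log2"):
            raise ValueError("input_scale must be 'linear' or 'log2'")
        if self.matrix_path is None and self.synthetic is None:
            raise ValueError("either matrix_path or synthetic config is required")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg.validate()


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Expand one global seed into independent per-stage seeds (< 2^31)."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        m, ann, truth = generate_cohort(cfg.synthetic)
        return m, ann, truth
    m = eio.read_expression_matrix(cfg.matrix_path)
    ann = eio.read_sample_annotations(cfg.annotation_path)
    return m, ann, None


def run_derivation(cfg: RunConfig) -> tuple[esig.Signature, dict]:
    """Execute the full derivation workflow; returns (signature, reports).

    ``reports`` maps comparison name → :class:`PredictionReport`, plus
    bookkeeping entries (counts per stage, dendrogram, planted truth for
    synthetic runs).  Artifacts are written under ``cfg.out_dir``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = _stage_seeds(cfg.seed, 4)
    stage = "load"
    try:
        m, ann, truth = _load_inputs(cfg)
        counts = {"input_genes": m.shape[0], "input_samples": m.shape[1]}
        logger.info("loaded %d genes x %d samples", *m.shape)

        if cfg.input_scale == "linear":
            stage = "log2"
            m = preprocess.log2_transform(m)
        if cfg.quantile_normalize:
            stage = "quantile_normalize"
            m = preprocess.quantile_normalize(m)
        if cfg.variation_filter:
            stage = "variation_filter"
            m = preprocess.variation_filter(m)
            counts["filtered_genes"] = m.shape[0]
            logger.info("variation filter kept %d genes", m.shape[0])

        dendro = None
        if cfg.cluster:
            stage = "cluster"
            clusterable = m.dropna(axis=0, how="any")
            spread = clusterable.std(axis=1) > 0
            scaled = preprocess.center_scale_genes(clusterable.loc[spread])
            dendro = preprocess.cluster_samples(scaled)
            (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")

        stage = "derive_signature"
        sig = esig.derive_signature(
            m,
            ann,
            alpha_strict=cfg.alpha_strict,
            target_fdr=cfg.target_fdr,
            n_permutations=cfg.n_permutations,
            seed=seeds[0],
        )
        counts.update(sig.provenance)
        sig.to_tsv(out / "signature.tsv")
        logger.info("signature: %d genes", len(sig))

        stage = "predict"
        reports: dict = {"counts": counts, "dendrogram": dendro, "truth": truth}
        groups = ann.set_index("sample_id")["group"].loc[m.columns]
        if len(sig) > 0:
            for ref, seed in (("CSP", seeds[1]), ("TBCL", seeds[2])):
                sel = groups.isin(["SMZL", ref]).to_numpy()
                rep = epredict.loocv_predict(
                    m.loc[:, m.columns[sel]],
                    groups[sel].to_numpy(),
                    sig.genes,
                    alpha=cfg.predict_alpha,
                    seed=seed,
                )
                reports[f"SMZL_vs_{ref}"] = rep
                rep.to_tsv(out / f"prediction_SMZL_vs_{ref}.tsv")
                rep.calls.to_csv(out / f"calls_SMZL_vs_{ref}.tsv", sep="\t")
                logger.info("LOOCV SMZL vs %s: mean rate %.3f", ref, rep.mean_rate)

        provenance = {
            "config": {
                k: v
                for k, v in dataclasses.asdict(cfg).items()
                if not isinstance(v, dict) or v
            },
            "counts": {k: v for k, v in counts.items() if not isinstance(v, pd.DataFrame)},
        }
        (out / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=False))
        return sig, reports
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("run failed at stage %s", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_replication(
    cfg: RunConfig,
    sig: esig.Signature,
    m: pd.DataFrame,
    ann: pd.DataFrame,
    min_coverage: float = 0.8,
) -> dict:
    """Evaluate an existing signature on a replication cohort.

    The signature is not re-derived; its genes must cover at least
    ``min_coverage`` of the list in the new matrix.  Returns prediction
    reports for SMZL vs CSP and SMZL vs TBCL.
    """
    cfg.validate()
    genes = sig.genes
    present = [g for g in genes if g in m.index]
    if len(genes) == 0:
        raise ValueError("signature is empty")
    if len(present) / len(genes) < min_coverage:
        missing = sorted(set(genes) - set(present))
        raise ValueError(
            f"signature coverage {len(present)}/{len(genes)} below "
            f"{min_coverage:.0%}; missing genes: {missing[:10]}"
        )
    seeds = _stage_seeds(cfg.seed, 4)
    groups = ann.set_index("sample_id")["group"].loc[m.columns]
    reports = {}
    for ref, seed in (("CSP", seeds[1]), ("TBCL", seeds[2])):
        sel = groups.isin(["SMZL", ref]).to_numpy()
        reports[f"SMZL_vs_{ref}"] = epredict.loocv_predict(
            m.loc[:, m.columns[sel]],
            groups[sel].to_numpy(),
            present,
            alpha=cfg.predict_alpha,
            seed=seed,
        )
    return reports
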