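"""End-to-end reproducibility harness.

Wires the stages together: simulate a paired cohort, train contrastive
alignment, build the frozen embedding library, retrieve proxy pathology
embeddings for imaging-only patients, train the survival classifier in
three input modes (imaging-only, imaging + trained proxy, imaging + proxy
from a randomly initialized control model), and evaluate retrieval and
classification, including the top-k proxy-fusion ablation.

Every run is fully determined by (config, master seed); the resolved
configuration is written beside the outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .alignment import (AlignmentResult, TrainConfig, make_random_model,
                        save_checkpoint, train_alignment)
from .containers import PairedSample
from .encoders import AggregatorConfig
from .retrieval import EmbeddingLibrary, build_library, retrieve_proxy, save_library
from .survival import SurvivalTrainConfig, fuse_features, predict_os, train_os_classifier
from .synthetic import SyntheticConfig, generate_cohort, save_cohort

__all__ = ["RunConfig", "run_pipeline", "proxy_features", "load_run_config"]


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    aggregator: AggregatorConfig = field(default_factory=AggregatorConfig)
    align: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=30, tau=0.07))
    survival: SurvivalTrainConfig = field(default_factory=lambda: SurvivalTrainConfig(epochs=50))
    align_train: int = 98
    align_val: int = 38
    os_patients: int = 600
    os_train_fraction: float = 0.7
    retrieval_k: int = 1
    retrieval_mode: str = "cross"
    ablation_ks: tuple[int, ...] = (1, 3, 5, 10)
    eval_ks: tuple[int, ...] = (1, 5)
    seed: int = 0

    def __post_init__(self):
        n_needed = self.align_train + self.align_val + self.os_patients
        self.synthetic = dataclasses.replace(
            self.synthetic, n_patients=n_needed, seed=self.seed)
        self.align = dataclasses.replace(self.align, seed=self.seed)
        self.survival = dataclasses.replace(self.survival, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["survival_weights"] = self.synthetic.survival_weights.tolist()
        return d


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (JSON is a YAML subset and also accepted)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "synthetic" in kwargs:
        kwargs["synthetic"] = SyntheticConfig(**_tuplify(kwargs["synthetic"],
                                                         ("patch_count_range", "volume_shape")))
    if "aggregator" in kwargs:
        kwargs["aggregator"] = AggregatorConfig(**kwargs["aggregator"])
    if "align" in kwargs:
        kwargs["align"] = TrainConfig(**_tuplify(kwargs["align"], ("tau_grid",)))
    if "survival" in kwargs:
        kwargs["survival"] = SurvivalTrainConfig(**kwargs["survival"])
    for key in ("ablation_ks", "eval_ks"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def _tuplify(d: dict, keys: tuple[str, ...]) -> dict:
    d = dict(d)
    for key in keys:
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return d


def proxy_features(samples: list[PairedSample], model, library: EmbeddingLibrary,
                   k: int, mode: str = "cross") -> tuple[np.ndarray, list]:
    """Fused imaging+proxy feature matrix for imaging-only patients."""
    imaging = np.stack([s.imaging for s in samples])
    queries = model.embed_imaging(imaging)
    fused, results = [], []
    for s, q in zip(samples, queries):
        r = retrieve_proxy(q, library, k=k, mode=mode)
        fused.append(fuse_features(s.imaging, r.proxy).values)
        results.append(r)
    return np.stack(fused), results


def _classify(x_train, y_train, x_val, y_val, config: SurvivalTrainConfig) -> dict:
    clf, history = train_os_classifier(x_train, y_train, config, x_val, y_val)
    metrics = evaluation.classification_metrics(y_val, predict_os(clf, x_val))
    metrics["epochs_run"] = len(history)
    return metrics


def run_pipeline(config: RunConfig | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run the full harness; returns a nested dict of metrics.

    Stages are logged by name so a failure is attributable; when outdir is
    given, checkpoints, the library, per-mode metrics, the top-k ablation
    table and the resolved config are written there.
    """
    config = config or RunConfig()
    log: list[str] = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)

    stage = "simulate"
    try:
        cohort = generate_cohort(config.synthetic)
        n_align = config.align_train + config.align_val
        align_train = cohort.samples[:config.align_train]
        align_val = cohort.samples[config.align_train:n_align]
        os_samples = cohort.samples[n_align:]
        n_os_train = int(round(config.os_train_fraction * len(os_samples)))
        os_train, os_val = os_samples[:n_os_train], os_samples[n_os_train:]
        log.append(f"simulate: n={len(cohort)} (align {config.align_train}+"
                   f"{config.align_val}, survival {len(os_train)}+{len(os_val)}), "
                   f"seed={config.seed}")
        if out is not None:
            save_cohort(cohort, out / "cohort")

        stage = "train-align"
        result: AlignmentResult = train_alignment(
            align_train, align_val, config=config.align, agg_config=config.aggregator)
        model = result.model
        log.append(f"train-align: selected tau={result.tau}, "
                   f"val {config.align.val_metric}={result.val_score:.4f}")
        if out is not None:
            save_checkpoint(model, out / "alignment.npz")
            result.history.to_csv(out / "align_history.csv", index=False)

        stage = "eval-retrieval"
        e_img, e_path = model.embed_samples(align_val)
        ranks = evaluation.rank_matches(e_img @ e_path.T)
        retrieval_rep = evaluation.retrieval_report(ranks, config.eval_ks)
        random_rep = evaluation.random_retrieval_baseline(
            len(align_val), config.eval_ks, n_seeds=200,
            embed_dim=model.embed_dim, seed=config.seed)
        log.append(f"eval-retrieval: heldout recall@1={retrieval_rep['recall_at'][1]:.3f}, "
                   f"mrr={retrieval_rep['mrr']:.3f}")

        stage = "build-library"
        library = build_library(model, align_train + align_val)
        random_model = make_random_model(
            model.imaging_dim, config.aggregator, seed=config.seed + 1,
            embed_dim=model.embed_dim)
        random_library = build_library(random_model, align_train + align_val)
        log.append(f"build-library: K={library.K}")
        if out is not None:
            save_library(library, out / "library")

        stage = "retrieve"
        k = config.retrieval_k
        fused_tr_train, _ = proxy_features(os_train, model, library, k, config.retrieval_mode)
        fused_tr_val, results_val = proxy_features(os_val, model, library, k, config.retrieval_mode)
        fused_rnd_train, _ = proxy_features(os_train, random_model, random_library,
                                            k, config.retrieval_mode)
        fused_rnd_val, _ = proxy_features(os_val, random_model, random_library,
                                          k, config.retrieval_mode)
        if out is not None:
            pd.DataFrame({
                "query_id": [s.patient_id for s in os_val],
                "neighbor_ids": [";".join(r.neighbor_ids) for r in results_val],
                "similarities": [";".join(f"{v:.6f}" for v in r.similarities)
                                 for r in results_val],
            }).to_csv(out / "retrieval_val.csv", index=False)

        stage = "train-os"
        y_train = np.array([s.os_label for s in os_train])
        y_val = np.array([s.os_label for s in os_val])
        x_img_train = np.stack([s.imaging for s in os_train])
        x_img_val = np.stack([s.imaging for s in os_val])
        modes = {
            "imaging": _classify(x_img_train, y_train, x_img_val, y_val, config.survival),
            "trained_proxy": _classify(fused_tr_train, y_train, fused_tr_val, y_val,
                                       config.survival),
            "random_proxy": _classify(fused_rnd_train, y_train, fused_rnd_val, y_val,
                                      config.survival),
        }
        for name, m in modes.items():
            log.append(f"train-os[{name}]: auroc={m['auroc']:.3f}, acc={m['accuracy']:.3f}")

        stage = "ablation"
        ablation = {}
        for kk in config.ablation_ks:
            if kk == k:
                ablation[kk] = modes["trained_proxy"]["auroc"]
                continue
            ftr, _ = proxy_features(os_train, model, library, kk, config.retrieval_mode)
            fva, _ = proxy_features(os_val, model, library, kk, config.retrieval_mode)
            ablation[kk] = _classify(ftr, y_train, fva, y_val, config.survival)["auroc"]
        log.append("ablation: " + ", ".join(f"k={kk}: {v:.3f}" for kk, v in ablation.items()))
    except Exception as err:
        log.append(f"FAILED at stage {stage}: {err}")
        if out is not None:
            (out / "run.log").write_text("\n".join(log) + "\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    results = {
        "tau": result.tau,
        "retrieval": retrieval_rep,
        "retrieval_random_baseline": random_rep,
        "survival": modes,
        "ablation": ablation,
        "library_size": library.K,
        "seed": config.seed,
    }
    if out is not None:
        rows = [{"mode": name, **metrics} for name, metrics in modes.items()]
        pd.DataFrame(rows).to_csv(out / "survival_metrics.csv", index=False)
        pd.DataFrame([{"k": kk, "auroc": v} for kk, v in ablation.items()]).to_csv(
            out / "ablation.csv", index=False)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, default=float)
        (out / "run.log").write_text("\n".join(log) + "\n")
    return results
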