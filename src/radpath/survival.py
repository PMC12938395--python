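"""Fusion of imaging features with proxy pathology embeddings and the
binary 12-month overall-survival classifier.

The classifier is a small feed-forward network trained with cross-entropy
under the same Adam/cosine-annealing regime as alignment but batch size 20.
Input modes: imaging-only, imaging + trained proxy, and imaging + proxy
from a randomly initialized (untrained) alignment model as a control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Tensor, exp as t_exp, log as t_log, relu
from ._nn import Adam, Linear, Module, cosine_lr
from .containers import OS_CUTOFF_MONTHS
from . import evaluation

__all__ = ["FusedFeature", "OsPrediction", "SurvivalTrainConfig", "OsClassifier",
           "fuse_features", "make_os_label", "train_os_classifier", "predict_os"]


@dataclass
class FusedFeature:
    """Concatenated multimodal vector: imaging block first, proxy block second."""

    values: np.ndarray
    imaging_len: int
    proxy_len: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.imaging_len + self.proxy_len,):
            raise ValueError("fused length must equal imaging_len + proxy_len")

    def imaging_block(self) -> np.ndarray:
        return self.values[:self.imaging_len]

    def proxy_block(self) -> np.ndarray:
        return self.values[self.imaging_len:]


@dataclass
class OsPrediction:
    patient_id: str
    score: float     # probability of surviving beyond 12 months
    label: int       # score >= 0.5

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be a probability")


def fuse_features(imaging_feature: np.ndarray, proxy: np.ndarray) -> FusedFeature:
    """Channel-wise concatenation of the imaging feature and the proxy embedding."""
    imaging_feature = np.asarray(imaging_feature, dtype=np.float64).ravel()
    proxy = np.asarray(proxy, dtype=np.float64).ravel()
    if imaging_feature.size == 0 or proxy.size == 0:
        raise ValueError("cannot fuse an empty feature block")
    if not (np.isfinite(imaging_feature).all() and np.isfinite(proxy).all()):
        raise ValueError("fused inputs must be finite")
    return FusedFeature(np.concatenate([imaging_feature, proxy]),
                        imaging_len=imaging_feature.size, proxy_len=proxy.size)


def make_os_label(os_months: float) -> int:
    """1 iff overall survival strictly exceeds 12 months."""
    if not os_months > 0:
        raise ValueError("os_months must be positive")
    return int(os_months > OS_CUTOFF_MONTHS)


@dataclass
class SurvivalTrainConfig:
    lr_init: float = 3e-3
    lr_final: float = 1e-6
    epochs: int = 100
    weight_decay: float = 1e-5
    batch_size: int = 20
    hidden_dim: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class OsClassifier(Module):
    """One-hidden-layer network producing a single survival logit."""

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.in_dim = in_dim
        self.fc1 = self.add_module("fc1", Linear(in_dim, hidden_dim, rng))
        self.fc2 = self.add_module("fc2", Linear(hidden_dim, 1, rng))
        # feature standardization fitted on the training set
        self.mu = np.zeros(in_dim)
        self.sd = np.ones(in_dim)

    def logits(self, x: np.ndarray | Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor((np.atleast_2d(x) - self.mu) / self.sd)
        return self.fc2(relu(self.fc1(x))).reshape(-1)


def _bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """mean(softplus(logit) - y*logit); stabilized with a detached shift."""
    m = Tensor(np.maximum(logits.data, 0.0))
    softplus = m + t_log(t_exp(-m) + t_exp(logits - m))
    return (softplus - logits * Tensor(labels.astype(np.float64))).mean()


def train_os_classifier(features: np.ndarray, labels: np.ndarray,
                        config: SurvivalTrainConfig | None = None,
                        val_features: np.ndarray | None = None,
                        val_labels: np.ndarray | None = None
                        ) -> tuple[OsClassifier, pd.DataFrame]:
    """Train the survival head; with validation data, keep the best-AUROC epoch."""
    config = config or SurvivalTrainConfig()
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if features.ndim != 2 or features.shape[0] != labels.size:
        raise ValueError("features must be (n, p) with one label per row")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 41]))
    clf = OsClassifier(features.shape[1], config.hidden_dim, rng)
    clf.mu = features.mean(axis=0)
    clf.sd = np.maximum(features.std(axis=0), 1e-8)
    x_all = (features - clf.mu) / clf.sd
    opt = Adam(clf.parameters(), lr=config.lr_init, weight_decay=config.weight_decay)
    n = labels.size
    rows, best = [], None
    for epoch in range(config.epochs):
        opt.lr = cosine_lr(epoch, config.epochs, config.lr_init, config.lr_final)
        perm = rng.permutation(n)
        clf.train()
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            batch = perm[i:i + config.batch_size]
            logits = clf.logits(Tensor(x_all[batch]))
            loss = _bce_with_logits(logits, labels[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        row = {"epoch": epoch, "lr": opt.lr, "train_loss": epoch_loss / n}
        if val_features is not None and val_labels is not None:
            val_auroc = evaluation.classification_metrics(
                val_labels, predict_os(clf, val_features))["auroc"]
            row["val_auroc"] = val_auroc
            if best is None or val_auroc > best[0]:
                best = (val_auroc, clf.state_dict())
        rows.append(row)
    if best is not None:
        clf.load_state_dict(best[1])
    clf.eval()
    return clf, pd.DataFrame(rows)


def predict_os(classifier: OsClassifier, features: np.ndarray) -> np.ndarray:
    """Survival probabilities P(OS > 12 months) for one or more feature rows."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[1] != classifier.in_dim:
        raise ValueError(f"feature length {features.shape[1]} != classifier input "
                         f"{classifier.in_dim}")
    classifier.eval()
    logits = classifier.logits(features).data
    return 1.0 / (1.0 + np.exp(-logits))
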