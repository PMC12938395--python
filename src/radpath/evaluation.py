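"""Retrieval and classification metrics with analytic random baselines.

Ranks are pessimistic under ties: a true match tied with competitors is
ranked after all of them, so reported recall never benefits from ties.
AUROC uses the Mann-Whitney rank statistic (ties contribute 1/2), which is
exact and invariant to strictly monotone score transforms.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "rank_matches", "recall_at_k", "mean_reciprocal_rank", "retrieval_report",
    "classification_metrics", "expected_recall_at_k", "expected_mrr",
    "random_retrieval_baseline",
]


def rank_matches(similarity: np.ndarray) -> np.ndarray:
    """1-based rank of each diagonal entry within its row (descending).

    similarity[i, j] scores query i against candidate j; the true match is
    at (i, i). Ties are broken pessimistically: equal-similarity competitors
    are counted ahead of the true match.
    """
    S = np.asarray(similarity, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity data must be square")
    diag = np.diag(S)
    return (S >= diag[:, None]).sum(axis=1)


def recall_at_k(ranks: np.ndarray, k: int) -> float:
    """Fraction of queries whose true match ranks within the top k."""
    ranks = np.asarray(ranks)
    n = ranks.size
    if n == 0:
        raise ValueError("empty rank table")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    return float(np.mean(ranks <= k))


def mean_reciprocal_rank(ranks: np.ndarray) -> float:
    ranks = np.asarray(ranks, dtype=np.float64)
    if ranks.size == 0:
        raise ValueError("empty rank table")
    return float(np.mean(1.0 / ranks))


def retrieval_report(ranks: np.ndarray, ks: tuple[int, ...] = (1, 5)) -> dict:
    """Recall@k for each requested k plus MRR and the candidate count."""
    ranks = np.asarray(ranks)
    return {
        "recall_at": {int(k): recall_at_k(ranks, k) for k in ks},
        "mrr": mean_reciprocal_rank(ranks),
        "N": int(ranks.size),
    }


def classification_metrics(labels: np.ndarray, scores: np.ndarray,
                           threshold: float = 0.5) -> dict:
    """Accuracy, AUROC, sensitivity, specificity and F1.

    Predicted positive means score >= threshold. AUROC requires both
    classes; with a single class it is reported as nan while the
    threshold-based metrics are still computed.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos and n_neg:
        r = rankdata(scores)  # average ranks handle ties as 1/2
        auroc = (r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    else:
        auroc = float("nan")
    return {
        "accuracy": (tp + tn) / labels.size,
        "auroc": float(auroc),
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan"),
    }


# -- analytic and Monte-Carlo random baselines --------------------------------

def expected_recall_at_k(n: int, k: int) -> float:
    """Recall@k of a uniformly random ranking: k/N."""
    return k / n


def expected_mrr(n: int) -> float:
    """MRR of a uniformly random ranking: H_N / N (harmonic number)."""
    return float(np.sum(1.0 / np.arange(1, n + 1)) / n)


def random_retrieval_baseline(n: int, ks: tuple[int, ...] = (1, 5),
                              n_seeds: int = 1000, embed_dim: int = 256,
                              seed: int = 0) -> dict:
    """Monte-Carlo retrieval metrics of random unit embeddings.

    Draws n_seeds independent cohorts of N random unit embeddings per
    modality, ranks true matches by cosine similarity and averages the
    metrics; converges to the analytic k/N and H_N/N levels.
    """
    rng = np.random.default_rng(seed)
    recalls = {k: 0.0 for k in ks}
    mrr = 0.0
    for _ in range(n_seeds):
        a = rng.standard_normal((n, embed_dim))
        b = rng.standard_normal((n, embed_dim))
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        ranks = rank_matches(a @ b.T)
        for k in ks:
            recalls[k] += recall_at_k(ranks, k)
        mrr += mean_reciprocal_rank(ranks)
    return {
        "recall_at": {k: recalls[k] / n_seeds for k in ks},
        "mrr": mrr / n_seeds,
        "N": n,
        "n_seeds": n_seeds,
    }
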