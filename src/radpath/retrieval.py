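"""Cross-modal embedding library and proxy pathology retrieval.

After alignment training the frozen model embeds every paired patient once;
the resulting (imaging, pathology) unit-embedding pairs form the library.
An imaging-only query is answered by the pathology embeddings of its most
cosine-similar library entries: with k=1 the single best match is returned
verbatim, with k>1 the top-k pathology embeddings are combined with
similarity weights and re-normalized to the unit sphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignmentModel
from .containers import PairedSample

__all__ = ["EmbeddingLibrary", "RetrievalResult", "build_library",
           "retrieve_proxy", "save_library", "load_library"]


@dataclass
class EmbeddingLibrary:
    """Ordered (patient_id, imaging embedding, pathology embedding) records."""

    patient_ids: list[str]
    img: np.ndarray   # K x d, unit rows
    path: np.ndarray  # K x d, unit rows

    def __post_init__(self):
        self.img = np.asarray(self.img, dtype=np.float64)
        self.path = np.asarray(self.path, dtype=np.float64)
        K = len(self.patient_ids)
        if self.img.shape[0] != K or self.path.shape[0] != K:
            raise ValueError("embedding row counts must match the id list")
        if len(set(self.patient_ids)) != K:
            raise ValueError("patient ids must be unique")
        for name, arr in (("imaging", self.img), ("pathology", self.path)):
            norms = np.linalg.norm(arr, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError(f"{name} embeddings must be unit norm")

    @property
    def K(self) -> int:
        return len(self.patient_ids)


@dataclass
class RetrievalResult:
    proxy: np.ndarray        # unit-norm proxy pathology embedding
    neighbor_ids: list[str]
    similarities: np.ndarray  # non-increasing, in [-1, 1]
    k: int


def build_library(model: AlignmentModel, samples: list[PairedSample]) -> EmbeddingLibrary:
    """One frozen forward pass over the paired cohort, sorted by patient id."""
    if not samples:
        raise ValueError("cannot build a library from an empty cohort")
    samples = sorted(samples, key=lambda s: s.patient_id)
    e_img, e_path = model.embed_samples(samples)
    return EmbeddingLibrary([s.patient_id for s in samples], e_img, e_path)


def retrieve_proxy(query_img: np.ndarray, library: EmbeddingLibrary, k: int = 1,
                   mode: str = "cross") -> RetrievalResult:
    """Proxy pathology embedding for an imaging-only query.

    mode="cross" (default) matches the query directly against stored
    pathology embeddings; mode="paired" matches imaging-to-imaging and
    returns the paired pathology embeddings of those neighbors. Ties are
    broken by patient-id order. Top-k weights are max(similarity, 0)
    normalized to sum 1 (uniform if all are nonpositive); the weighted mean
    is re-normalized to unit length.
    """
    query = np.asarray(query_img, dtype=np.float64)
    if not 1 <= k <= library.K:
        raise ValueError(f"k={k} out of range [1, {library.K}]")
    if mode not in ("cross", "paired"):
        raise ValueError(f"unknown retrieval mode: {mode}")
    keys = library.path if mode == "cross" else library.img
    sims = keys @ query
    order = np.argsort(-sims, kind="stable")[:k]  # ids are sorted, so stable = id order
    top_sims = sims[order]
    if k == 1:
        proxy = library.path[order[0]].copy()
    else:
        weights = np.maximum(top_sims, 0.0)
        total = weights.sum()
        weights = weights / total if total > 0 else np.full(k, 1.0 / k)
        proxy = weights @ library.path[order]
        norm = np.linalg.norm(proxy)
        if norm < 1e-12:
            # weighted neighbors cancelled out; fall back to the best match
            proxy = library.path[order[0]].copy()
        else:
            proxy = proxy / norm
    return RetrievalResult(proxy=proxy,
                           neighbor_ids=[library.patient_ids[i] for i in order],
                           similarities=top_sims, k=k)


def save_library(library: EmbeddingLibrary, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "library.npz", img=library.img, path=library.path)
    pd.DataFrame({"patient_id": library.patient_ids}).to_csv(
        directory / "library_ids.csv", index=False)


def load_library(directory: str | Path) -> EmbeddingLibrary:
    directory = Path(directory)
    ids = pd.read_csv(directory / "library_ids.csv")["patient_id"].tolist()
    with np.load(directory / "library.npz") as data:
        return EmbeddingLibrary(ids, data["img"], data["path"])
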