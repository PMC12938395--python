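"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatchFeatureSet", "PairedSample", "SurvivalRecord", "Cohort"]

OS_CUTOFF_MONTHS = 12.0


@dataclass
class PatchFeatureSet:
    """Variable-length set of patch-level feature vectors for one slide.

    features is an N x C matrix; mask marks valid rows (padding rows are
    False). A set must contain at least one valid patch.
    """

    features: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    slide_id: str = ""

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("patch features must be a 2-d (N x C) matrix")
        if self.mask is None:
            self.mask = np.ones(self.features.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.features.shape[0],):
            raise ValueError("mask length must equal the number of patch rows")
        if not self.mask.any():
            raise ValueError("patch set must contain at least one valid patch")

    @property
    def n_patches(self) -> int:
        return int(self.mask.sum())

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]

    def valid_features(self) -> np.ndarray:
        return self.features[self.mask]


@dataclass
class PairedSample:
    """One patient: imaging view, pathology patch set and survival record.

    imaging is either a feature vector (1-d) or a 4-channel voxel volume
    (4-d, channels first). os_label follows the strict >12-month rule.
    """

    patient_id: str
    imaging: np.ndarray
    patches: PatchFeatureSet
    os_months: float
    os_label: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.imaging = np.asarray(self.imaging, dtype=np.float64)
        if self.imaging.ndim not in (1, 4):
            raise ValueError("imaging must be a feature vector or a 4-d volume")
        if self.imaging.ndim == 4 and self.imaging.shape[0] != 4:
            raise ValueError("imaging volume must have 4 channels (T1, T1CE, T2, FLAIR)")
        if not self.os_months > 0:
            raise ValueError("os_months must be positive")
        expected = int(self.os_months > OS_CUTOFF_MONTHS)
        if self.os_label is None:
            self.os_label = expected
        elif int(self.os_label) != expected:
            raise ValueError("os_label inconsistent with os_months under the 12-month rule")


@dataclass
class SurvivalRecord:
    patient_id: str
    os_months: float
    os_label: int

    def __post_init__(self):
        if not self.os_months > 0:
            raise ValueError("os_months must be positive")


@dataclass
class Cohort:
    """A generated cohort: samples plus the mixing model that produced them.

    Behaves as a sequence of PairedSample. A maps latent -> imaging space,
    B maps [z; h(z)] -> patch-feature space, survival_weights weight h(z)
    in the survival logit.
    """

    samples: list[PairedSample]
    A: np.ndarray
    B: np.ndarray
    survival_weights: np.ndarray
    latents: np.ndarray  # n_patients x latent_dim, for diagnostics

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i):
        return self.samples[i]
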