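"""Synthetic paired radiology-pathology cohorts and raster fixtures.

The generator emulates the structure of a paired MRI/WSI survival cohort:
a latent patient state z drives both modalities. The imaging view is a
noisy linear mixture of z; each pathology patch is a low-noise linear
mixture of [z; h(z)], where h(z) = z^2 - 1 is a fixed smooth nonlinearity.
Survival depends on h(z), so the pathology modality exposes the
survival-relevant signal almost directly while imaging carries it only
implicitly through z under heavier noise. This is exactly the regime in
which a retrieved pathology proxy can complement imaging features.

os_months is log-logistic: log(os/12) = logit + eps with eps standard
logistic, so P(os > 12) = sigmoid(logit) exactly and the binary label law
is analytic. Exactly 12.0 months maps to label 0 (strict >12 rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Cohort, PairedSample, PatchFeatureSet

__all__ = [
    "SyntheticConfig", "low_noise_config", "generate_cohort",
    "generate_he_patch", "generate_bimodal_image", "save_cohort", "load_cohort",
]


@dataclass
class SyntheticConfig:
    """Configuration of the paired-cohort generator.

    Defaults define the mediated study condition: imaging is a heavily
    noised 512-d linear view of a 4-d latent state, pathology patches are
    low-noise 64-d views of [z; h(z)], and survival is driven by h(z).
    """

    n_patients: int = 200
    latent_dim: int = 4
    imaging_dim: int = 512
    patch_dim: int = 64
    patch_count_range: tuple[int, int] = (8, 32)
    imaging_noise_sd: float = 2.5
    patch_noise_sd: float = 0.1
    survival_weights: np.ndarray | None = None
    seed: int = 0
    volume_shape: tuple[int, int, int] | None = None  # (D,H,W); 4 channels implied

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("latent_dim", "imaging_dim", "patch_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.patch_count_range
        if lo < 1 or lo > hi:
            raise ValueError("patch_count_range must satisfy 1 <= min <= max")
        if self.imaging_noise_sd < 0 or self.patch_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.survival_weights is None:
            # alternating-sign contrast weights: the survival logit is then a
            # *directional* function of the latent state rather than a radial
            # one, which unit-sphere (cosine) retrieval can transfer
            signs = np.where(np.arange(self.latent_dim) % 2 == 0, 1.0, -1.0)
            self.survival_weights = 1.5 / np.sqrt(self.latent_dim) * signs
        self.survival_weights = np.asarray(self.survival_weights, dtype=np.float64)
        if self.survival_weights.shape != (self.latent_dim,):
            raise ValueError("survival_weights must have length latent_dim")


def low_noise_config(**overrides) -> SyntheticConfig:
    """Preset with weak modality noise, used for alignment-recovery studies."""
    kwargs = dict(imaging_noise_sd=1.0, patch_noise_sd=0.1)
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def _h(z: np.ndarray) -> np.ndarray:
    """Pathology-visible nonlinearity: coordinate-wise squaring, centered."""
    return z ** 2 - 1.0


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a paired cohort; bit-identical for identical (config, seed)."""
    rng = np.random.default_rng(config.seed)
    L = config.latent_dim
    img_dim = config.imaging_dim
    if config.volume_shape is not None:
        d, h, w = config.volume_shape
        img_dim = 4 * d * h * w

    A = rng.normal(0.0, 1.0 / np.sqrt(L), size=(img_dim, L))
    B = rng.normal(0.0, 1.0 / np.sqrt(2 * L), size=(config.patch_dim, 2 * L))

    samples: list[PairedSample] = []
    latents = np.empty((config.n_patients, L))
    lo, hi = config.patch_count_range
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        z = rng.standard_normal(L)
        latents[i] = z
        hz = _h(z)

        imaging = A @ z + config.imaging_noise_sd * rng.standard_normal(img_dim)
        if config.volume_shape is not None:
            imaging = imaging.reshape(4, *config.volume_shape)

        n_patches = int(rng.integers(lo, hi + 1))
        base = B @ np.concatenate([z, hz])
        patches = base[None, :] + config.patch_noise_sd * rng.standard_normal(
            (n_patches, config.patch_dim))

        logit = float(config.survival_weights @ hz)
        eps = rng.logistic(0.0, 1.0)
        os_months = 12.0 * np.exp(logit + eps)

        samples.append(PairedSample(
            patient_id=pid,
            imaging=imaging,
            patches=PatchFeatureSet(patches, slide_id=f"{pid}-WSI"),
            os_months=float(os_months),
        ))
    return Cohort(samples=samples, A=A, B=B,
                  survival_weights=config.survival_weights.copy(), latents=latents)


def survival_logits(cohort: Cohort) -> np.ndarray:
    """Per-patient survival logits implied by the generator model."""
    return _h(cohort.latents) @ cohort.survival_weights


# -- raster fixtures ----------------------------------------------------------

def generate_he_patch(stain_matrix: np.ndarray, concentration_map: np.ndarray,
                      I0: float = 255.0) -> np.ndarray:
    """Render an H&E-like RGB patch through the Beer-Lambert law.

    pixel = I0 * exp(-stain_matrix @ concentrations), clipped to [0, I0]
    and quantized to uint8. stain_matrix is 3x2 (columns = stain OD
    vectors); concentration_map is (H, W, 2) with nonnegative entries.
    """
    M = np.asarray(stain_matrix, dtype=np.float64)
    C = np.asarray(concentration_map, dtype=np.float64)
    if M.shape != (3, 2):
        raise ValueError("stain_matrix must be 3x2")
    if C.ndim != 3 or C.shape[2] != 2:
        raise ValueError("concentration_map must be (H, W, 2)")
    if (C < 0).any():
        raise ValueError("concentrations must be nonnegative")
    if not I0 > 0:
        raise ValueError("I0 must be positive")
    od = C @ M.T                                   # (H, W, 3)
    img = np.clip(I0 * np.exp(-od), 0.0, I0)
    return np.rint(img).astype(np.uint8)


def generate_bimodal_image(mu0: float, mu1: float, fractions: tuple[float, float],
                           noise_sd: float, shape: tuple[int, int],
                           seed: int = 0) -> np.ndarray:
    """Two-component grayscale mixture image for thresholding fixtures."""
    if not mu0 < mu1:
        raise ValueError("mu0 must be strictly less than mu1")
    f0, f1 = fractions
    if abs(f0 + f1 - 1.0) > 1e-9 or f0 < 0 or f1 < 0:
        raise ValueError("fractions must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.random(shape) < f1
    img = np.where(comp, mu1, mu0).astype(np.float64)
    if noise_sd > 0:
        img += noise_sd * rng.standard_normal(shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# -- serialization ------------------------------------------------------------

def save_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write manifest.csv plus per-patient arrays (one npz) and the mixing model."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame({
        "patient_id": [s.patient_id for s in cohort],
        "os_months": [s.os_months for s in cohort],
        "os_label": [s.os_label for s in cohort],
        "n_patches": [s.patches.n_patches for s in cohort],
    })
    manifest.to_csv(directory / "manifest.csv", index=False)
    arrays: dict[str, np.ndarray] = {
        "A": cohort.A, "B": cohort.B,
        "survival_weights": cohort.survival_weights, "latents": cohort.latents,
    }
    for s in cohort:
        arrays[f"imaging_{s.patient_id}"] = s.imaging
        arrays[f"patches_{s.patient_id}"] = s.patches.features
    np.savez(directory / "cohort.npz", **arrays)


def load_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    with np.load(directory / "cohort.npz") as data:
        samples = [
            PairedSample(
                patient_id=row.patient_id,
                imaging=data[f"imaging_{row.patient_id}"],
                patches=PatchFeatureSet(data[f"patches_{row.patient_id}"],
                                        slide_id=f"{row.patient_id}-WSI"),
                os_months=float(row.os_months),
                os_label=int(row.os_label),
            )
            for row in manifest.itertuples()
        ]
        return Cohort(samples=samples, A=data["A"], B=data["B"],
                      survival_weights=data["survival_weights"],
                      latents=data["latents"])
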