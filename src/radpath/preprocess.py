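"""Deterministic whole-slide and volume preprocessing.

Tiling into non-overlapping square patches, Otsu background rejection on
the slide-level luminance histogram, Macenko stain normalization toward a
fixed reference hematoxylin/eosin model, and tumor-centroid cropping of
4-channel volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2gray

__all__ = [
    "Patch", "StainModel", "REFERENCE_STAIN", "tile_image", "otsu_threshold",
    "luminance", "luminance_histogram", "filter_background",
    "estimate_stain_model", "macenko_normalize", "crop_tumor_volume",
    "StainEstimationError", "tile_and_filter", "save_volume_nifti",
    "load_volume_nifti",
]


def save_volume_nifti(volume: np.ndarray, path) -> None:
    """Write a (4, D, H, W) volume as a 4D NIfTI (sequences on the last axis)."""
    import nibabel as nib
    if volume.ndim != 4 or volume.shape[0] != 4:
        raise ValueError("volume must have shape (4, D, H, W)")
    nib.save(nib.Nifti1Image(np.moveaxis(volume, 0, -1), affine=np.eye(4)), str(path))


def load_volume_nifti(path) -> np.ndarray:
    """Read a 4D NIfTI written by save_volume_nifti back to (4, D, H, W)."""
    import nibabel as nib
    data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 4:
        raise ValueError("expected a 4D NIfTI with 4 sequences on the last axis")
    return np.moveaxis(data, -1, 0)


class StainEstimationError(ValueError):
    """Raised when a patch does not support stain-vector estimation."""


@dataclass
class Patch:
    """A square tile with its 0-based (row, col) origin in the source image."""

    pixels: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self):
        h, w = self.pixels.shape[:2]
        if h != w:
            raise ValueError("patch must be square")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class StainModel:
    """Macenko stain model: unit OD stain vectors and concentration scale.

    stain_matrix columns are the hematoxylin and eosin OD direction vectors
    (hematoxylin first); max_concentrations holds the 99th-percentile
    concentration per stain, used to match concentration ranges across
    slides.
    """

    stain_matrix: np.ndarray        # 3x2, unit-norm columns
    max_concentrations: np.ndarray  # length 2, positive
    I0: float = 255.0

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=np.float64)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=np.float64)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain_matrix columns must be unit Euclidean norm")
        if (self.max_concentrations <= 0).any():
            raise ValueError("max_concentrations must be positive")
        if not self.I0 > 0:
            raise ValueError("I0 must be positive")


def _unit_columns(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=0, keepdims=True)


# Conventional H&E OD reference (hematoxylin, eosin columns) with the
# customary concentration ceilings; overridable everywhere it is used.
REFERENCE_STAIN = StainModel(
    stain_matrix=_unit_columns(np.array([[0.65, 0.07],
                                         [0.70, 0.99],
                                         [0.29, 0.11]])),
    max_concentrations=np.array([1.9705, 1.0308]),
    I0=255.0,
)


def tile_image(image: np.ndarray, patch_size: int) -> list[Patch]:
    """Partition an image into non-overlapping patch_size tiles.

    Partial border tiles are dropped; origins are multiples of patch_size.
    """
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError("image smaller than one patch")
    patches = []
    for r in range(0, (h // patch_size) * patch_size, patch_size):
        for c in range(0, (w // patch_size) * patch_size, patch_size):
            patches.append(Patch(image[r:r + patch_size, c:c + patch_size].copy(), (r, c)))
    return patches


def otsu_threshold(gray_histogram: np.ndarray) -> int:
    """Otsu's threshold from a 256-bin histogram of gray levels.

    Returns the level t maximizing the between-class variance
    w0*w1*(mu0-mu1)^2 with class 0 = levels <= t; ties resolve to the
    lowest qualifying level. Requires at least two occupied levels.
    """
    hist = np.asarray(gray_histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if (hist < 0).any():
        raise ValueError("histogram counts must be nonnegative")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate input: fewer than 2 occupied gray levels")
    levels = np.arange(256, dtype=np.float64)
    total = hist.sum()
    w0 = np.cumsum(hist) / total
    w1 = 1.0 - w0
    cum_mean = np.cumsum(hist * levels) / total
    grand_mean = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand_mean - cum_mean) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where(np.isfinite(sigma_b), sigma_b, -np.inf)
    return int(np.argmax(sigma_b))


def luminance(image: np.ndarray) -> np.ndarray:
    """Gray-level luminance in [0, 255] for RGB or grayscale input."""
    if image.ndim == 3:
        return rgb2gray(image) * 255.0
    return image.astype(np.float64)


def luminance_histogram(image: np.ndarray) -> np.ndarray:
    lum = np.clip(np.rint(luminance(image)), 0, 255).astype(np.intp)
    return np.bincount(lum.ravel(), minlength=256)[:256]


def tissue_fraction(patch_pixels: np.ndarray, threshold: float) -> float:
    """Fraction of pixels darker than the background threshold.

    H&E tissue absorbs light and is darker than the glass background, so
    tissue is luminance strictly below the threshold.
    """
    return float(np.mean(luminance(patch_pixels) < threshold))


def filter_background(patches: list[Patch], threshold: float,
                      min_tissue_fraction: float = 0.5) -> list[Patch]:
    """Keep patches whose tissue fraction reaches min_tissue_fraction."""
    if not patches:
        raise ValueError("empty patch list")
    return [p for p in patches
            if tissue_fraction(p.pixels, threshold) >= min_tissue_fraction]


def _nnls_2col(M: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Exact nonnegative least squares for a 3x2 system, vectorized over rows.

    Solves min ||M c - od||^2 s.t. c >= 0 for each od row by checking the
    unconstrained solution and the three boundary candidates.
    """
    G = M.T @ M
    if abs(np.linalg.det(G)) < 1e-12:
        raise ValueError("singular stain matrix")
    b = od @ M                                   # (n, 2)
    c_free = b @ np.linalg.inv(G).T
    ok = (c_free >= 0).all(axis=1)
    out = np.where(ok[:, None], c_free, 0.0)
    bad = ~ok
    if bad.any():
        bb = b[bad]
        cands = np.zeros((bb.shape[0], 3, 2))
        cands[:, 0, 0] = np.maximum(bb[:, 0] / G[0, 0], 0.0)   # eosin = 0
        cands[:, 1, 1] = np.maximum(bb[:, 1] / G[1, 1], 0.0)   # hematoxylin = 0
        # residual^2 = ||od||^2 - 2 c.b + c.G.c ; ||od||^2 is common
        score = -2.0 * np.einsum("nkj,nj->nk", cands, bb) \
            + np.einsum("nkj,ji,nki->nk", cands, G, cands)
        best = np.argmin(score, axis=1)
        out[bad] = cands[np.arange(bb.shape[0]), best]
    return out


def _optical_density(pixels: np.ndarray, I0: float, eps: float = 1.0) -> np.ndarray:
    # eps added to numerator and ceiling alike so a pixel at I0 has OD exactly 0
    return -np.log((pixels.astype(np.float64) + eps) / (I0 + eps))


def estimate_stain_model(patch: np.ndarray, I0: float = 255.0,
                         od_floor: float = 0.15, angular_percentile: float = 1.0,
                         min_pixels: int = 20) -> StainModel:
    """Macenko stain estimation from an RGB patch.

    Pixels whose OD is at or below od_floor in every channel are discarded;
    the top-2 singular directions of the remaining OD cloud define a plane;
    stain vectors are the extreme directions at the angular_percentile and
    100 - angular_percentile angular percentiles, sign-fixed to nonnegative
    orientation and ordered hematoxylin-first (larger blue-channel OD).
    """
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError("patch must be RGB")
    od = _optical_density(patch.reshape(-1, 3), I0)
    keep = (od > od_floor).any(axis=1)
    od = od[keep]
    if od.shape[0] < min_pixels:
        raise StainEstimationError(
            f"only {od.shape[0]} pixels above OD floor {od_floor}; need {min_pixels}")
    _, s, vt = np.linalg.svd(od, full_matrices=False)
    # quantized single-stain clouds still show s1/s0 ~ 3e-3; genuine two-stain
    # patches sit around 0.1 or higher
    if s[1] < 0.02 * s[0]:
        raise StainEstimationError("rank-1 OD cloud: single-stain or degenerate patch")
    plane = vt[:2]                                # (2, 3)
    # orient the plane basis so projections are predominantly positive
    proj = od @ plane.T                           # (n, 2)
    for j in range(2):
        if proj[:, j].sum() < 0:
            plane[j] = -plane[j]
            proj[:, j] = -proj[:, j]
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, angular_percentile)
    hi = np.percentile(phi, 100.0 - angular_percentile)
    vecs = []
    for ang in (lo, hi):
        v = np.cos(ang) * plane[0] + np.sin(ang) * plane[1]
        if v.sum() < 0:
            v = -v
        vecs.append(v / np.linalg.norm(v))
    v1, v2 = vecs
    # hematoxylin has the larger blue-channel OD weight
    if v1[2] >= v2[2]:
        stain_matrix = np.column_stack([v1, v2])
    else:
        stain_matrix = np.column_stack([v2, v1])
    conc = _nnls_2col(stain_matrix, od)
    max_c = np.maximum(np.percentile(conc, 99, axis=0), 1e-6)
    return StainModel(stain_matrix=stain_matrix, max_concentrations=max_c, I0=I0)


def macenko_normalize(patch: np.ndarray, source: StainModel,
                      reference: StainModel = REFERENCE_STAIN) -> np.ndarray:
    """Re-render a patch from its source stain model into the reference model.

    Concentrations are solved by nonnegative least squares against the
    source stain matrix, rescaled by the reference/source concentration
    ceilings, and re-rendered through the reference matrix via the
    Beer-Lambert law.
    """
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError("patch must be RGB")
    shape = patch.shape
    od = _optical_density(patch.reshape(-1, 3), source.I0)
    conc = _nnls_2col(source.stain_matrix, od)
    conc *= reference.max_concentrations / source.max_concentrations
    od_new = conc @ reference.stain_matrix.T
    out = (reference.I0 + 1.0) * np.exp(-od_new) - 1.0  # exact inverse of the OD map
    out = np.clip(out, 0.0, reference.I0).reshape(shape)
    if np.issubdtype(patch.dtype, np.integer):
        return np.rint(out).astype(patch.dtype)
    return out


def crop_tumor_volume(volume: np.ndarray, centroid: tuple[int, int, int],
                      size: int) -> np.ndarray:
    """Axis-aligned size^3 crop of a 4-channel volume centered at centroid.

    Windows that would cross a boundary are shifted inward (no padding);
    all 4 channels are cropped identically.
    """
    if volume.ndim != 4 or volume.shape[0] != 4:
        raise ValueError("volume must be 4-channel, shape (4, D, H, W)")
    dims = volume.shape[1:]
    if any(size > d for d in dims):
        raise ValueError(f"crop size {size} exceeds volume dimensions {dims}")
    starts = [int(np.clip(c - size // 2, 0, d - size)) for c, d in zip(centroid, dims)]
    sl = tuple(slice(s, s + size) for s in starts)
    return volume[(slice(None),) + sl].copy()


def tile_and_filter(image: np.ndarray, patch_size: int,
                    min_tissue_fraction: float = 0.5,
                    normalize: bool = True,
                    reference: StainModel = REFERENCE_STAIN,
                    slide_id: str = "slide") -> tuple[list[Patch], pd.DataFrame]:
    """Full slide preprocessing: tile, Otsu-filter, optionally stain-normalize.

    Otsu runs once on the slide-level luminance histogram. Returns the kept
    (normalized) patches and a manifest with one row per tile.
    """
    tiles = tile_image(image, patch_size)
    thr = otsu_threshold(luminance_histogram(image))
    fractions = [tissue_fraction(p.pixels, thr) for p in tiles]
    kept_mask = [f >= min_tissue_fraction for f in fractions]
    kept: list[Patch] = []
    for p, keep in zip(tiles, kept_mask):
        if not keep:
            continue
        pixels = p.pixels
        if normalize and pixels.ndim == 3:
            try:
                model = estimate_stain_model(pixels, I0=reference.I0)
                pixels = macenko_normalize(pixels, model, reference)
            except StainEstimationError:
                pass  # keep un-normalized if the tile cannot support estimation
        kept.append(Patch(pixels, p.origin))
    manifest = pd.DataFrame({
        "slide_id": slide_id,
        "row": [p.origin[0] for p in tiles],
        "col": [p.origin[1] for p in tiles],
        "kept": kept_mask,
        "tissue_fraction": fractions,
    })
    return kept, manifest
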