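"""DAB optical densitometry of immunohistochemistry micrographs.

Chromogen amount in an H-DAB stained section is quantified in two steps.
First, the RGB micrograph is colour-deconvolved: per-pixel channel
intensities are converted to absorbances via the Beer–Lambert relation and
projected onto the haematoxylin / DAB / residual stain basis, and each
stain's absorbance map is re-expressed as an 8-bit intensity image.
Second, square regions of equal size are sampled at seeded-random positions
(in triplicate by default) and each region's optical density is computed
from its mean intensity as

    OD = log10(max_intensity / mean_intensity),  max_intensity = 255.

The package absorbance convention is A = -log10((I + 1) / 256): a blank
pixel (I = 255) has exactly zero absorbance and the forward synthesis
I = 256 * 10**(-A) - 1 is its exact inverse up to 8-bit quantization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError

MAX_INTENSITY = 255.0

#: Standard published H-DAB absorbance vectors (unit RGB), configurable.
HEMATOXYLIN_RGB = (0.650, 0.704, 0.286)
DAB_RGB = (0.269, 0.568, 0.778)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("stain vector must be non-zero")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Unit RGB absorbance vectors for haematoxylin, DAB and the residual.

    The residual defaults to the normalized cross product of the two named
    stains, completing an invertible 3x3 stain matrix.
    """

    hematoxylin: tuple = HEMATOXYLIN_RGB
    dab: tuple = DAB_RGB
    residual: Optional[tuple] = None

    @property
    def matrix(self) -> np.ndarray:
        """Rows = unit stain absorbance vectors (hema, dab, residual)."""
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        if self.residual is not None:
            r = _unit(self.residual)
        else:
            r = np.cross(h, d)
            norm = np.linalg.norm(r)
            if norm < 1e-12:
                raise ValidationError("stain vectors are collinear")
            r = np.abs(r) / norm
        m = np.vstack([h, d, r])
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValidationError("singular stain matrix")
        if np.any(np.vstack([h, d]) < 0):
            raise ValidationError("stain vector components must be >= 0")
        return m


def _to_absorbance(intensity: np.ndarray) -> np.ndarray:
    return -np.log10((np.asarray(intensity, dtype=float) + 1.0) / 256.0)


def _to_intensity(absorbance: np.ndarray, quantize: bool = True) -> np.ndarray:
    raw = 256.0 * np.power(10.0, -np.asarray(absorbance, dtype=float)) - 1.0
    if not quantize:
        return np.clip(raw, 0.0, 255.0)
    return np.clip(np.round(raw), 0, 255).astype(np.uint8)


def hdab_deconvolve(
    rgb: np.ndarray, vectors: StainVectors | None = None
) -> dict[str, np.ndarray]:
    """Separate an 8-bit RGB image into per-stain 8-bit intensity images.

    Returns ``{"hematoxylin": ..., "dab": ..., "residual": ...}`` where each
    value is a uint8 image re-expressing that stain's absorbance as
    transmitted intensity (255 = no stain).
    """
    vectors = vectors or StainVectors()
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError("expected an H x W x 3 RGB image")
    if rgb.dtype != np.uint8:
        if np.any(rgb < 0) or np.any(rgb > 255):
            raise ValidationError("RGB values must lie in [0, 255]")
    m = vectors.matrix
    absorb = _to_absorbance(rgb.astype(float))  # H x W x 3
    # A = M^T c  =>  c = (M^T)^-1 A, per pixel
    inv = np.linalg.inv(m.T)
    amounts = absorb @ inv.T  # H x W x 3 stain amounts
    names = ("hematoxylin", "dab", "residual")
    return {name: _to_intensity(amounts[..., i]) for i, name in enumerate(names)}


def stain_amounts(rgb: np.ndarray, vectors: StainVectors | None = None) -> np.ndarray:
    """Per-pixel stain absorbance amounts (H x W x 3, order hema/dab/residual)."""
    vectors = vectors or StainVectors()
    absorb = _to_absorbance(np.asarray(rgb, dtype=float))
    return absorb @ np.linalg.inv(vectors.matrix.T).T


def synthesize_rgb(
    amounts: np.ndarray,
    vectors: StainVectors | None = None,
    quantize: bool = True,
) -> np.ndarray:
    """Forward model: stain amounts (H x W x 3) to an RGB image.

    ``quantize=False`` returns the continuous float image (useful for exact
    round trips); small negative amounts, as produced by deconvolving a
    quantized image, are accepted so that deconvolve-then-synthesize is an
    identity.
    """
    vectors = vectors or StainVectors()
    amounts = np.asarray(amounts, dtype=float)
    if amounts.ndim != 3 or amounts.shape[2] != 3:
        raise ValidationError("amounts must be H x W x 3 (hema, dab, residual)")
    absorb = amounts @ vectors.matrix  # A = c @ M (rows of M are stain vectors)
    return _to_intensity(absorb, quantize=quantize)


def optical_density(mean_intensity: float, max_intensity: float = MAX_INTENSITY) -> float:
    """OD = log10(max_intensity / mean_intensity); strictly decreasing in the mean."""
    if not 0 < mean_intensity <= max_intensity:
        raise ValidationError(
            f"mean intensity must be in (0, {max_intensity}], got {mean_intensity}"
        )
    return float(np.log10(max_intensity / mean_intensity))


def sample_region_ods(
    image: np.ndarray,
    n_regions: int = 3,
    region_size: int = 128,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    no_overlap: bool = False,
    max_resample: int = 1000,
) -> tuple[list[float], float, list[tuple[int, int]]]:
    """Optical densities of randomly placed equal-size square regions.

    Regions are axis-aligned ``region_size`` squares at uniform-random
    positions inside the image (seeded; identical seed gives identical
    coordinates). Each region's OD comes from its mean intensity; the
    summary is the arithmetic mean over regions. Overlap is allowed unless
    ``no_overlap`` is set, in which case colliding draws are resampled.

    Returns (per-region ODs, mean OD, region top-left coordinates).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("expected a single-channel intensity image")
    h, w = img.shape
    if region_size > h or region_size > w:
        raise ValidationError(
            f"region size {region_size} exceeds image shape {(h, w)}"
        )
    rng = rng if rng is not None else np.random.default_rng(seed)

    coords: list[tuple[int, int]] = []
    attempts = 0
    while len(coords) < n_regions:
        r = int(rng.integers(0, h - region_size + 1))
        c = int(rng.integers(0, w - region_size + 1))
        if no_overlap:
            collide = any(
                abs(r - r0) < region_size and abs(c - c0) < region_size
                for r0, c0 in coords
            )
            if collide:
                attempts += 1
                if attempts > max_resample:
                    raise ValidationError(
                        "could not place non-overlapping regions; "
                        "reduce region_size or n_regions"
                    )
                continue
        coords.append((r, c))

    ods = []
    for r, c in coords:
        mean = float(img[r : r + region_size, c : c + region_size].mean())
        ods.append(optical_density(mean))
    return ods, float(np.mean(ods)), coords
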