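"""Thermal-domain features: binary pixel count and Fourier ring/wedge texture sums.

A fatigued face shows a warmer periorbital region; the thermal image is
summarised by (i) the number of pixels above a binarization threshold over
the whole facial image and (ii) texture descriptors of two regions of
interest — the periorbital box mapped from the visible-spectrum eye-pair
detection, and an equal-size forehead box directly above it. Texture is
quantified on the centred power spectrum |F(u,v)|^2 by partitioning the
off-DC bins within radius R0 into concentric rings (radial frequency
content) and angular wedges (orientation content) and summing power in each
partition. The scalar features are the wedge-partition total (angular sum)
and ring-partition total (radial sum); with rings and wedges covering the
same disc both equal the total off-DC power within R0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import InvalidParameterError

__all__ = [
    "ThermalImage",
    "RoiPair",
    "ThermalFeatureVector",
    "binarize_and_count",
    "map_rois",
    "power_spectrum",
    "ring_wedge_profiles",
    "ring_wedge_features",
    "thermal_features",
    "THERMAL_FEATURE_NAMES",
]

THERMAL_FEATURE_NAMES = ("pixel_count", "FHFa", "FHFr", "PRFa", "PRFr")

#: Default binarization threshold for the white-pixel count (8-bit midpoint).
DEFAULT_BINARIZE_THRESHOLD = 128


@dataclass(frozen=True)
class ThermalImage:
    """One grayscale thermal frame (320x240 by default) with a source tag."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidParameterError("thermal image must be a non-empty 2-D array")
        if px.min() < 0 or px.max() > 255:
            raise InvalidParameterError("thermal intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)


Box = tuple[int, int, int, int]  # x, y, w, h


def _check_box(box: Box, shape: tuple[int, int], name: str) -> None:
    x, y, w, h = box
    if w <= 0 or h <= 0:
        raise InvalidParameterError(f"{name} box has non-positive size")
    if x < 0 or y < 0 or x + w > shape[1] or y + h > shape[0]:
        raise InvalidParameterError(f"{name} box {box} outside image {shape}")


@dataclass(frozen=True)
class RoiPair:
    """Periorbital box plus the equal-size forehead box directly above it."""

    periorbital: Box
    forehead: Box

    def validate_within(self, shape: tuple[int, int]) -> "RoiPair":
        _check_box(self.periorbital, shape, "periorbital")
        _check_box(self.forehead, shape, "forehead")
        return self


@dataclass(frozen=True)
class ThermalFeatureVector:
    """pixel_count plus angular/radial power sums of both ROIs."""

    pixel_count: float
    FHFa: float
    FHFr: float
    PRFa: float
    PRFr: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, n) for n in THERMAL_FEATURE_NAMES], dtype=float
        )


def binarize_and_count(
    image: np.ndarray, threshold: float | str = DEFAULT_BINARIZE_THRESHOLD
) -> int:
    """Count pixels strictly above ``threshold`` (``"otsu"`` for adaptive)."""
    image = np.asarray(image)
    if image.size == 0:
        raise InvalidParameterError("image is empty")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise InvalidParameterError(f"unknown threshold mode {threshold!r}")
        if image.max() == image.min():
            return 0
        threshold = threshold_otsu(image)
    return int(np.count_nonzero(image > threshold))


def map_rois(
    eye_bbox: Box,
    visible_size: tuple[int, int],
    thermal_size: tuple[int, int],
) -> RoiPair:
    """Map a visible-spectrum eye-pair box onto the thermal image.

    The visible image is notionally resized to the thermal size, so the box
    is scaled by (thermal_w/visible_w, thermal_h/visible_h) and rounded to
    the nearest pixel, giving the periorbital box; the forehead box has the
    same size and sits directly above it, clamped at the top edge.
    """
    vw, vh = visible_size
    tw, th = thermal_size
    if vw <= 0 or vh <= 0 or tw <= 0 or th <= 0:
        raise InvalidParameterError("image sizes must be positive")
    _check_box(eye_bbox, (vh, vw), "eye")
    sx, sy = tw / vw, th / vh
    x, y, w, h = eye_bbox
    px = int(round(x * sx))
    py = int(round(y * sy))
    pw = int(round(w * sx))
    ph = int(round(h * sy))
    if pw <= 0 or ph <= 0:
        raise InvalidParameterError("eye box degenerates to zero area after scaling")
    px = min(px, tw - pw)
    py = min(py, th - ph)
    periorbital = (px, py, pw, ph)
    forehead = (px, max(py - ph, 0), pw, ph)
    pair = RoiPair(periorbital=periorbital, forehead=forehead)
    return pair.validate_within((th, tw))


def power_spectrum(roi: np.ndarray) -> np.ndarray:
    """Centred squared-magnitude DFT, |F(u,v)|^2 = F(u,v) F*(u,v).

    Real and non-negative; the DC bin sits at the array centre
    (``(h//2, w//2)`` after shifting). Satisfies Parseval's identity:
    ``spectrum.sum() == h*w * (roi**2).sum()``.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.size == 0 or roi.ndim != 2:
        raise InvalidParameterError("ROI must be a non-empty 2-D array")
    spectrum = np.fft.fftshift(np.fft.fft2(roi))
    return (spectrum * spectrum.conj()).real


def _polar_bins(
    shape: tuple[int, int], R0: float, n_rings: int, n_wedges: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Off-DC mask plus ring and wedge index arrays about the spectrum centre."""
    h, w = shape
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    # opposite half-plane folded onto [0, pi) by the spectrum's point symmetry
    theta = np.mod(np.arctan2(dy, dx), np.pi)
    mask = (r > 0) & (r <= R0)
    ring = np.minimum((r / R0 * n_rings).astype(int), n_rings - 1)
    wedge = np.minimum((theta / np.pi * n_wedges).astype(int), n_wedges - 1)
    return mask, ring, wedge


def ring_wedge_profiles(
    spectrum: np.ndarray,
    R0: float | None = None,
    n_rings: int = 16,
    n_wedges: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial and angular power profiles of a centred power spectrum.

    The off-DC bins with radius <= R0 are assigned wholly (by bin centre, no
    interpolation) to one of ``n_rings`` equal-width concentric rings and to
    one of ``n_wedges`` equal wedges over [0, pi) (the opposite half-plane
    folds on top by symmetry). Returns ``(radial_profile, angular_profile)``:
    power summed per ring and per wedge. Each profile partitions the same
    disc, so both sum to the total off-DC power within R0.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size == 0 or spectrum.ndim != 2:
        raise InvalidParameterError("spectrum must be a non-empty 2-D array")
    if np.any(spectrum < -1e-9):
        raise InvalidParameterError("power spectrum must be non-negative")
    half_min = min(spectrum.shape) / 2
    if R0 is None:
        R0 = half_min
    if R0 <= 0 or R0 > half_min:
        raise InvalidParameterError(
            f"R0 must lie in (0, {half_min}] for shape {spectrum.shape}"
        )
    if n_rings < 1 or n_wedges < 1:
        raise InvalidParameterError("n_rings and n_wedges must be >= 1")
    mask, ring, wedge = _polar_bins(spectrum.shape, R0, n_rings, n_wedges)
    power = np.where(mask, spectrum, 0.0)
    radial = np.bincount(ring.ravel(), weights=power.ravel(), minlength=n_rings)[
        :n_rings
    ]
    angular = np.bincount(wedge.ravel(), weights=power.ravel(), minlength=n_wedges)[
        :n_wedges
    ]
    return radial, angular


def ring_wedge_features(
    spectrum: np.ndarray,
    R0: float | None = None,
    n_rings: int = 16,
    n_wedges: int = 16,
) -> tuple[float, float]:
    """Scalar ``(angular_sum, radial_sum)`` texture features.

    Both equal the total off-DC spectral power within radius R0 (the rings
    and the wedges each partition the same disc); they are kept as two named
    features to mirror the per-ROI feature table.
    """
    radial, angular = ring_wedge_profiles(
        spectrum, R0=R0, n_rings=n_rings, n_wedges=n_wedges
    )
    return float(angular.sum()), float(radial.sum())


def thermal_features(
    image: ThermalImage | np.ndarray,
    rois: RoiPair,
    threshold: float | str = DEFAULT_BINARIZE_THRESHOLD,
    R0: float | None = None,
    n_rings: int = 16,
    n_wedges: int = 16,
) -> ThermalFeatureVector:
    """Full thermal feature vector for one image and ROI pair."""
    pixels = image.pixels if isinstance(image, ThermalImage) else np.asarray(image)
    rois.validate_within(pixels.shape)
    count = binarize_and_count(pixels, threshold=threshold)

    def roi_sums(box: Box) -> tuple[float, float]:
        x, y, w, h = box
        spec = power_spectrum(pixels[y : y + h, x : x + w].astype(float))
        return ring_wedge_features(spec, R0=R0, n_rings=n_rings, n_wedges=n_wedges)

    fhfa, fhfr = roi_sums(rois.forehead)
    prfa, prfr = roi_sums(rois.periorbital)
    return ThermalFeatureVector(
        pixel_count=float(count), FHFa=fhfa, FHFr=fhfr, PRFa=prfa, PRFr=prfr
    )
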