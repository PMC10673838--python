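"""Threshold-segmentation foci counting per nucleus.

Pipeline, mirroring a standard ImageJ macro: rolling-ball-style background
subtraction (approximated by grayscale morphological opening with a disk),
linear contrast rescale saturating a small fraction of pixels at each tail,
Gaussian blur, fixed threshold to a focus mask, then connected-component
particle counting within each nucleus label with an area gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, morphology

__all__ = ["FociParams", "FociResult", "segment_nuclei", "count_foci", "percent_positive",
           "preprocess"]


@dataclass(frozen=True)
class FociParams:
    """Foci-mask parameters.

    ``threshold`` applies to the preprocessed image, which is rescaled to
    [0, 1]; integer-scale thresholds (> 1) are interpreted in the input
    image's dtype range and normalized. Saturation fraction defaults to the
    ImageJ contrast default (0.35% per tail).
    """

    background_radius_px: float = 15.0
    saturation_fraction: float = 0.0035
    blur_sigma_px: float = 1.0
    threshold: float = 0.25
    min_area_px: int = 2
    max_area_px: int = 500
    positivity_k: int = 5
    positivity_rule: str = "gt"  # "gt": count > k; "ge": count >= k

    def __post_init__(self) -> None:
        if self.background_radius_px <= 0:
            raise ValueError("background_radius_px must be > 0")
        if self.blur_sigma_px <= 0:
            raise ValueError("blur_sigma_px must be > 0")
        if not 0 <= self.saturation_fraction < 0.5:
            raise ValueError("saturation_fraction must be in [0, 0.5)")
        if self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px must be <= max_area_px")
        if self.min_area_px < 0:
            raise ValueError("areas must be >= 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.positivity_rule not in ("gt", "ge"):
            raise ValueError("positivity_rule must be 'gt' or 'ge'")


@dataclass(frozen=True)
class FociResult:
    per_nucleus: pd.DataFrame  # nucleus_id, focus_count, nucleus_area
    params: FociParams

    @property
    def counts(self) -> np.ndarray:
        return self.per_nucleus["focus_count"].to_numpy()


def _as_float01(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Return the image as float in [0, 1] plus the dtype scale divisor."""
    if np.issubdtype(image.dtype, np.integer):
        scale = float(np.iinfo(image.dtype).max)
        return image.astype(float) / scale, scale
    return image.astype(float), 1.0


def segment_nuclei(
    image: np.ndarray, nucleus_threshold: float, min_nucleus_area: int = 50
) -> np.ndarray:
    """Label connected components above ``nucleus_threshold`` that are larger
    than ``min_nucleus_area`` pixels, labeled 1..n. Empty result warns."""
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    img, scale = _as_float01(image)
    if nucleus_threshold > 1:
        nucleus_threshold /= scale
    mask = img >= nucleus_threshold
    labels, _ = ndi.label(mask)
    if labels.max():
        areas = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(areas >= min_nucleus_area) + 1
        relabel = np.zeros(labels.max() + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
    if labels.max() == 0:
        warnings.warn("no nucleus found", stacklevel=2)
    return labels.astype(np.int32)


def preprocess(image: np.ndarray, params: FociParams) -> np.ndarray:
    """Background-subtract, contrast-rescale, and blur; output float in [0, 1]."""
    img, _ = _as_float01(image)
    footprint = morphology.disk(int(round(params.background_radius_px)))
    background = morphology.opening(img, footprint)
    img = np.clip(img - background, 0.0, None)

    lo, hi = np.quantile(img, [params.saturation_fraction, 1.0 - params.saturation_fraction])
    if hi > lo:
        img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)

    return filters.gaussian(img, sigma=params.blur_sigma_px, preserve_range=True)


def count_foci(image: np.ndarray, labels: np.ndarray, params: FociParams) -> FociResult:
    """Count area-gated focus particles inside each nucleus label."""
    if image.shape != labels.shape:
        raise ValueError("labels must be aligned to the image")
    img, scale = _as_float01(image)
    threshold = params.threshold / scale if params.threshold > 1 else params.threshold

    processed = preprocess(image, params)
    mask = processed >= threshold

    rows = []
    for nucleus_id in range(1, int(labels.max()) + 1):
        in_nucleus = labels == nucleus_id
        particles, n_particles = ndi.label(mask & in_nucleus)
        count = 0
        if n_particles:
            areas = np.bincount(particles.ravel())[1:]
            count = int(((areas >= params.min_area_px) & (areas <= params.max_area_px)).sum())
        rows.append(
            {"nucleus_id": nucleus_id, "focus_count": count, "nucleus_area": int(in_nucleus.sum())}
        )
    per_nucleus = pd.DataFrame(rows, columns=["nucleus_id", "focus_count", "nucleus_area"])
    return FociResult(per_nucleus=per_nucleus, params=params)


def percent_positive(result: FociResult | np.ndarray, k: int, rule: str = "gt") -> float:
    """Percent of nuclei with focus count > k ('gt') or >= k ('ge')."""
    if rule not in ("gt", "ge"):
        raise ValueError("rule must be 'gt' or 'ge'")
    counts = result.counts if isinstance(result, FociResult) else np.asarray(result)
    if counts.size == 0:
        raise ValueError("need at least one nucleus")
    positive = counts > k if rule == "gt" else counts >= k
    return 100.0 * positive.mean()
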