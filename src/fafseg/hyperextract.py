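"""Intensity-calibration baseline for hyperfluorescence segmentation.

A deliberately simple, fast HF predictor: after contrast enhancement
(CLAHE), median filtering and a center crop that removes the fuzzy FAF
image border, the 8-bit intensity histogram is calibrated against the
annotated HF masks of a training set.  For each intensity value
``I in {0..255}`` the calibration stores how often it occurs and how often
it falls inside an HF mask, yielding an empirical probability
``p(I) = hf_count / occurrence`` of an intensity belonging to HF
(0 for intensities never observed).  Prediction thresholds ``p(I)`` at
``mu_he``; the cropped border is re-embedded as background so all outputs
share the original image frame.

Besides serving as a standalone baseline, the calibrated predictor is the
default member for bagged ensembles: two members fitted on different
bootstrap resamples of heterogeneous scenes learn different p(I) tables,
which is exactly the member diversity the ensemble variance map feeds on.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.exposure import equalize_adapthist


@dataclasses.dataclass
class PreprocessParams:
    """CLAHE + median-filter + center-crop settings.

    ``clahe_clip`` follows scikit-image semantics (fraction of the local
    histogram, typical values 0.005–0.05).  ``crop_to = None`` disables
    cropping, for inputs that have no fuzzy border (e.g. synthetic
    scenes).  The native clinical frame is 768 px cropped to 700 px,
    i.e. a 34 px margin on each side.
    """

    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    median_kernel: int = 5
    crop_to: int | None = 700


def _center_crop_slices(shape: tuple[int, int], crop_to: int) -> tuple[slice, slice]:
    h, w = shape
    if crop_to > min(h, w):
        raise ValueError(f"image {h}x{w} smaller than crop size {crop_to}")
    top = (h - crop_to) // 2
    left = (w - crop_to) // 2
    return slice(top, top + crop_to), slice(left, left + crop_to)


def preprocess(image: np.ndarray, params: PreprocessParams | None = None) -> np.ndarray:
    """CLAHE, then median filter, then center crop; returns uint8."""
    params = params or PreprocessParams()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if params.clahe_clip > 0:
        tile = max(1, min(img.shape) // params.clahe_tiles)
        out = equalize_adapthist(img.astype(np.uint8), kernel_size=tile,
                                 clip_limit=params.clahe_clip)
        img = (out * 255).round().astype(np.uint8)
    else:
        img = img.astype(np.uint8)
    if params.median_kernel > 1:
        img = ndimage.median_filter(img, size=params.median_kernel)
    if params.crop_to is not None:
        sy, sx = _center_crop_slices(img.shape, params.crop_to)
        img = img[sy, sx]
    return img


@dataclasses.dataclass
class IntensityCalibration:
    """Per-intensity occurrence/HF counts and the derived probabilities."""

    occurrence: np.ndarray  # (256,) int64
    hf_count: np.ndarray  # (256,) int64

    def __post_init__(self) -> None:
        self.occurrence = np.asarray(self.occurrence, dtype=np.int64)
        self.hf_count = np.asarray(self.hf_count, dtype=np.int64)
        if self.occurrence.shape != (256,) or self.hf_count.shape != (256,):
            raise ValueError("calibration tables must have 256 entries")
        if (self.hf_count > self.occurrence).any() or (self.hf_count < 0).any():
            raise ValueError("inconsistent calibration counts")

    @property
    def probability(self) -> np.ndarray:
        """p(I) for every intensity; 0 where the intensity was never seen."""
        occ = self.occurrence
        return np.divide(self.hf_count, occ, out=np.zeros(256), where=occ > 0)


def fit_intensity_calibration(images: Sequence[np.ndarray],
                              hf_masks: Sequence[np.ndarray],
                              params: PreprocessParams | None = None) -> IntensityCalibration:
    """Accumulate intensity/HF counts over all pixels of all image-mask pairs.

    Masks are given in the original frame and cropped alongside the image
    so counts come from the same coordinate window.
    """
    params = params or PreprocessParams()
    occurrence = np.zeros(256, dtype=np.int64)
    hf_count = np.zeros(256, dtype=np.int64)
    for image, mask in zip(images, hf_masks, strict=True):
        pre = preprocess(image, params)
        mask = np.asarray(mask).astype(bool)
        if mask.shape != np.asarray(image).shape:
            raise ValueError("image/mask grid mismatch")
        if params.crop_to is not None:
            sy, sx = _center_crop_slices(mask.shape, params.crop_to)
            mask = mask[sy, sx]
        occurrence += np.bincount(pre.ravel(), minlength=256)
        hf_count += np.bincount(pre[mask].ravel(), minlength=256)
    return IntensityCalibration(occurrence=occurrence, hf_count=hf_count)


def _predict(image, calibration, params) -> tuple[np.ndarray, tuple[slice, slice] | None]:
    pre = preprocess(image, params)
    prob_crop = calibration.probability[pre]
    if params.crop_to is None:
        return prob_crop, None
    return prob_crop, _center_crop_slices(np.asarray(image).shape, params.crop_to)


def predict_hf_probability(image: np.ndarray, calibration: IntensityCalibration,
                           params: PreprocessParams | None = None) -> np.ndarray:
    """Per-pixel p(I) in the original frame (cropped border = 0)."""
    params = params or PreprocessParams()
    prob_crop, slices = _predict(image, calibration, params)
    if slices is None:
        return prob_crop
    out = np.zeros(np.asarray(image).shape, dtype=float)
    out[slices] = prob_crop
    return out


def predict_hf(image: np.ndarray, calibration: IntensityCalibration,
               mu_he: float = 0.07,
               params: PreprocessParams | None = None) -> np.ndarray:
    """Binary HF mask: foreground where ``p(I) >= mu_he`` inside the crop.

    The output is re-embedded into the original frame with the cropped
    border set to background, so masks from this baseline compare
    directly against full-frame annotations.
    """
    params = params or PreprocessParams()
    prob_crop, slices = _predict(image, calibration, params)
    fg = prob_crop >= mu_he
    if slices is None:
        return fg
    out = np.zeros(np.asarray(image).shape, dtype=bool)
    out[slices] = fg
    return out


class IntensityCalibrationPredictor:
    """The calibration baseline wrapped in the ensemble predictor contract.

    ``fit`` learns the p(I) table from (image, mask) pairs; ``predict``
    returns the per-pixel probability map.  Deterministic given the
    fitted state.
    """

    def __init__(self, params: PreprocessParams | None = None) -> None:
        self.params = params or PreprocessParams()
        self.calibration: IntensityCalibration | None = None

    def fit(self, images: Sequence[np.ndarray], masks: Sequence[np.ndarray]) -> "IntensityCalibrationPredictor":
        self.calibration = fit_intensity_calibration(images, masks, self.params)
        return self

    def predict(self, image: np.ndarray) -> np.ndarray:
        if self.calibration is None:
            raise RuntimeError("predictor is not fitted")
        return predict_hf_probability(image, self.calibration, self.params)
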