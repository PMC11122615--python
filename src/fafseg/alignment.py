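"""Alignment of fine annotations with coarse ones via morphological closing.

Fine, pixel-accurate lesion outlines are made comparable to coarse
annotations by closing each mask with a square structuring element, which
fills small gaps and connects nearby fragments the way a coarse rater
would sweep over them.  Closing may make the hyperfluorescence (HF) and
reduced-autofluorescence (RA) masks overlap; any such conflict pixel is
assigned to HF.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage


@dataclasses.dataclass
class AnnotationPair:
    """One rater's HF and RA masks on a shared grid (disjoint after alignment)."""

    hf: np.ndarray
    ra: np.ndarray

    def __post_init__(self) -> None:
        self.hf = np.asarray(self.hf).astype(bool)
        self.ra = np.asarray(self.ra).astype(bool)
        if self.hf.shape != self.ra.shape:
            raise ValueError(f"grid mismatch: hf {self.hf.shape} vs ra {self.ra.shape}")


def morphological_closing(mask, kernel_px: int = 15) -> np.ndarray:
    """Binary closing with a square kernel, padding with background.

    The input is zero-padded by the kernel size before dilation/erosion so
    that the image border never generates spurious foreground, then
    cropped back.  Closing is extensive (output contains the input) and
    idempotent.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be odd and >= 1")
    mask = np.asarray(mask).astype(bool)
    if kernel_px == 1:
        return mask.copy()
    structure = np.ones((kernel_px, kernel_px), dtype=bool)
    pad = kernel_px
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=structure), structure=structure
    )
    return closed[pad:-pad, pad:-pad]


def align_fine_annotation(pair: AnnotationPair, kernel_px: int = 15) -> AnnotationPair:
    """Close both masks, then resolve HF/RA conflicts in favor of HF.

    Both masks are closed independently first; a pixel foreground in both
    closed masks ends up in the HF mask only, so the output masks are
    always disjoint.
    """
    hf = morphological_closing(pair.hf, kernel_px)
    ra = morphological_closing(pair.ra, kernel_px)
    ra &= ~hf
    return AnnotationPair(hf=hf, ra=ra)
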