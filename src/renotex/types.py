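"""Shared domain types used across the pipeline.

A *GrayImage* is simply a 2-D ``numpy`` array of 8-bit intensities; helper
validation lives here so every module agrees on what counts as a valid image.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class ClassLabel(str, Enum):
    """Disease severity class of one kidney image.

    Three admissible values: healthy kidneys, mild & moderate chronic kidney
    disease (CKD), and severe CKD.
    """

    NORMAL = "normal"
    MILD_MODERATE = "mild_moderate"
    SEVERE = "severe"


#: Canonical class ordering used for feature tables, confusion matrices and
#: network outputs.
CLASS_ORDER: tuple[ClassLabel, ...] = (
    ClassLabel.NORMAL,
    ClassLabel.MILD_MODERATE,
    ClassLabel.SEVERE,
)

#: Canonical ROI names, in feature-vector order.
ROI_NAMES: tuple[str, ...] = ("cortex", "boundary", "medulla")


@dataclass(frozen=True)
class ROISpec:
    """A square region-of-interest window inside a grayscale image.

    Coordinates are 0-based; the window covers the half-open ranges
    ``[top_row, top_row + side)`` x ``[left_col, left_col + side)``.
    """

    name: str
    top_row: int
    left_col: int
    side: int = 50

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValueError(f"unknown ROI name {self.name!r}; expected one of {ROI_NAMES}")
        if self.side < 2:
            raise ValueError(f"ROI side must be >= 2, got {self.side}")
        if self.top_row < 0 or self.left_col < 0:
            raise ValueError("ROI coordinates must be nonnegative")

    def crop(self, img: np.ndarray) -> np.ndarray:
        """Extract the window from ``img``; raises if it falls outside."""
        img = as_gray_image(img)
        r1 = self.top_row + self.side
        c1 = self.left_col + self.side
        if r1 > img.shape[0] or c1 > img.shape[1]:
            raise ValueError(
                f"ROI {self.name!r} [{self.top_row}:{r1}, {self.left_col}:{c1}] "
                f"exceeds image of shape {img.shape}"
            )
        return img[self.top_row:r1, self.left_col:c1]

    def overlaps(self, other: "ROISpec") -> bool:
        return not (
            self.top_row + self.side <= other.top_row
            or other.top_row + other.side <= self.top_row
            or self.left_col + self.side <= other.left_col
            or other.left_col + other.side <= self.left_col
        )


def as_gray_image(img: np.ndarray) -> np.ndarray:
    """Validate and return ``img`` as a 2-D integer array in [0, 255]."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2-D image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("gray image must hold integer intensities")
        arr = np.round(arr).astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("gray image intensities must lie in [0, 255]")
    return arr
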