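"""ROI preprocessing: histogram equalization followed by a local range filter.

Both operators are standard B-mode preprocessing steps: equalization spreads
the intensity histogram over the full dynamic range, and the range filter
(max minus min over a sliding window) responds to local contrast, which
highlights tissue boundaries while flattening homogeneous speckle regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import as_gray_image


@dataclass(frozen=True)
class PreprocessConfig:
    """Which preprocessing stages run, and their parameters.

    The cascade order is fixed: equalization first, then the range filter.
    ``levels`` is the output gray-level count of equalization; ``window`` is
    the (odd) side of the range-filter neighborhood.
    """

    equalize: bool = True
    range_filter: bool = True
    levels: int = 256
    window: int = 3

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")

    def to_dict(self) -> dict:
        return {
            "equalize": self.equalize,
            "range_filter": self.range_filter,
            "levels": self.levels,
            "window": self.window,
        }


def equalize_histogram(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Histogram-equalize an 8-bit image onto ``levels`` output levels.

    Uses the classical discrete mapping
    ``out(v) = round((cdf(v) - cdf_min) / (1 - cdf_min) * (levels - 1))``
    where ``cdf`` is the empirical cumulative histogram and ``cdf_min`` its
    smallest nonzero value.  A constant image maps to all zeros.  The mapping
    is monotone non-decreasing in the input intensity.
    """
    arr = as_gray_image(img)
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    counts = np.bincount(arr.ravel(), minlength=256)
    cdf = np.cumsum(counts) / arr.size
    cdf_min = cdf[np.nonzero(counts)[0][0]]
    if cdf_min >= 1.0:  # single occupied bin: degenerate histogram
        return np.zeros_like(arr, dtype=np.uint8 if levels <= 256 else np.int64)
    lut = np.round((cdf - cdf_min) / (1.0 - cdf_min) * (levels - 1))
    lut = np.clip(lut, 0, levels - 1)
    out = lut[arr]
    return out.astype(np.uint8 if levels <= 256 else np.int64)


def range_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Local range (max - min) over a ``window`` x ``window`` neighborhood.

    Borders use replicate padding, so a window centered at an edge pixel sees
    the nearest in-image values; this avoids spurious responses at ROI edges.
    """
    arr = as_gray_image(img)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    hi = ndimage.maximum_filter(arr, size=window, mode="nearest")
    lo = ndimage.minimum_filter(arr, size=window, mode="nearest")
    return (hi.astype(np.int64) - lo.astype(np.int64)).astype(np.uint8)


def preprocess_roi(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Apply the enabled preprocessing stages to one ROI window, in order."""
    if cfg is None:
        cfg = PreprocessConfig()
    out = as_gray_image(img)
    if cfg.equalize:
        out = equalize_histogram(out, cfg.levels)
    if cfg.range_filter:
        out = range_filter(out, cfg.window)
    return out
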