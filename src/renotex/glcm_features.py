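"""Gray-level co-occurrence matrices and the 19 second-order texture descriptors.

One descriptor vector is computed per ROI: the image is quantized to a small
number of gray levels, a co-occurrence matrix is built at each of the four
standard orientations (0, 45, 90, 135 degrees) at pixel distance ``d``, the 19
descriptors are evaluated per orientation, and the four vectors are averaged
element-wise.

Two descriptor *dialects* are provided because published formula tables for
this family are not uniform:

* ``as_printed`` — cluster prominence uses exponent 3 and cluster shade
  exponent 4, and the inverse-difference inner sum starts at the second
  column.
* ``classical_haralick`` — the conventional exponents (prominence 4,
  shade 3), inverse difference summed over the full matrix, and the square
  root applied in the second information measure of correlation.

All summation indices inside the formulas are 1-based gray levels
(``i, j`` in ``1..N``, ``k = i + j`` in ``2..2N``, ``k = |i - j|`` in
``0..N-1``); array storage is an implementation detail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import PreprocessConfig, preprocess_roi
from .types import ROISpec, as_gray_image

ANGLES_DEG: tuple[int, ...] = (0, 45, 90, 135)

# (row, col) displacement per unit distance for each orientation, following
# the prevailing image-processing convention (rows grow downward).
_DISPLACEMENTS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

#: Canonical ordering of the 19 descriptors.
FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "sum_of_squares_variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference",
)


@dataclass(frozen=True)
class OffsetSpec:
    """One co-occurrence displacement: an orientation plus a pixel distance."""

    angle_deg: int
    distance: int = 1

    def __post_init__(self) -> None:
        if self.angle_deg not in _DISPLACEMENTS:
            raise ValueError(f"angle must be one of {ANGLES_DEG}, got {self.angle_deg}")
        if self.distance < 1:
            raise ValueError(f"distance must be a positive integer, got {self.distance}")

    @property
    def displacement(self) -> tuple[int, int]:
        dr, dc = _DISPLACEMENTS[self.angle_deg]
        return dr * self.distance, dc * self.distance


@dataclass(frozen=True)
class FeatureConfig:
    """Choices left open by the descriptor family, pinned for reproducibility.

    ``n_levels``
        Number of quantization gray levels Ng (default 8, the common
        co-occurrence toolbox convention; 50x50 ROIs keep an 8x8 matrix
        well populated).
    ``symmetric``
        Count each pixel pair in both directions before normalizing.
    ``log_base``
        Base of every entropy term: ``natural`` or ``log2``.
    ``dialect``
        ``as_printed`` or ``classical_haralick`` (see module docstring).
    ``gray_limits``
        ``image_minmax`` stretches each ROI's own range over the bins;
        ``full_range`` always bins [0, 255].
    ``distance``
        Co-occurrence pixel distance d.
    """

    n_levels: int = 8
    symmetric: bool = True
    log_base: str = "natural"
    dialect: str = "as_printed"
    gray_limits: str = "image_minmax"
    distance: int = 1

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")
        if self.log_base not in ("natural", "log2"):
            raise ValueError(f"log_base must be 'natural' or 'log2', got {self.log_base!r}")
        if self.dialect not in ("as_printed", "classical_haralick"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.gray_limits not in ("image_minmax", "full_range"):
            raise ValueError(f"unknown gray_limits {self.gray_limits!r}")

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "symmetric": self.symmetric,
            "log_base": self.log_base,
            "dialect": self.dialect,
            "gray_limits": self.gray_limits,
            "distance": self.distance,
        }

    def _log(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.log(x) if self.log_base == "natural" else np.log2(x)


@dataclass(frozen=True)
class QuantizedImage:
    """A raster of 1-based gray levels in ``1..n_levels``."""

    levels: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.ndim != 2 or lv.size == 0:
            raise ValueError("quantized image must be a nonempty 2-D raster")
        if lv.min() < 1 or lv.max() > self.n_levels:
            raise ValueError("quantized levels must lie in [1, n_levels]")


@dataclass(frozen=True)
class GLCMatrix:
    """Co-occurrence counts and normalized probabilities for one offset."""

    counts: np.ndarray
    p: np.ndarray
    symmetric: bool
    offset: OffsetSpec

    @property
    def n_levels(self) -> int:
        return self.p.shape[0]


@dataclass(frozen=True)
class MarginalStats:
    """Every marginal quantity the descriptor formulas reference.

    ``px_plus_y`` is indexed by ``k = i + j`` (entries 0 and 1 unused);
    ``px_minus_y`` by ``k = |i - j|``.
    """

    px: np.ndarray
    py: np.ndarray
    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    px_plus_y: np.ndarray
    px_minus_y: np.ndarray
    mu_sum: float
    mu_diff: float
    hx: float
    hy: float
    hxy: float
    hxy1: float
    hxy2: float


@dataclass(frozen=True)
class FeatureVector19:
    """The 19 descriptors for one ROI, in canonical order."""

    autocorrelation: float
    contrast: float
    correlation: float
    cluster_prominence: float
    cluster_shade: float
    dissimilarity: float
    energy: float
    entropy: float
    homogeneity: float
    maximum_probability: float
    sum_of_squares_variance: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    difference_variance: float
    difference_entropy: float
    imc1: float
    imc2: float
    inverse_difference: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "FeatureVector19":
        values = np.asarray(values, dtype=float)
        if values.shape != (19,):
            raise ValueError(f"expected 19 values, got shape {values.shape}")
        return cls(**{name: float(v) for name, v in zip(FEATURE_NAMES, values)})

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}


assert tuple(f.name for f in fields(FeatureVector19)) == FEATURE_NAMES


def quantize(img: np.ndarray, cfg: FeatureConfig | None = None) -> QuantizedImage:
    """Linear-bin an 8-bit image into ``cfg.n_levels`` 1-based gray levels.

    With ``image_minmax`` limits a constant image maps entirely to level 1.
    """
    if cfg is None:
        cfg = FeatureConfig()
    arr = as_gray_image(img)
    if cfg.gray_limits == "full_range":
        lo, hi = 0, 255
    else:
        lo, hi = int(arr.min()), int(arr.max())
    n = cfg.n_levels
    if hi == lo:
        levels = np.ones_like(arr, dtype=np.int64)
    else:
        # equal-width bins over the inclusive integer range [lo, hi]
        levels = ((arr.astype(np.int64) - lo) * n) // (hi - lo + 1) + 1
        levels = np.clip(levels, 1, n)
    return QuantizedImage(levels=levels, n_levels=n)


class NoPairsError(ValueError):
    """The image has no in-bounds pixel pair for the requested offset."""


def build_glcm(q: QuantizedImage, offset: OffsetSpec, symmetric: bool = True) -> GLCMatrix:
    """Count co-occurring gray-level pairs at ``offset`` and normalize.

    Every in-bounds ordered pair (pixel, pixel + displacement) contributes one
    count; in symmetric mode the transposed counts are added before
    normalization, so the matrix equals its transpose.
    """
    lv = q.levels
    n = q.n_levels
    dr, dc = offset.displacement
    rows, cols = lv.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    if r0 >= r1 or c0 >= c1:
        raise NoPairsError(
            f"no valid pixel pairs in a {rows}x{cols} image for displacement ({dr}, {dc})"
        )
    a = lv[r0:r1, c0:c1].ravel() - 1
    b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel() - 1
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    if symmetric:
        counts = counts + counts.T
    p = counts / counts.sum()
    return GLCMatrix(counts=counts, p=p, symmetric=symmetric, offset=offset)


def _entropy(p: np.ndarray, cfg: FeatureConfig) -> float:
    """Shannon entropy with the 0·log 0 = 0 convention."""
    p = p[p > 0]
    return float(-(p * cfg._log(p)).sum()) if p.size else 0.0


def compute_marginals(g: GLCMatrix, cfg: FeatureConfig | None = None) -> MarginalStats:
    """Row/column/sum/difference marginals, their moments, and the entropies."""
    if cfg is None:
        cfg = FeatureConfig()
    p = g.p
    n = g.n_levels
    i = np.arange(1, n + 1, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    ii, jj = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    px_plus_y = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * n + 1)
    px_minus_y = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=n)
    k_sum = np.arange(px_plus_y.size, dtype=float)
    k_diff = np.arange(px_minus_y.size, dtype=float)
    mu_sum = float((k_sum * px_plus_y).sum())
    mu_diff = float((k_diff * px_minus_y).sum())

    hx = _entropy(px, cfg)
    hy = _entropy(py, cfg)
    hxy = _entropy(p.ravel(), cfg)
    pxpy = np.outer(px, py)
    pos = pxpy > 0
    log_pxpy = np.zeros_like(pxpy)
    log_pxpy[pos] = cfg._log(pxpy[pos])
    hxy1 = float(-(p[pos] * log_pxpy[pos]).sum())
    hxy2 = float(-(pxpy[pos] * log_pxpy[pos]).sum())
    return MarginalStats(
        px=px, py=py, mu_x=mu_x, mu_y=mu_y, var_x=var_x, var_y=var_y,
        px_plus_y=px_plus_y, px_minus_y=px_minus_y, mu_sum=mu_sum, mu_diff=mu_diff,
        hx=hx, hy=hy, hxy=hxy, hxy1=hxy1, hxy2=hxy2,
    )


def compute_features(
    g: GLCMatrix, m: MarginalStats | None = None, cfg: FeatureConfig | None = None
) -> FeatureVector19:
    """Evaluate all 19 descriptors on one normalized co-occurrence matrix.

    Degenerate conventions: correlation is 0 when either marginal variance is
    zero, and both information measures of correlation are 0 on a zero-entropy
    (single-cell) matrix.
    """
    if cfg is None:
        cfg = FeatureConfig()
    if m is None:
        m = compute_marginals(g, cfg)
    p = g.p
    n = g.n_levels
    ii, jj = np.meshgrid(
        np.arange(1, n + 1, dtype=float), np.arange(1, n + 1, dtype=float), indexing="ij"
    )
    mu = m.mu_x  # unsubscripted mean: standard reading (equals mu_y when symmetric)

    autocorrelation = float((ii * jj * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    sigma = math.sqrt(m.var_x * m.var_y)
    if sigma > 0:
        correlation = float(((ii - m.mu_x) * (jj - m.mu_y) * p).sum() / sigma)
    else:
        correlation = 0.0
    prom_exp, shade_exp = (3, 4) if cfg.dialect == "as_printed" else (4, 3)
    cluster_prominence = float(((ii + jj - 2 * mu) ** prom_exp * p).sum())
    cluster_shade = float(((ii + jj - 2 * mu) ** shade_exp * p).sum())
    dissimilarity = float((np.abs(ii - jj) * p).sum())
    energy = float((p**2).sum())
    entropy = m.hxy
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    maximum_probability = float(p.max())
    sum_of_squares_variance = float(((ii - mu) ** 2 * p).sum())
    k_sum = np.arange(m.px_plus_y.size, dtype=float)
    k_diff = np.arange(m.px_minus_y.size, dtype=float)
    sum_average = float((k_sum * m.px_plus_y).sum())
    sum_variance = float(((k_sum - m.mu_sum) ** 2 * m.px_plus_y).sum())
    sum_entropy = _entropy(m.px_plus_y, cfg)
    difference_variance = float(((k_diff - m.mu_diff) ** 2 * m.px_minus_y).sum())
    difference_entropy = _entropy(m.px_minus_y, cfg)

    if m.hxy <= 0.0:
        imc1 = 0.0
        imc2 = 0.0
    else:
        denom = max(m.hx, m.hy)
        imc1 = float((m.hxy - m.hxy1) / denom) if denom > 0 else 0.0
        core = 1.0 - math.exp(-2.0 * (m.hxy2 - m.hxy))
        imc2 = core if cfg.dialect == "as_printed" else math.sqrt(max(0.0, core))

    inv_mask = jj >= 2 if cfg.dialect == "as_printed" else np.ones_like(jj, dtype=bool)
    inverse_difference = float((p[inv_mask] / (1.0 + np.abs(ii - jj)[inv_mask])).sum())

    return FeatureVector19(
        autocorrelation=autocorrelation,
        contrast=contrast,
        correlation=correlation,
        cluster_prominence=cluster_prominence,
        cluster_shade=cluster_shade,
        dissimilarity=dissimilarity,
        energy=energy,
        entropy=entropy,
        homogeneity=homogeneity,
        maximum_probability=maximum_probability,
        sum_of_squares_variance=sum_of_squares_variance,
        sum_average=sum_average,
        sum_variance=sum_variance,
        sum_entropy=sum_entropy,
        difference_variance=difference_variance,
        difference_entropy=difference_entropy,
        imc1=imc1,
        imc2=imc2,
        inverse_difference=inverse_difference,
    )


def average_over_angles(vectors: Iterable[FeatureVector19]) -> FeatureVector19:
    """Element-wise arithmetic mean of exactly four per-orientation vectors."""
    vecs = list(vectors)
    if len(vecs) != 4:
        raise ValueError(f"expected exactly 4 per-angle vectors, got {len(vecs)}")
    stacked = np.stack([v.to_array() for v in vecs])
    return FeatureVector19.from_array(stacked.mean(axis=0))


def compute_roi_features(img: np.ndarray, fcfg: FeatureConfig | None = None) -> FeatureVector19:
    """Quantize a (preprocessed) window and angle-average the descriptors."""
    if fcfg is None:
        fcfg = FeatureConfig()
    q = quantize(img, fcfg)
    per_angle = []
    for angle in ANGLES_DEG:
        g = build_glcm(q, OffsetSpec(angle, fcfg.distance), fcfg.symmetric)
        per_angle.append(compute_features(g, cfg=fcfg))
    return average_over_angles(per_angle)


def extract_roi_features(
    img: np.ndarray,
    roi: ROISpec,
    pcfg: PreprocessConfig | None = None,
    fcfg: FeatureConfig | None = None,
) -> FeatureVector19:
    """Full per-ROI chain: crop, preprocess, quantize, four GLCMs, average."""
    window = roi.crop(img)
    window = preprocess_roi(window, pcfg)
    return compute_roi_features(window, fcfg)
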