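"""Intensity standardization and augmentation for MR slices.

MR intensities carry no standard scale: the same tissue lands at different
grey values in different scans (the white-matter peak drifts between
acquisitions).  Piece-wise linear histogram matching fixes this by learning
a standard scale — the mean of chosen intensity percentiles (landmarks)
over a training set — and mapping each scan's own landmarks onto it.  The
background peak at zero is excluded throughout: percentiles, z-scoring and
the standardization map act on foreground (positive) pixels only.

Rotation augmentation follows the +/-20 degree, 5-degree-step scheme:
nine orientations per slice including the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "StandardScale", "AugmentationPlan", "DEFAULT_ANGLES",
    "foreground_mask", "foreground_mode", "compute_landmarks",
    "fit_standard_scale", "standardize_image", "zscore_foreground",
    "augment_rotations",
]

DEFAULT_ANGLES = tuple(range(-20, 21, 5))  # -20 ... +20 in 5-degree steps


class DegenerateImageError(ValueError):
    """Raised when an image has no usable foreground intensity spread."""


def foreground_mask(image: np.ndarray) -> np.ndarray:
    """Foreground = strictly positive pixels (the zero peak is background)."""
    return np.asarray(image) > 0


@dataclass
class StandardScale:
    """Learned standard intensity landmarks for piece-wise linear mapping."""

    percentiles: list[float] = field(default_factory=lambda: [1.0, 99.0])
    landmarks: list[float] = field(default_factory=list)

    def __post_init__(self):
        p = np.asarray(self.percentiles, dtype=float)
        if p.size < 2 or (np.diff(p) <= 0).any() or p[0] <= 0 or p[-1] >= 100:
            raise ValueError("percentile ranks must be strictly increasing in (0, 100)")
        if self.landmarks:
            l = np.asarray(self.landmarks, dtype=float)
            if l.size != p.size or (np.diff(l) <= 0).any():
                raise ValueError("landmarks must be strictly increasing, one per percentile")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"percentiles": list(map(float, self.percentiles)),
                       "landmarks": list(map(float, self.landmarks))}, fh)

    @classmethod
    def from_json(cls, path) -> "StandardScale":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class AugmentationPlan:
    """Rotation schedule; the default is the nine-angle +/-20 degree sweep."""

    angles_deg: tuple = DEFAULT_ANGLES
    image_interpolation: str = "bilinear"
    mask_interpolation: str = "nearest"
    fill_value: float = 0.0

    def __post_init__(self):
        a = sorted(self.angles_deg)
        if 0 not in a:
            raise ValueError("angle list must include 0")
        if sorted(-x for x in a) != a:
            raise ValueError("angle list must be symmetric about 0")


def foreground_mode(image: np.ndarray, bw_method: float = 0.3) -> float:
    """Location of the dominant foreground intensity peak (the tissue peak
    of the two-peak MR density), estimated by a Gaussian KDE.

    A wide bandwidth keeps the estimate stable on the broad tissue peak;
    this is the statistic used to demonstrate that standardization brings
    the tissue peaks of differently scaled scans into register.
    """
    from scipy.stats import gaussian_kde

    fg = np.asarray(image, dtype=float)
    fg = fg[foreground_mask(fg)]
    if fg.size < 2:
        raise DegenerateImageError("foreground too small for a mode estimate")
    kde = gaussian_kde(fg, bw_method=bw_method)
    grid = np.linspace(fg.min(), fg.max(), 300)
    return float(grid[np.argmax(kde(grid))])


def compute_landmarks(image: np.ndarray, percentiles=(1.0, 99.0)) -> np.ndarray:
    """Percentiles of the foreground intensity distribution.

    Uses the linear-interpolation order-statistic convention
    (``numpy.percentile`` default).  Raises :class:`DegenerateImageError`
    for empty or constant foreground.
    """
    img = np.asarray(image, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    fg = img[foreground_mask(img)]
    if fg.size == 0 or np.unique(fg).size < 2:
        raise DegenerateImageError("foreground is empty or constant")
    lm = np.percentile(fg, percentiles)
    if (np.diff(lm) <= 0).any():
        raise DegenerateImageError("degenerate (non-increasing) landmarks")
    return lm


def fit_standard_scale(images, percentiles=(1.0, 99.0)) -> StandardScale:
    """Standard scale = per-landmark arithmetic mean over training images."""
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    lms = np.stack([compute_landmarks(im, percentiles) for im in images])
    return StandardScale(percentiles=list(map(float, percentiles)),
                         landmarks=list(map(float, lms.mean(axis=0))))


def standardize_image(image: np.ndarray, scale: StandardScale) -> np.ndarray:
    """Map the image's own landmarks onto the standard scale.

    Piece-wise linear between adjacent landmarks, linear extrapolation with
    the edge segment's slope beyond them.  Background zeros are untouched;
    the map is monotonically non-decreasing on the foreground.
    """
    img = np.asarray(image, dtype=float)
    own = compute_landmarks(img, scale.percentiles)
    std = np.asarray(scale.landmarks, dtype=float)
    mask = foreground_mask(img)
    vals = img[mask]
    out_vals = np.interp(vals, own, std)
    lo = vals < own[0]
    hi = vals > own[-1]
    if lo.any():
        slope = (std[1] - std[0]) / (own[1] - own[0])
        out_vals[lo] = std[0] + (vals[lo] - own[0]) * slope
    if hi.any():
        slope = (std[-1] - std[-2]) / (own[-1] - own[-2])
        out_vals[hi] = std[-1] + (vals[hi] - own[-1]) * slope
    out = np.zeros_like(img)
    out[mask] = out_vals
    return out


def zscore_foreground(image: np.ndarray,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean / unit-sd normalization on valued (foreground) pixels only.

    Uses the population standard deviation.  ``mask`` overrides the default
    positive-pixel foreground (useful after standardization, which can move
    individual foreground values across zero).
    """
    img = np.asarray(image, dtype=float)
    m = foreground_mask(img) if mask is None else np.asarray(mask, dtype=bool)
    fg = img[m]
    if fg.size == 0 or np.unique(fg).size < 2:
        raise DegenerateImageError("foreground is empty or constant")
    out = np.zeros_like(img)
    out[m] = (fg - fg.mean()) / fg.std()
    return out


def augment_rotations(image: np.ndarray, mask: np.ndarray,
                      plan: AugmentationPlan | None = None):
    """Rotate (image, mask) through the plan's angles.

    Images use bilinear interpolation, masks nearest-neighbour so they stay
    binary; out-of-frame areas are filled with the background value.  The
    default plan returns nine pairs, the 0-degree entry being the input
    itself.
    """
    plan = plan or AugmentationPlan()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    out = []
    for ang in plan.angles_deg:
        if ang == 0:
            out.append((image.copy(), mask.copy()))
            continue
        img_r = ndimage.rotate(image, ang, reshape=False, order=1,
                               mode="constant", cval=plan.fill_value)
        msk_r = ndimage.rotate(mask.astype(np.uint8), ang, reshape=False,
                               order=0, mode="constant", cval=0)
        out.append((img_r, msk_r.astype(mask.dtype)))
    return out
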