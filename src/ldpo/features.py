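"""Gradient-magnitude comparator map for blurred-junction detection.

The classical junction feature: the magnitude of the first-order intensity
derivative estimated inside a local 5x5x5 window.  A sharp gray/white
interface produces a steep gradient, a blurred one a gradual gradient, so
small values flag candidate lesions (polarity ``low_is_positive``).  Voxels
with intensity below 5 are treated as image background and excluded from
evaluations (``background_rule``).

The derivative estimator is an unweighted least-squares plane fit over the
window.  Because the window is a full centred cuboid the normal equations
diagonalize, and the fit reduces to a separable correlation with a ramp
kernel along each axis divided by the window's second moment; this makes the
estimator isotropic and cheap.  A plain central-difference estimator is
available via ``estimator="central"``.  Derivatives are per millimetre
(divided by the voxel spacing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .exceptions import DomainError, GeometryError
from .volume import Volume


@dataclass
class FeatureMap:
    """A scalar feature volume plus its evaluation conventions."""

    data: Volume
    feature_name: str
    polarity: str  # "high_is_positive" | "low_is_positive"
    background_rule: float | None = None  # exclude voxels with value < rule

    def __post_init__(self):
        if self.polarity not in ("high_is_positive", "low_is_positive"):
            raise DomainError(f"unknown polarity {self.polarity!r}")


def _lsq_gradient(data: np.ndarray, spacing, window: int) -> list[np.ndarray]:
    """Per-axis LSQ plane-fit slope over a centred window^3 cuboid, per mm."""
    half = window // 2
    ramp = np.arange(-half, half + 1, dtype=float)
    ones = np.ones(window)
    norm = (ramp ** 2).sum() * window * window
    grads = []
    for axis in range(3):
        g = data.astype(float)
        for ax2 in range(3):
            kern = ramp if ax2 == axis else ones
            g = correlate1d(g, kern, axis=ax2, mode="reflect")
        grads.append(g / (norm * spacing[axis]))
    return grads


def gradient_map(y: Volume, window: int = 5, estimator: str = "lsq") -> FeatureMap:
    """Gradient-magnitude feature map of an intensity volume.

    Near the volume faces the largest centred window that still fits is used
    (minimum 3; the outermost voxel layer falls back to a reflected window-3
    estimate).
    """
    if window < 3 or window % 2 == 0:
        raise DomainError(f"window must be an odd count >= 3, got {window}")
    if window > min(y.shape):
        raise GeometryError(
            f"window {window} exceeds the smallest image dimension {min(y.shape)}")
    data = np.asarray(y.data, dtype=float)
    if estimator == "central":
        gx = [np.gradient(data, y.spacing[a], axis=a) for a in range(3)]
        mag = np.sqrt(sum(g ** 2 for g in gx))
    elif estimator == "lsq":
        halves = list(range(1, window // 2 + 1))
        mags = {}
        for h in halves:
            g = _lsq_gradient(data, y.spacing, 2 * h + 1)
            mags[h] = np.sqrt(sum(c ** 2 for c in g))
        idx = np.indices(data.shape)
        dist = np.minimum.reduce(
            [np.minimum(idx[a], data.shape[a] - 1 - idx[a]) for a in range(3)])
        h_sel = np.clip(dist, 1, window // 2)
        mag = np.zeros_like(data)
        for h in halves:
            sel = h_sel == h
            mag[sel] = mags[h][sel]
    else:
        raise DomainError(f"unknown estimator {estimator!r}")
    vol = Volume(mag, y.spacing, y.affine.copy(), "intensity")
    return FeatureMap(vol, "gradient", "low_is_positive", background_rule=5.0)
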