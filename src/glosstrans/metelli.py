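"""Episcotister (Metelli) transparency model and image diagnostics.

A transparent layer is described by two numbers: its transmittance
``alpha`` (fraction of background luminance passed through) and its
reflectance ``t`` (the luminance the layer would show if it were fully
opaque).  A background pixel of luminance ``b`` seen through the layer has
luminance

    p = alpha * b + t * (1 - alpha)

i.e. a convex combination of the background and the layer's own
reflectance.  This module applies that mapping to luminance images and
computes the diagnostics used to characterise the filtered images:
Michelson contrast, luminance-histogram moments (including skewness, a
classical gloss correlate), and the fraction of pixels darkened by the
layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FilterSpec",
    "apply_filter",
    "rgb_to_luminance",
    "michelson_contrast",
    "histogram_stats",
    "fraction_darkened",
    "read_image",
    "write_image",
]

logger = logging.getLogger(__name__)

#: Grayscale conversion weights (ITU-R BT.601, as used by MATLAB's rgb2gray).
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass(frozen=True)
class FilterSpec:
    """A Metelli transparent layer.

    Parameters
    ----------
    t : float
        Reflectance of the layer when opaque, in [0, 1].
    alpha : float
        Transmittance of the layer, in [0, 1].  ``alpha = 1`` is a fully
        transmissive (invisible) layer; ``alpha = 0`` is opaque.
    """

    t: float
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= 1.0):
            raise ValueError(f"filter reflectance t must be in [0, 1], got {self.t}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"transmittance alpha must be in [0, 1], got {self.alpha}")


def _as_luminance(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("luminance image must be a non-empty 2-D array")
    if np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0:
        raise ValueError("luminance values must lie in [0, 1]")
    return arr


def _region(image: np.ndarray, region_mask: np.ndarray | None) -> np.ndarray:
    """Pixels of `image` selected by the (optional) boolean mask."""
    arr = _as_luminance(image)
    if region_mask is None:
        return arr.ravel()
    mask = np.asarray(region_mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("region mask shape must match the image shape")
    vals = arr[mask]
    if vals.size == 0:
        raise ValueError("region mask selects no pixels")
    return vals


def apply_filter(image: np.ndarray, filt: FilterSpec) -> np.ndarray:
    """Place a transparent layer in front of a luminance image.

    Each pixel ``b`` maps independently to ``alpha * b + t * (1 - alpha)``.
    The map sends [0, 1] into [0, 1]; the output is clipped defensively
    against floating-point drift.
    """
    arr = _as_luminance(image)
    out = filt.alpha * arr + filt.t * (1.0 - filt.alpha)
    return np.clip(out, 0.0, 1.0)


def rgb_to_luminance(rgb_image: np.ndarray) -> np.ndarray:
    """Convert an RGB image in [0, 1] to luminance.

    Uses the BT.601 weighted sum 0.2989 R + 0.5870 G + 0.1140 B.
    """
    arr = np.asarray(rgb_image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("rgb image must have shape (H, W, 3)")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("rgb values must lie in [0, 1]")
    wr, wg, wb = LUMA_WEIGHTS
    return wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]


def michelson_contrast(image: np.ndarray, region_mask: np.ndarray | None = None) -> float:
    """Michelson contrast (Lmax - Lmin) / (Lmax + Lmin) over a region.

    Returns 0 for a region with Lmax = Lmin = 0 (all black), with a
    logged warning, so that downstream summaries never see NaN.
    """
    vals = _region(image, region_mask)
    lmax = float(vals.max())
    lmin = float(vals.min())
    denom = lmax + lmin
    if denom == 0.0:
        logger.warning("michelson_contrast: all-black region, returning 0 by convention")
        return 0.0
    return (lmax - lmin) / denom


def histogram_stats(image: np.ndarray, region_mask: np.ndarray | None = None) -> dict:
    """Luminance-histogram moments over a region.

    Returns a dict with ``mean``, ``min``, ``max``, ``range`` and
    ``skewness``.  Skewness is the population (biased) standardized third
    central moment; a zero-variance region has skewness 0 by convention.
    """
    vals = _region(image, region_mask)
    mean = float(vals.mean())
    vmin = float(vals.min())
    vmax = float(vals.max())
    centred = vals - mean
    var = float(np.mean(centred**2))
    if var == 0.0:
        skew = 0.0
    else:
        skew = float(np.mean(centred**3) / var**1.5)
    return {"mean": mean, "min": vmin, "max": vmax, "range": vmax - vmin, "skewness": skew}


def fraction_darkened(before: np.ndarray, after: np.ndarray) -> float:
    """Fraction of pixels strictly darker in `after` than in `before`.

    Ties count as not darkened.  This is the "percentage of pixels getting
    darker" diagnostic for a layer's overall darkening/lightening effect.
    """
    b = _as_luminance(before)
    a = _as_luminance(after)
    if a.shape != b.shape:
        raise ValueError("images must have identical dimensions")
    return float(np.mean(a < b))


# ---------------------------------------------------------------------------
# Image I/O: 16-bit grayscale PNG or whitespace-delimited text matrix.

def write_image(path, image: np.ndarray) -> None:
    arr = _as_luminance(image)
    path = str(path)
    if path.endswith(".png"):
        import imageio.v3 as iio

        iio.imwrite(path, np.round(arr * 65535.0).astype(np.uint16))
    else:
        np.savetxt(path, arr, fmt="%.8f")


def read_image(path) -> np.ndarray:
    path = str(path)
    if path.endswith(".png"):
        import imageio.v3 as iio

        raw = iio.imread(path)
        if raw.ndim == 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw = raw[..., :3]
            return rgb_to_luminance(raw.astype(float) / float(np.iinfo(raw.dtype).max))
        return raw.astype(float) / float(np.iinfo(raw.dtype).max)
    return _as_luminance(np.loadtxt(path))
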