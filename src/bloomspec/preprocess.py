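"""Noise suppression and bright-light masking ahead of feature extraction.

Low-altitude water imagery carries impulse noise from the sensor and small
saturated glint spots where the sun reflects off the surface.  Two defences
run before any index is computed: a two-stage adaptive median filter per band,
and a brightness mask that removes glint pixels from all downstream analysis.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .raster_io import MultispectralScene

logger = logging.getLogger(__name__)

__all__ = ["PreprocessConfig", "adaptive_median_filter", "light_mask", "preprocess_scene"]


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing stage.

    Attributes
    ----------
    max_filter_window
        Largest (odd) window side the adaptive median filter may grow to.
    light_quantile
        Quantile of the visible-band mean brightness above which pixels are
        masked when no absolute threshold is given.  The default 0.995 targets
        small glint spots without eating into legitimately bright classes.
    light_abs_threshold
        Absolute reflectance threshold for the light mask; overrides the
        quantile rule when set.
    """

    max_filter_window: int = 7
    light_quantile: float = 0.995
    light_abs_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.max_filter_window < 3 or self.max_filter_window % 2 == 0:
            raise ValueError(
                f"max_filter_window must be odd and >= 3, got {self.max_filter_window}"
            )
        if not 0.0 < self.light_quantile <= 1.0:
            raise ValueError(f"light_quantile must be in (0, 1], got {self.light_quantile}")


def adaptive_median_filter(band: np.ndarray, max_window: int = 7) -> np.ndarray:
    """Two-stage adaptive median filter (Gonzalez–Woods).

    Per pixel, the window grows from 3x3 until the window median lies strictly
    between the window minimum and maximum, or ``max_window`` is reached.  The
    centre pixel is kept if it is itself strictly between the window extremes
    (not an impulse); otherwise it is replaced by the window median.  Borders
    use reflected padding.

    Parameters
    ----------
    band
        2-D image.
    max_window
        Odd maximum window side, >= 3 and <= min(height, width).
    """
    band = np.asarray(band, dtype=np.float64)
    if band.ndim != 2:
        raise ValueError(f"band must be 2-D, got shape {band.shape}")
    if max_window % 2 == 0 or max_window < 3:
        raise ValueError(f"max_window must be odd and >= 3, got {max_window}")
    if max_window > min(band.shape):
        raise ValueError(
            f"max_window {max_window} exceeds image side {min(band.shape)}"
        )

    windows = list(range(3, max_window + 1, 2))
    meds = np.stack([ndimage.median_filter(band, size=w, mode="reflect") for w in windows])
    mins = np.stack([ndimage.minimum_filter(band, size=w, mode="reflect") for w in windows])
    maxs = np.stack([ndimage.maximum_filter(band, size=w, mode="reflect") for w in windows])

    good = (mins < meds) & (meds < maxs)  # stage A success per window size
    # smallest window whose median is not an impulse; fall back to the largest
    first = np.argmax(good, axis=0)
    any_good = good.any(axis=0)
    first = np.where(any_good, first, len(windows) - 1)

    ii, jj = np.indices(band.shape)
    med = meds[first, ii, jj]
    lo = mins[first, ii, jj]
    hi = maxs[first, ii, jj]

    keep_centre = (lo < band) & (band < hi)  # stage B: centre not an impulse
    return np.where(keep_centre, band, med)


def light_mask(scene: MultispectralScene, config: PreprocessConfig) -> np.ndarray:
    """Boolean mask of bright-light (glint) pixels; ``True`` = masked.

    Brightness is the mean reflectance of the visible bands B1–B3.  A pixel is
    masked when that mean exceeds ``light_abs_threshold`` if given, otherwise
    when it exceeds the ``light_quantile`` quantile of the brightness values
    over currently-valid pixels.
    """
    vis = (scene.bands["B1"] + scene.bands["B2"] + scene.bands["B3"]) / 3.0
    if config.light_abs_threshold is not None:
        thresh = float(config.light_abs_threshold)
        mask = vis > thresh
    else:
        pool = vis[scene.valid_mask] if scene.valid_mask is not None else vis
        thresh = float(np.quantile(pool, config.light_quantile))
        mask = vis > thresh
    if mask.all():
        logger.warning("light mask covers the entire scene (threshold %.4g)", thresh)
    return mask


def preprocess_scene(
    scene: MultispectralScene, config: PreprocessConfig | None = None
) -> MultispectralScene:
    """Filter every band and fold the light mask into the validity mask.

    Masked pixels are *kept* in the raster (no inpainting) but marked invalid,
    which maps them to the ignore class in training, evaluation and grading.
    """
    config = config or PreprocessConfig()
    filtered = {
        b: np.clip(adaptive_median_filter(g, config.max_filter_window), 0.0, 1.0)
        for b, g in scene.bands.items()
    }
    clean = MultispectralScene(bands=filtered, valid_mask=scene.valid_mask)
    bright = light_mask(clean, config)
    return clean.with_mask(~bright)
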