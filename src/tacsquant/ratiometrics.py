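"""Masked ratiometric SHG measures.

Two readouts of collagen microstructure:

* **Normalized B_SHG** — backward SHG intensity per unit collagen I protein.
  The collagen I IF projection is thresholded to select collagen-positive
  features; the backward-SHG channel is masked to the same pixel set, and the
  metric is mean(B_SHG | mask) / mean(IF | mask). Because both means run over
  the identical pixels, the ratio tracks SHG conversion efficiency rather
  than collagen abundance.

* **F/B ratio** — forward/backward SHG, sensitive to sub-resolution fibril
  diameter and packing. The background-subtracted channels are divided
  pixelwise; sub-threshold (non-fiber) pixels are excluded by a binary mask
  built from the backward-SHG channel, and the metric is the pixel-weighted
  mean of the ratio over that mask.

The same thresholding standard (a fixed quantile or a fixed absolute value)
is applied to every image of every group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .stacks import Channel, ProjectedImage

logger = logging.getLogger(__name__)

#: excitation wavelength of the two-photon source, nm
EXCITATION_NM = 810.0
#: center of the backward-SHG emission filter, nm
BSHG_FILTER_CENTER_NM = 405.0


def shg_emission_nm(excitation_nm: float = EXCITATION_NM) -> float:
    """SHG emission wavelength: two excitation photons combine into one at
    half the wavelength."""
    if excitation_nm <= 0:
        raise ValueError("excitation wavelength must be positive")
    return excitation_nm / 2.0


class EmptyMaskWarning(UserWarning):
    """Issued when a threshold mask selects no pixels; the metric is absent."""


@dataclass
class BinaryMask:
    """Pixel-selection mask with provenance."""

    pixels: np.ndarray
    threshold_used: float
    source_channel: Channel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.source_channel = Channel(self.source_channel)

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())


@dataclass
class ChannelPairMetrics:
    """Per-FOV scalar metrics; a metric is None when its mask was empty or
    its channel missing."""

    fov_id: str
    group: str
    animal: str
    n_if_mask_pixels: int = 0
    n_fb_mask_pixels: int = 0
    normalized_bshg: Optional[float] = None
    mean_fb_ratio: Optional[float] = None
    mean_if: Optional[float] = None
    mean_coherency: Optional[float] = None


def threshold_mask(image: ProjectedImage, threshold: float) -> BinaryMask:
    """Strictly-greater-than threshold mask."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return BinaryMask(
        pixels=image.pixels > threshold,
        threshold_used=float(threshold),
        source_channel=image.channel,
    )


def resolve_threshold(image: ProjectedImage, mode: str) -> float:
    """Threshold value from a mode string: ``quantile:<q>`` or ``fixed:<v>``.

    The quantile mode (default 0.95 in the pipeline) applies one standard to
    all images; the fixed mode applies one absolute value to all images.
    """
    kind, _, arg = mode.partition(":")
    if kind == "quantile":
        q = float(arg) if arg else 0.95
        if not 0.0 <= q < 1.0:
            raise ValueError("quantile must lie in [0, 1)")
        return float(np.quantile(image.pixels, q))
    if kind == "fixed":
        v = float(arg)
        if v < 0:
            raise ValueError("fixed threshold must be non-negative")
        return v
    raise ValueError(f"unknown threshold mode {mode!r}")


def normalized_bshg(
    bshg: ProjectedImage,
    ifimg: ProjectedImage,
    mask: BinaryMask,
) -> Optional[float]:
    """mean(B_SHG | mask) / mean(IF | mask) over the identical pixel set.

    Returns None (with an EmptyMaskWarning) if the mask is empty; raises if
    the masked IF mean is zero (undefined ratio).
    """
    if bshg.shape != ifimg.shape or mask.pixels.shape != ifimg.shape:
        raise ValueError("B_SHG, IF and mask shapes must match")
    if mask.n_true == 0:
        warnings.warn("empty collagen mask; normalized B_SHG undefined", EmptyMaskWarning)
        logger.warning("empty collagen mask; normalized B_SHG absent")
        return None
    mean_if = float(ifimg.pixels[mask.pixels].mean())
    if mean_if == 0.0:
        raise ZeroDivisionError("masked IF mean is zero; normalized B_SHG undefined")
    mean_b = float(bshg.pixels[mask.pixels].mean())
    return mean_b / mean_if


def fb_ratio(
    fshg: ProjectedImage,
    bshg: ProjectedImage,
    mask: BinaryMask,
) -> Tuple[np.ndarray, Optional[float]]:
    """Pixelwise F/B ratio image over the mask, plus its pixel-weighted mean.

    The ratio image is NaN outside the mask so that downstream means cannot
    silently include non-fiber pixels. The mask must have been built so that
    B_SHG > 0 at every selected pixel; a zero denominator inside the mask is
    a mask-construction bug and raises.
    """
    if fshg.shape != bshg.shape or mask.pixels.shape != bshg.shape:
        raise ValueError("F_SHG, B_SHG and mask shapes must match")
    ratio = np.full(bshg.shape, np.nan)
    if mask.n_true == 0:
        warnings.warn("empty fiber mask; F/B ratio undefined", EmptyMaskWarning)
        logger.warning("empty fiber mask; mean F/B absent")
        return ratio, None
    b = bshg.pixels[mask.pixels]
    if np.any(b == 0.0):
        raise ValueError("B_SHG is zero inside the fiber mask; mask must exclude zero-denominator pixels")
    ratio[mask.pixels] = fshg.pixels[mask.pixels] / b
    return ratio, float(ratio[mask.pixels].mean())


def compute_pair_metrics(
    ifimg: ProjectedImage,
    bshg: ProjectedImage,
    fshg: Optional[ProjectedImage],
    *,
    if_threshold_mode: str = "quantile:0.95",
    fb_threshold_mode: str = "quantile:0.95",
    fov_id: str = "",
    group: str = "",
    animal: str = "",
) -> ChannelPairMetrics:
    """Both ratiometric metrics for one FOV from background-corrected
    projections.

    The IF-derived mask gates normalized B_SHG; the B_SHG-derived mask gates
    the F/B analysis. The two masks are never interchanged.
    """
    if_mask = threshold_mask(ifimg, resolve_threshold(ifimg, if_threshold_mode))
    nb = normalized_bshg(bshg, ifimg, if_mask)

    mean_fb: Optional[float] = None
    n_fb = 0
    if fshg is not None:
        fb_mask = threshold_mask(bshg, resolve_threshold(bshg, fb_threshold_mode))
        n_fb = fb_mask.n_true
        _, mean_fb = fb_ratio(fshg, bshg, fb_mask)

    return ChannelPairMetrics(
        fov_id=fov_id,
        group=group,
        animal=animal,
        n_if_mask_pixels=if_mask.n_true,
        n_fb_mask_pixels=n_fb,
        normalized_bshg=nb,
        mean_fb_ratio=mean_fb,
        mean_if=float(ifimg.pixels.mean()),
    )
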