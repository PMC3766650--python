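"""Structure-tensor coherency analysis of fiber organization.

The local orientation content of an image I(y, x) is summarized by the
structure tensor

    J = W * [[gx*gx, gx*gy],
             [gx*gy, gy*gy]]

where gx, gy are Gaussian-derivative gradients and W is a smoothing window
(Gaussian by default, optionally uniform). The coherency at a pixel is the
normalized eigenvalue spread of J,

    C = (lam_max - lam_min) / (lam_max + lam_min),

which is 1 for perfectly oriented local structure (rank-1 tensor) and 0 for
isotropy. The image-level statistic is the arithmetic mean of C over all
pixels. Pixels whose tensor trace is numerically zero (flat regions) carry no
orientation and are assigned C = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .stacks import ProjectedImage

#: relative trace cutoff below which a tensor is treated as orientation-free
ZERO_TRACE_REL_EPS = 1e-12


@dataclass
class StructureTensorField:
    """Window-smoothed structure tensor components of one image."""

    jxx: np.ndarray
    jxy: np.ndarray
    jyy: np.ndarray
    gradient_sigma_px: float
    window_sigma_px: float
    window: str = "gaussian"
    window_size_px: Optional[int] = None

    @property
    def shape(self) -> tuple:
        return self.jxx.shape

    def interior_margin_px(self) -> int:
        """Border width affected by filter support: 3*(sigma_g + window scale)."""
        if self.window == "uniform":
            w_scale = (self.window_size_px or 0) / 2.0
        else:
            w_scale = self.window_sigma_px
        return int(np.ceil(3.0 * (self.gradient_sigma_px + w_scale)))


@dataclass
class CoherencyMap:
    """Per-pixel coherency in [0, 1] plus its all-pixel mean."""

    c: np.ndarray
    mean_c: float
    n_pixels: int
    gradient_sigma_px: float
    window_sigma_px: float


def gaussian_kernel1d(sigma: float, order: int = 0, truncate: float = 4.0) -> np.ndarray:
    """Sampled Gaussian (order 0, normalized to unit sum) or its first
    derivative (order 1) on a symmetric support of ``truncate`` sigmas."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        return g * (-x / sigma ** 2)
    raise ValueError("only order 0 or 1 supported")


def _sep_correlate(image: np.ndarray, ky: np.ndarray, kx: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(image, ky, axis=0, mode="reflect")
    return ndimage.correlate1d(out, kx, axis=1, mode="reflect")


def structure_tensor(
    image: Union[ProjectedImage, np.ndarray],
    gradient_sigma_px: float = 1.0,
    window_sigma_px: float = 2.0,
    *,
    window: str = "gaussian",
    window_size_px: Optional[int] = None,
) -> StructureTensorField:
    """Compute the window-smoothed structure tensor of a 2-D image.

    Parameters
    ----------
    image
        2-D array or ProjectedImage; at least 16x16 and no smaller than
        4*(gradient_sigma + window scale) on either axis.
    gradient_sigma_px
        Scale of the Gaussian-derivative gradient estimator.
    window_sigma_px
        Scale of the Gaussian tensor-smoothing window (ignored when
        ``window="uniform"``).
    window
        ``"gaussian"`` (default) or ``"uniform"``; the uniform window averages
        over a ``window_size_px`` square box, useful when the window must span
        an exact integer number of structure periods.

    Boundaries are handled by reflection.
    """
    pixels = image.pixels if isinstance(image, ProjectedImage) else np.asarray(image, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("structure_tensor expects a 2-D image")
    if gradient_sigma_px <= 0:
        raise ValueError("gradient_sigma_px must be positive")
    if window == "gaussian":
        if window_sigma_px <= 0:
            raise ValueError("window_sigma_px must be positive")
        w_scale = window_sigma_px
    elif window == "uniform":
        if not window_size_px or window_size_px < 1:
            raise ValueError("uniform window requires window_size_px >= 1")
        w_scale = window_size_px / 2.0
    else:
        raise ValueError(f"unknown window kind {window!r}")
    min_dim = min(pixels.shape)
    required = max(16, int(np.ceil(4.0 * (gradient_sigma_px + w_scale))))
    if min_dim < required:
        raise ValueError(
            f"image of shape {pixels.shape} too small for sigmas "
            f"(need at least {required} px per axis)"
        )

    g = gaussian_kernel1d(gradient_sigma_px, order=0)
    dg = gaussian_kernel1d(gradient_sigma_px, order=1)
    gx = _sep_correlate(pixels, g, dg)   # d/dx: derivative along columns
    gy = _sep_correlate(pixels, dg, g)   # d/dy: derivative along rows

    def smooth(a: np.ndarray) -> np.ndarray:
        if window == "uniform":
            return ndimage.uniform_filter(a, size=window_size_px, mode="reflect")
        k = gaussian_kernel1d(window_sigma_px, order=0)
        return _sep_correlate(a, k, k)

    return StructureTensorField(
        jxx=smooth(gx * gx),
        jxy=smooth(gx * gy),
        jyy=smooth(gy * gy),
        gradient_sigma_px=gradient_sigma_px,
        window_sigma_px=window_sigma_px if window == "gaussian" else 0.0,
        window=window,
        window_size_px=window_size_px,
    )


def coherency_map(field: StructureTensorField) -> CoherencyMap:
    """Per-pixel coherency from the tensor eigenvalue spread.

    Uses the closed form C = sqrt((jxx - jyy)^2 + 4 jxy^2) / (jxx + jyy),
    identical to the eigen-decomposition ratio for a symmetric 2x2 tensor.
    Pixels with trace <= eps (relative to the max trace) are set to C = 0.
    """
    trace = field.jxx + field.jyy
    spread = np.sqrt((field.jxx - field.jyy) ** 2 + 4.0 * field.jxy ** 2)
    eps = ZERO_TRACE_REL_EPS * max(float(trace.max(initial=0.0)), np.finfo(np.float64).tiny)
    c = np.zeros_like(trace)
    ok = trace > eps
    c[ok] = spread[ok] / trace[ok]
    c = np.clip(c, 0.0, 1.0)
    return CoherencyMap(
        c=c,
        mean_c=float(c.mean()),
        n_pixels=int(c.size),
        gradient_sigma_px=field.gradient_sigma_px,
        window_sigma_px=field.window_sigma_px,
    )


def mean_coherency(cmap: CoherencyMap, mask: Optional[np.ndarray] = None) -> float:
    """Arithmetic mean of C over all pixels (default) or over a mask.

    The all-pixel mean, background included, is the image-level statistic; the
    mask variant is an extension for restricted regions of interest.
    """
    if mask is None:
        return cmap.mean_c
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cmap.c.shape:
        raise ValueError("mask shape does not match coherency map")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return float(cmap.c[mask].mean())


def interior_mask(shape: tuple, margin_px: int) -> np.ndarray:
    """Boolean mask excluding a border of ``margin_px`` on every side."""
    if 2 * margin_px >= min(shape):
        raise ValueError("margin leaves no interior pixels")
    m = np.zeros(shape, dtype=bool)
    m[margin_px : shape[0] - margin_px, margin_px : shape[1] - margin_px] = True
    return m


def render_hsb(
    image: Union[ProjectedImage, np.ndarray],
    cmap: CoherencyMap,
    hue: float = 0.0,
) -> np.ndarray:
    """Hue-Saturation-Brightness coherency overlay.

    H is constant, S is the coherency, and B is the original image rescaled to
    [0, 1] by its maximum, so bright saturated hue marks ordered, bright
    structure. Returns a float RGB array of shape (H, W, 3).
    """
    pixels = image.pixels if isinstance(image, ProjectedImage) else np.asarray(image, dtype=np.float64)
    if pixels.shape != cmap.c.shape:
        raise ValueError("image and coherency map shapes differ")
    if not 0.0 <= hue <= 1.0:
        raise ValueError("hue must lie in [0, 1]")
    peak = pixels.max(initial=0.0)
    brightness = pixels / peak if peak > 0 else np.zeros_like(pixels)
    hsv = np.stack([np.full_like(brightness, hue), cmap.c, brightness], axis=-1)
    return hsv_to_rgb(hsv)
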