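"""TIFF z-stack I/O and preprocessing.

The acquisition model: each field of view (FOV) is imaged as a z-stack per
detection channel (collagen I immunofluorescence, backward SHG, forward SHG).
Stacks are collapsed by per-pixel maximum intensity projection, and a scalar
background — the mean pixel count of a laser-excited blank-slide image — is
subtracted from each projection, clipping at zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile


class Channel(str, enum.Enum):
    """Detection channel of a stack or image."""

    IF = "IF"          # collagen I immunofluorescence
    BSHG = "BSHG"      # backward (epi-detected) second harmonic generation
    FSHG = "FSHG"      # forward (trans-detected) second harmonic generation
    BLANK = "BLANK"    # blank-slide / closed-shutter background acquisition


class StackFormatError(ValueError):
    """Raised when a TIFF does not encode a single-channel grayscale z-stack."""


@dataclass
class ZStack:
    """A 3-D intensity volume (z, y, x) for one channel of one FOV.

    Voxel values are non-negative finite reals; integer TIFF encodings are
    converted losslessly on read.
    """

    voxels: np.ndarray
    channel: Channel
    pixel_size_um: float
    z_step_um: float
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError(f"voxels must be 3-D (z, y, x) with z >= 1, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        if np.any(self.voxels < 0):
            raise ValueError("voxels contain negative values")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")
        self.channel = Channel(self.channel)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class ProjectedImage:
    """A 2-D maximum projection, optionally background-corrected."""

    pixels: np.ndarray
    channel: Channel
    pixel_size_um: float
    background_value: Optional[float] = None
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("pixels contain negative values")
        if self.background_subtracted and self.background_value is None:
            raise ValueError("background_subtracted image must record background_value")
        self.channel = Channel(self.channel)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def read_stack(
    path: Union[str, Path],
    channel: Channel,
    pixel_size_um: float,
    z_step_um: float = 1.0,
) -> ZStack:
    """Read a single-channel multi-page grayscale TIFF as a ZStack.

    Raises
    ------
    StackFormatError
        If the file has zero pages, RGB/multi-sample pages, or is unreadable
        as TIFF.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) == 0:
                raise StackFormatError(f"{path}: TIFF has zero pages")
            for page in tif.pages:
                spp = page.samplesperpixel
                if spp is not None and spp != 1:
                    raise StackFormatError(
                        f"{path}: expected single-sample grayscale pages, got {spp} samples/pixel"
                    )
            data = tif.asarray()
    except StackFormatError:
        raise
    except Exception as exc:  # pragma: no cover - passthrough of tifffile errors
        raise StackFormatError(f"{path}: unreadable TIFF ({exc})") from exc
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise StackFormatError(f"{path}: expected 2-D or 3-D grayscale data, got shape {data.shape}")
    return ZStack(
        voxels=data.astype(np.float64),
        channel=channel,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        source_path=str(path),
    )


def write_stack(stack: ZStack, path: Union[str, Path]) -> None:
    """Write a ZStack as a multi-page grayscale 16-bit TIFF.

    Values are rounded to the nearest integer count (detector semantics) and
    must fall in [0, 65535]; integer-valued stacks round-trip exactly through
    ``read_stack``.
    """
    path = Path(path)
    rounded = np.round(stack.voxels)
    if rounded.max(initial=0.0) > 65535:
        raise ValueError("stack values exceed the 16-bit encoding range [0, 65535]")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, rounded.astype(np.uint16), photometric="minisblack")


def max_project(stack: ZStack) -> ProjectedImage:
    """Per-pixel maximum intensity projection across z."""
    return ProjectedImage(
        pixels=stack.voxels.max(axis=0),
        channel=stack.channel,
        pixel_size_um=stack.pixel_size_um,
    )


def estimate_background(blank: ProjectedImage) -> float:
    """Scalar background: the mean pixel count of a blank-slide projection."""
    if blank.pixels.size == 0:
        raise ValueError("cannot estimate background from an empty image")
    return float(blank.pixels.mean())


def subtract_background(image: ProjectedImage, background: float) -> ProjectedImage:
    """Subtract a scalar background, clipping negatives to zero."""
    if background < 0:
        raise ValueError("background must be non-negative")
    corrected = np.maximum(image.pixels - background, 0.0)
    return ProjectedImage(
        pixels=corrected,
        channel=image.channel,
        pixel_size_um=image.pixel_size_um,
        background_value=float(background),
        background_subtracted=True,
    )


def subtract_background_image(image: ProjectedImage, background: ProjectedImage) -> ProjectedImage:
    """Pixelwise background subtraction (closed-shutter projection path),
    clipping negatives to zero; records the background's mean as the scalar
    provenance value."""
    if background.shape != image.shape:
        raise ValueError("background image shape does not match")
    corrected = np.maximum(image.pixels - background.pixels, 0.0)
    return ProjectedImage(
        pixels=corrected,
        channel=image.channel,
        pixel_size_um=image.pixel_size_um,
        background_value=float(background.pixels.mean()),
        background_subtracted=True,
    )


def preprocess_stack(stack: ZStack, background: float) -> ProjectedImage:
    """Maximum-project then background-subtract in one step."""
    return subtract_background(max_project(stack), background)
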