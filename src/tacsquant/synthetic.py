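"""Synthetic two/three-channel fiber-scene generator.

Emulates collagen I organization at a mammary tumor boundary as seen by
simultaneous immunofluorescence (IF) and second harmonic generation (SHG)
microscopy. A scene is a field of straight fiber segments whose axial
orientations follow a von Mises law on the doubled angle (concentration
``orientation_kappa``; 0 = isotropic), superposed on an unoriented diffuse
speckle field carrying a prescribed fraction of the total collagen signal.

Channels are linked through the scene's ground truth:

* IF      = if_gain * (fibers + diffuse)
* B_SHG   = bshg_gain * (fibers + diffuse_bshg_weight * diffuse)
* F_SHG   = B_SHG * fb_gain, with fb_gain = fb_gain_per_um * local fiber
  width — forward emission grows with fibril diameter, so thick-fiber scenes
  have higher F/B ratios.

Two presets encode the study phenotypes: ``WT`` scenes have long, thick,
strongly co-oriented fibers (a taut, boundary-parallel TACS-2-like state);
``KO`` scenes have short, thin, weakly oriented fibers with a large diffuse
fraction, more total collagen signal, and higher SHG conversion per unit
collagen (a dense, disorganized TACS-1-like state).

z-structure is intensity-jittered replication of the in-focus plane (one
slice always carries the full signal), so maximum projection recovers the
noiseless scene exactly when noise is disabled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .stacks import Channel, ZStack

#: default lateral calibration: a 680 um field imaged at 512 px
DEFAULT_PIXEL_SIZE_UM = 680.0 / 512.0

#: nominal fiber area coverage used to scale a pure-diffuse scene (n_fibers=0)
_DIFFUSE_REFERENCE_COVERAGE = 0.02


class SceneParameterError(ValueError):
    """Raised when generator parameters are non-finite or out of range."""


@dataclass
class FiberSceneParams:
    """Controls for one synthetic FOV.

    Lengths/widths are in micrometers; intensities in arbitrary detector
    counts. ``seed`` fully determines the output.
    """

    image_size_px: Tuple[int, int] = (256, 256)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_slices: int = 8
    z_step_um: float = 2.5
    n_fibers: int = 45
    orientation_mean_rad: float = 0.0
    orientation_kappa: float = 8.0
    fiber_width_um_mean: float = 5.0
    fiber_width_um_sd: float = 0.8
    fiber_length_um_mean: float = 150.0
    fiber_length_um_sd: float = 30.0
    fiber_intensity: float = 120.0
    diffuse_fraction: float = 0.10
    if_gain: float = 1.0
    bshg_gain: float = 1.0
    diffuse_bshg_weight: float = 0.2
    fb_gain_per_um: float = 1.0
    diffuse_equiv_width_um: float = 0.5
    background_offset: float = 10.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        checks = [
            (h >= 64 and w >= 64, "image_size_px must be at least 64x64"),
            (self.pixel_size_um > 0, "pixel_size_um must be positive"),
            (self.n_slices >= 1, "n_slices must be >= 1"),
            (self.z_step_um > 0, "z_step_um must be positive"),
            (self.n_fibers >= 0, "n_fibers must be non-negative"),
            (0.0 <= self.orientation_mean_rad < np.pi, "orientation_mean_rad must lie in [0, pi)"),
            (self.orientation_kappa >= 0, "orientation_kappa must be non-negative"),
            (self.fiber_width_um_mean > 0 and self.fiber_width_um_sd > 0, "fiber widths must be positive"),
            (self.fiber_length_um_mean > 0 and self.fiber_length_um_sd > 0, "fiber lengths must be positive"),
            (self.fiber_intensity > 0, "fiber_intensity must be positive"),
            (0.0 <= self.diffuse_fraction <= 1.0, "diffuse_fraction must lie in [0, 1]"),
            (self.if_gain > 0 and self.bshg_gain > 0, "channel gains must be positive"),
            (0.0 <= self.diffuse_bshg_weight <= 1.0, "diffuse_bshg_weight must lie in [0, 1]"),
            (self.fb_gain_per_um > 0, "fb_gain_per_um must be positive"),
            (self.diffuse_equiv_width_um > 0, "diffuse_equiv_width_um must be positive"),
            (self.background_offset >= 0, "background_offset must be non-negative"),
            (self.noise_sd >= 0, "noise_sd must be non-negative"),
        ]
        numeric = [
            self.pixel_size_um, self.z_step_um, self.orientation_mean_rad,
            self.orientation_kappa, self.fiber_width_um_mean, self.fiber_width_um_sd,
            self.fiber_length_um_mean, self.fiber_length_um_sd, self.fiber_intensity,
            self.diffuse_fraction, self.if_gain, self.bshg_gain,
            self.diffuse_bshg_weight, self.fb_gain_per_um, self.diffuse_equiv_width_um,
            self.background_offset, self.noise_sd,
        ]
        if not np.all(np.isfinite(numeric)):
            raise SceneParameterError("non-finite scene parameter")
        for ok, msg in checks:
            if not ok:
                raise SceneParameterError(msg)
        if self.fiber_width_um_mean < self.pixel_size_um:
            raise SceneParameterError("fiber_width_um_mean must be at least one pixel after calibration")

    def replace(self, **kwargs) -> "FiberSceneParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size_px"] = list(self.image_size_px)
        return d


@dataclass
class SceneTruth:
    """Ground truth emitted with each scene, for validating the analysis."""

    orientation_field: np.ndarray   # rad in [0, pi) on fiber pixels, NaN elsewhere
    fiber_mask: np.ndarray          # True exactly on rendered fiber pixels
    per_fiber_width_um: List[float]
    per_fiber_orientation_rad: List[float]
    expected_fb_gain: np.ndarray    # per-pixel forward/backward gain


@dataclass
class SceneBundle:
    """All channels of one synthetic FOV plus parameters and ground truth."""

    if_stack: ZStack
    bshg_stack: ZStack
    blank_stack: ZStack
    truth: SceneTruth
    params: FiberSceneParams
    fshg_stack: Optional[ZStack] = None


def _sample_axial_orientations(rng: np.random.Generator, n: int, mean: float, kappa: float) -> np.ndarray:
    """Axial von Mises: sample the doubled angle, halve, fold to [0, pi)."""
    doubled = rng.vonmises(0.0, kappa, size=n)
    return np.mod(mean + doubled / 2.0, np.pi)


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float, lower: float) -> np.ndarray:
    """Normal draws redrawn until above ``lower`` (vectorized rejection)."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, lower + 1e-9)


def _render_components(params: FiberSceneParams, rng: np.random.Generator):
    """Render fiber and diffuse component images plus truth."""
    h, w = params.image_size_px
    px = params.pixel_size_um
    fiber_img = np.zeros((h, w), dtype=np.float64)
    best = np.zeros((h, w), dtype=np.float64)       # strongest fiber profile so far
    orientation = np.full((h, w), np.nan)
    width_map = np.zeros((h, w), dtype=np.float64)  # um, of the dominant fiber
    mask = np.zeros((h, w), dtype=bool)

    n = params.n_fibers
    thetas = _sample_axial_orientations(rng, n, params.orientation_mean_rad, params.orientation_kappa)
    widths = _truncated_normal(rng, n, params.fiber_width_um_mean, params.fiber_width_um_sd, px)
    lengths = _truncated_normal(rng, n, params.fiber_length_um_mean, params.fiber_length_um_sd, px)
    centers_y = rng.uniform(0, h, size=n)
    centers_x = rng.uniform(0, w, size=n)

    suppress_fibers = params.diffuse_fraction >= 1.0
    for i in range(n):
        theta = float(thetas[i])
        w_px = widths[i] / px
        half_len_px = lengths[i] / px / 2.0
        # axial direction in (x, y); image rows are y
        ux, uy = np.cos(theta), np.sin(theta)
        cy, cx = centers_y[i], centers_x[i]
        reach = half_len_px + w_px
        y0 = max(int(np.floor(cy - reach * (abs(uy) + 1))), 0)
        y1 = min(int(np.ceil(cy + reach * (abs(uy) + 1))), h)
        x0 = max(int(np.floor(cx - reach * (abs(ux) + 1))), 0)
        x1 = min(int(np.ceil(cx + reach * (abs(ux) + 1))), w)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy = yy - cy
        dx = xx - cx
        t = dx * ux + dy * uy                       # position along the axis
        t_clamped = np.clip(t, -half_len_px, half_len_px)
        d2 = (dx - t_clamped * ux) ** 2 + (dy - t_clamped * uy) ** 2
        sigma = w_px / 2.0
        profile = params.fiber_intensity * np.exp(-d2 / (2.0 * sigma ** 2))
        in_body = d2 <= (w_px / 2.0) ** 2
        if not suppress_fibers:
            fiber_img[y0:y1, x0:x1] += profile
            mask[y0:y1, x0:x1] |= in_body
        dominant = in_body & (profile > best[y0:y1, x0:x1])
        if not suppress_fibers and dominant.any():
            sub = best[y0:y1, x0:x1]
            sub[dominant] = profile[dominant]
            orientation[y0:y1, x0:x1][dominant] = theta
            width_map[y0:y1, x0:x1][dominant] = widths[i]

    # unoriented diffuse speckle: smoothed positive noise, normalized to unit sum
    speckle = rng.exponential(1.0, size=(h, w))
    speckle = ndimage.gaussian_filter(speckle, sigma=1.5, mode="reflect")
    speckle = np.maximum(speckle, 0.0)
    total_speckle = speckle.sum()
    d0 = speckle / total_speckle if total_speckle > 0 else speckle

    fiber_sum = fiber_img.sum()
    df = params.diffuse_fraction
    if suppress_fibers:
        # all signal diffuse; budget = what the fibers would have carried,
        # or a nominal coverage for a fiber-free scene
        ref = fiber_sum if fiber_sum > 0 else params.fiber_intensity * h * w * _DIFFUSE_REFERENCE_COVERAGE
        diffuse_img = d0 * ref
        fiber_img = np.zeros_like(fiber_img)
        mask[:] = False
        orientation[:] = np.nan
        width_map[:] = 0.0
    elif df == 0.0 or (fiber_sum == 0 and params.n_fibers > 0):
        diffuse_img = np.zeros_like(fiber_img)
    elif fiber_sum == 0:
        ref = params.fiber_intensity * h * w * _DIFFUSE_REFERENCE_COVERAGE
        diffuse_img = d0 * (ref * df / (1.0 - df)) if df < 1 else d0 * ref
    else:
        diffuse_img = d0 * (fiber_sum * df / (1.0 - df))

    fb_gain = np.where(
        mask,
        params.fb_gain_per_um * width_map,
        params.fb_gain_per_um * params.diffuse_equiv_width_um,
    )
    truth = SceneTruth(
        orientation_field=orientation,
        fiber_mask=mask,
        per_fiber_width_um=[float(v) for v in widths] if not suppress_fibers else [],
        per_fiber_orientation_rad=[float(v) for v in thetas] if not suppress_fibers else [],
        expected_fb_gain=fb_gain,
    )
    return fiber_img, diffuse_img, truth


def make_fiber_field(params: FiberSceneParams) -> Tuple[SceneTruth, np.ndarray]:
    """Noiseless 2-D collagen intensity image (fibers + diffuse) with truth."""
    rng = np.random.default_rng(params.seed)
    fiber_img, diffuse_img, truth = _render_components(params, rng)
    return truth, fiber_img + diffuse_img


def _stack_from_plane(
    plane: np.ndarray,
    params: FiberSceneParams,
    rng: np.random.Generator,
    channel: Channel,
) -> ZStack:
    """Replicate a plane across z with per-slice intensity jitter.

    One slice always carries factor 1.0, so the maximum projection of a
    noiseless stack equals the plane plus the background offset exactly.
    """
    nz = params.n_slices
    jitter = rng.uniform(0.7, 1.0, size=nz)
    jitter[rng.integers(nz)] = 1.0
    voxels = plane[np.newaxis] * jitter[:, np.newaxis, np.newaxis] + params.background_offset
    if params.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, params.noise_sd, size=voxels.shape)
    voxels = np.clip(voxels, 0.0, None)
    return ZStack(
        voxels=voxels,
        channel=channel,
        pixel_size_um=params.pixel_size_um,
        z_step_um=params.z_step_um,
    )


def render_scene(params: FiberSceneParams, include_fshg: bool = True) -> SceneBundle:
    """Render all channels of one synthetic FOV.

    Deterministic: identical ``params`` (including ``seed``) give bit-identical
    bundles.
    """
    rng = np.random.default_rng(params.seed)
    fiber_img, diffuse_img, truth = _render_components(params, rng)
    if_plane = params.if_gain * (fiber_img + diffuse_img)
    bshg_plane = params.bshg_gain * (fiber_img + params.diffuse_bshg_weight * diffuse_img)
    fshg_plane = bshg_plane * truth.expected_fb_gain

    if_stack = _stack_from_plane(if_plane, params, rng, Channel.IF)
    bshg_stack = _stack_from_plane(bshg_plane, params, rng, Channel.BSHG)
    fshg_stack = _stack_from_plane(fshg_plane, params, rng, Channel.FSHG) if include_fshg else None
    blank_stack = _stack_from_plane(np.zeros_like(if_plane), params, rng, Channel.BLANK)
    return SceneBundle(
        if_stack=if_stack,
        bshg_stack=bshg_stack,
        fshg_stack=fshg_stack,
        blank_stack=blank_stack,
        truth=truth,
        params=params,
    )


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

#: TACS-2-like: long, thick, strongly co-oriented fibers, little diffuse signal
WT_PRESET = dict(
    n_fibers=45,
    orientation_kappa=8.0,
    fiber_width_um_mean=5.0,
    fiber_width_um_sd=0.8,
    fiber_length_um_mean=150.0,
    fiber_length_um_sd=30.0,
    fiber_intensity=120.0,
    diffuse_fraction=0.10,
    if_gain=1.0,
    bshg_gain=1.0,
)

#: TACS-1-like: short, thin, weakly oriented fibers in a dense diffuse bed,
#: more total collagen and higher SHG conversion per unit collagen I
KO_PRESET = dict(
    n_fibers=70,
    orientation_kappa=0.5,
    fiber_width_um_mean=2.0,
    fiber_width_um_sd=0.4,
    fiber_length_um_mean=50.0,
    fiber_length_um_sd=15.0,
    fiber_intensity=300.0,
    diffuse_fraction=0.55,
    if_gain=1.3,
    bshg_gain=2.2,
)

PRESETS = {"WT": WT_PRESET, "KO": KO_PRESET}


def preset_params(group: str, seed: int = 0, **overrides) -> FiberSceneParams:
    """Scene parameters for a named group preset with optional overrides."""
    if group not in PRESETS:
        raise KeyError(f"unknown preset {group!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[group])
    kwargs.update(overrides)
    kwargs["seed"] = seed
    return FiberSceneParams(**kwargs)


def fov_seeds(cohort_seed: int, n_fovs: int) -> List[int]:
    """Deterministic per-FOV seeds spawned from one cohort seed."""
    ss = np.random.SeedSequence(cohort_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n_fovs)]


def make_cohort(
    group_preset: str,
    n_fovs: int,
    seed: int,
    include_fshg: bool = True,
    **overrides,
) -> List[SceneBundle]:
    """Render a cohort of FOVs for one experimental group."""
    if n_fovs < 1:
        raise ValueError("n_fovs must be >= 1")
    bundles = []
    for fov_seed in fov_seeds(seed, n_fovs):
        params = preset_params(group_preset, seed=fov_seed, **overrides)
        bundles.append(render_scene(params, include_fshg=include_fshg))
    return bundles
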