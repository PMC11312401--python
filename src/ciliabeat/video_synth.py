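"""Rendering of beat trajectories into 250 fps grayscale frame stacks.

The synthetic scene is a single ~10 µm filament anchored at one end to the
coverslip, imaged in-plane.  Each frame is the line integral of the filament
centerline convolved with a Gaussian point-spread function, on a constant
background, with optional Gaussian read noise and Poisson shot noise.  The
100 nm filament diameter is far below the resolution limit, so the filament
contributes only through its PSF-blurred centerline.

Default optics (0.1 µm pixels, 0.15 µm PSF sd) make the beat excursions of
0.5-1.5 µm span 5-15 pixels, comparable to real high-speed video microscopy
of cilia.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .beat_kinematics import FRAME_MS, BeatTrajectory, ConfigurationError

#: renderer refuses beat cycles sampled by fewer frames than this
MIN_FRAMES_PER_CYCLE = 6


class FormatError(ValueError):
    """Raised for malformed image stacks on disk."""


@dataclass(frozen=True)
class ImagingConfig:
    """Camera and optics model for the synthetic recording."""

    fps: float = 250.0
    pixel_size: float = 0.1          # µm per pixel
    frame_shape: tuple[int, int] = (128, 128)   # (rows, cols)
    psf_sigma: float = 0.15          # µm
    background_level: float = 100.0  # grayscale counts
    filament_intensity: float = 2000.0   # integrated counts per µm of filament
    noise_sd: float = 3.0            # additive Gaussian noise, counts
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigurationError(f"fps must be > 0, got {self.fps}")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.psf_sigma < 0:
            raise ConfigurationError("psf_sigma must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.fps


@dataclass(frozen=True)
class CiliumGeometry:
    """Placement of the anchored cilium in the image plane (µm coordinates)."""

    length: float = 10.0
    anchor: tuple[float, float] = (1.4, 4.6)   # (x, y) µm
    base_angle: float = 0.0                    # degrees, unbent orientation
    scanline_fraction: float = 0.7             # arc-length fraction of the scan line

    def __post_init__(self) -> None:
        if not 0 < self.scanline_fraction <= 1:
            raise ConfigurationError("scanline_fraction must be in (0, 1]")
        if self.length <= 0:
            raise ConfigurationError("length must be > 0")


@dataclass
class FrameStack:
    """Ordered grayscale frames with imaging metadata and optional ground truth."""

    frames: np.ndarray            # (T, H, W) uint16
    config: ImagingConfig
    truth: BeatTrajectory | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.config.frame_interval_ms


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def pose_cilium(
    geometry: CiliumGeometry, displacement: float, n_points: int = 400
) -> np.ndarray:
    """Centerline of the bent cilium as (n_points, 2) image coordinates, µm.

    The shape is a clamped smoothstep lateral-offset profile in the base-pose
    frame: the offset rises smoothly from 0 at the anchor to exactly
    ``displacement`` at the rest-pose scan-line station (and stays there
    distally), so the filament's crossing of the perpendicular scan line
    equals the commanded displacement.  Total arc length is held at
    ``geometry.length`` by truncation, and the anchor tangent stays along
    ``base_angle`` (clamped base).
    """
    L = geometry.length
    x_s = geometry.scanline_fraction * L
    # fine body-frame sampling; ds >= dx so x in [0, L] covers arc length L
    x = np.linspace(0.0, L, 2001)
    y = displacement * _smoothstep(x / x_s)
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate(([0.0], np.cumsum(seg)))
    s_grid = np.linspace(0.0, L, n_points)
    xb = np.interp(s_grid, s, x)
    yb = np.interp(s_grid, s, y)
    th = math.radians(geometry.base_angle)
    c, sn = math.cos(th), math.sin(th)
    pts = np.empty((n_points, 2))
    pts[:, 0] = geometry.anchor[0] + c * xb - sn * yb
    pts[:, 1] = geometry.anchor[1] + sn * xb + c * yb
    return pts


def _deposit_bilinear(canvas: np.ndarray, pts_px: np.ndarray, weight: float) -> None:
    """Accumulate point masses onto the pixel grid with bilinear weights."""
    cols = pts_px[:, 0]
    rows = pts_px[:, 1]
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    np.add.at(canvas, (r0, c0), weight * (1 - fr) * (1 - fc))
    np.add.at(canvas, (r0, c0 + 1), weight * (1 - fr) * fc)
    np.add.at(canvas, (r0 + 1, c0), weight * fr * (1 - fc))
    np.add.at(canvas, (r0 + 1, c0 + 1), weight * fr * fc)


def render_stack(
    trajectory: BeatTrajectory,
    geometry: CiliumGeometry | None = None,
    config: ImagingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FrameStack:
    """Render a trajectory into a synthetic recording.

    With noise off (``noise_sd == 0`` and ``shot_noise == False``) the output
    is a deterministic function of its inputs.
    """
    geometry = geometry or CiliumGeometry()
    config = config or ImagingConfig()
    if len(trajectory.times) == 0:
        raise ConfigurationError("empty trajectory")
    if len(trajectory.times) > 1:
        dt = float(trajectory.times[1] - trajectory.times[0])
        if not math.isclose(dt, config.frame_interval_ms, rel_tol=1e-9):
            raise ConfigurationError(
                f"trajectory time step {dt} ms does not match the configured "
                f"frame interval {config.frame_interval_ms} ms"
            )
    peaks = trajectory.peak_times
    if len(peaks) >= 2:
        min_cycle_frames = float(np.min(np.diff(peaks))) / config.frame_interval_ms
        if min_cycle_frames < MIN_FRAMES_PER_CYCLE:
            raise ConfigurationError(
                f"beat cycle sampled by only {min_cycle_frames:.1f} frames "
                f"(< {MIN_FRAMES_PER_CYCLE}); increase fps or slow the beat"
            )
    H, W = config.frame_shape
    px = config.pixel_size
    n_points = 400
    weight = config.filament_intensity * geometry.length / n_points
    sigma_px = config.psf_sigma / px
    need_noise = config.noise_sd > 0 or config.shot_noise
    if need_noise and rng is None:
        raise ConfigurationError("noise enabled but no random generator supplied")

    frames = np.empty((len(trajectory.positions), H, W), dtype=np.uint16)
    canvas = np.empty((H, W))
    for k, d in enumerate(trajectory.positions):
        pts = pose_cilium(geometry, float(d), n_points) / px
        if (
            pts[:, 0].min() < 0.5
            or pts[:, 0].max() > W - 1.5
            or pts[:, 1].min() < 0.5
            or pts[:, 1].max() > H - 1.5
        ):
            raise ConfigurationError(
                f"cilium pose exits the frame at frame {k} "
                f"(t = {k * config.frame_interval_ms:.0f} ms, displacement {d:.2f} µm)"
            )
        canvas[:] = 0.0
        _deposit_bilinear(canvas, pts, weight)
        img = gaussian_filter(canvas, sigma_px, mode="constant") + config.background_level
        if config.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        frames[k] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return FrameStack(frames=frames, config=config, truth=trajectory)


def write_stack(stack: FrameStack, path) -> None:
    """Write a stack as multi-page 16-bit grayscale TIFF with fps/pixel metadata."""
    meta = {
        "fps": stack.config.fps,
        "pixel_size_um": stack.config.pixel_size,
        "psf_sigma_um": stack.config.psf_sigma,
    }
    tifffile.imwrite(path, stack.frames, description=json.dumps(meta))


def read_stack(
    path, fps: float | None = None, pixel_size: float | None = None
) -> FrameStack:
    """Read a multi-page TIFF back into a :class:`FrameStack`.

    For foreign files without embedded metadata, ``fps`` and ``pixel_size``
    must be supplied.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].description or ""
            shapes = {p.shape for p in tf.pages}
    except (tifffile.TiffFileError, OSError, ValueError, IndexError, KeyError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if len(shapes) > 1:
        raise FormatError(f"inconsistent page shapes in {path}: {shapes}")
    if frames.ndim == 2:
        frames = frames[None, :, :]
    elif frames.ndim != 3:
        raise FormatError(f"expected 2-D pages in {path}, got shape {frames.shape}")
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    fps = fps if fps is not None else meta.get("fps")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if fps is None or pixel_size is None:
        raise FormatError(
            f"{path} lacks fps/pixel size metadata; supply them explicitly"
        )
    config = ImagingConfig(
        fps=float(fps),
        pixel_size=float(pixel_size),
        frame_shape=frames.shape[1:],
        psf_sigma=float(meta.get("psf_sigma_um", 0.15)),
    )
    return FrameStack(frames=np.ascontiguousarray(frames), config=config)
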