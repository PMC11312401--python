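"""Scan-line quantification of beat frequency and bend distance.

The measurement mirrors the classic kymograph workflow: a line is set across
the beat envelope, the intensity along that line is sampled in every frame,
and the cilium's crossing position becomes a one-dimensional wave in time.
The ciliary beat frequency (CBF) is the number of wave peaks counted over the
record (2 s by convention); the ciliary bend distance (CBD) is the mean
peak-to-preceding-trough excursion over the first ten waves.

Positions, not intensity amplitudes, are traced so the CBD is natively in µm
and invariant to uniform intensity rescaling or background changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks, savgol_filter

from .video_synth import CiliumGeometry, FrameStack

#: default topographic prominence for a peak to count as a beat, µm.
#: Below the smallest stimulated bend distance (~0.57 µm) and above the
#: excursion scale of unstimulated baseline fluctuation.
DEFAULT_MIN_PROMINENCE = 0.2
#: default minimum peak separation, ms (5 frames; shortest plausible cycle ~65 ms)
DEFAULT_MIN_SEPARATION = 20.0


class NoCrossingError(ValueError):
    """The scan line never intersects a detectable filament crossing."""


@dataclass(frozen=True)
class ScanLine:
    """A user-set line across the beat envelope, image coordinates in µm."""

    a: tuple[float, float]
    b: tuple[float, float]
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError("scan line endpoints coincide")

    @property
    def length(self) -> float:
        return math.hypot(self.b[0] - self.a[0], self.b[1] - self.a[1])


def scanline_for(
    geometry: CiliumGeometry, amplitude: float, pad: float = 0.75
) -> tuple[ScanLine, float]:
    """Scan line perpendicular to the base pose through the scan-line station.

    Returns the line and the offset (µm from endpoint ``a``) at which the
    rest-pose filament crosses it, so ground-truth displacements map to trace
    positions as ``offset + displacement``.
    """
    th = math.radians(geometry.base_angle)
    ex = (math.cos(th), math.sin(th))
    ey = (-math.sin(th), math.cos(th))  # positive displacement direction
    x_s = geometry.scanline_fraction * geometry.length
    p = (geometry.anchor[0] + x_s * ex[0], geometry.anchor[1] + x_s * ex[1])
    lo, hi = -pad, amplitude + pad
    a = (p[0] + lo * ey[0], p[1] + lo * ey[1])
    b = (p[0] + hi * ey[0], p[1] + hi * ey[1])
    return ScanLine(a=a, b=b), -lo


@dataclass
class PositionTrace:
    """Crossing position of the cilium along the scan line, per frame."""

    times: np.ndarray      # ms
    positions: np.ndarray  # µm from scan-line endpoint a
    quality: np.ndarray    # per-frame confidence in [0, 1]

    @property
    def dt_ms(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 4.0

    @property
    def duration_s(self) -> float:
        return len(self.times) * self.dt_ms / 1000.0


@dataclass
class BeatSet:
    """Detected beats: peak indices and matched preceding-trough indices."""

    peaks: np.ndarray      # indices into the trace
    troughs: np.ndarray    # preceding trough index per peak
    complete: np.ndarray   # bool: wave has a genuine preceding trough
    smoothed: np.ndarray   # the (lightly smoothed) positions used for detection


@dataclass
class BeatMeasurement:
    """Per-cilium result of the scan-line quantification."""

    cbf: float                 # Hz
    cbd: float                 # µm; NaN when no complete wave was available
    peak_times: np.ndarray     # ms
    trough_depths: np.ndarray  # µm excursion per used wave
    n_waves_used: int

    @property
    def cbd_defined(self) -> bool:
        return self.n_waves_used > 0 and not math.isnan(self.cbd)


def _smooth(x: np.ndarray, window: int = 5) -> np.ndarray:
    if window <= 1 or len(x) < window:
        return x
    return savgol_filter(x, window_length=window, polyorder=2)


def extract_trace(stack: FrameStack, line: ScanLine) -> PositionTrace:
    """Reduce a frame stack to the crossing-position wave along a scan line.

    Intensity is sampled along the line by bilinear interpolation; a robust
    background profile (elementwise minimum of the temporal-median profile
    and each frame's spatial median) is subtracted; the intensity-weighted
    centroid of the dominant peak gives the crossing position in µm.  Quality
    is the peak contrast relative to the local noise scale.
    """
    cfg = stack.config
    L = line.length
    n = line.n_samples or int(math.ceil(L / (cfg.pixel_size / 2.0))) + 1
    t_lin = np.linspace(0.0, 1.0, n)
    xs = (line.a[0] + t_lin * (line.b[0] - line.a[0])) / cfg.pixel_size
    ys = (line.a[1] + t_lin * (line.b[1] - line.a[1])) / cfg.pixel_size
    H, W = stack.frames.shape[1:]
    if xs.min() < 0 or xs.max() > W - 1 or ys.min() < 0 or ys.max() > H - 1:
        raise ValueError("scan line extends outside the frame")
    coords = np.vstack([ys, xs])  # (row, col) order
    ds = L / (n - 1)

    profiles = np.empty((stack.n_frames, n))
    for k in range(stack.n_frames):
        profiles[k] = map_coordinates(
            stack.frames[k].astype(float), coords, order=1, mode="nearest"
        )

    bg = np.minimum(
        np.median(profiles, axis=0)[None, :],
        np.median(profiles, axis=1)[:, None],
    )
    sub = np.clip(profiles - bg, 0.0, None)

    # noise scale from frame-to-frame flicker, robust to the moving filament
    if stack.n_frames > 1:
        sigma = float(np.median(np.abs(np.diff(profiles, axis=0)))) * 1.4826 / math.sqrt(2)
    else:
        sigma = 0.0

    am = np.argmax(sub, axis=1)
    contrast = sub[np.arange(stack.n_frames), am]
    if contrast.max() < max(5.0 * sigma, 1e-6):
        raise NoCrossingError(
            "no crossing detected: scan line profile is flat in every frame"
        )

    psf = getattr(cfg, "psf_sigma", 0.15)
    w = max(2, int(round(max(3.0 * psf, 0.3) / ds)))
    idx = np.arange(n)
    positions = np.empty(stack.n_frames)
    for k in range(stack.n_frames):
        lo = max(0, am[k] - w)
        hi = min(n, am[k] + w + 1)
        seg = sub[k, lo:hi]
        tot = seg.sum()
        if tot <= 0:
            positions[k] = am[k] * ds
        else:
            positions[k] = float((seg * idx[lo:hi]).sum() / tot) * ds
    quality = np.clip(contrast / (contrast + 5.0 * sigma + 1e-12), 0.0, 1.0)
    times = np.arange(stack.n_frames) * cfg.frame_interval_ms
    return PositionTrace(times=times, positions=positions, quality=quality)


def detect_beats(
    trace: PositionTrace,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    smooth_window: int = 5,
) -> BeatSet:
    """Find beat peaks and their preceding troughs in a position trace.

    Peaks must exceed ``min_prominence`` (µm, topographic prominence) and be
    at least ``min_separation`` ms apart; each peak is matched to the minimum
    of the trace since the previous peak (or the record start).  An empty
    result is valid.
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be > 0")
    x = _smooth(trace.positions, smooth_window)
    distance = max(1, int(round(min_separation / trace.dt_ms)))
    peaks, _ = find_peaks(x, prominence=min_prominence, distance=distance)
    troughs = np.empty(len(peaks), dtype=int)
    complete = np.empty(len(peaks), dtype=bool)
    prev = 0
    for i, p in enumerate(peaks):
        seg = x[prev:p]
        t = prev + int(np.argmin(seg)) if len(seg) else prev
        troughs[i] = t
        complete[i] = t > prev or (i > 0)
        prev = p
    return BeatSet(peaks=peaks, troughs=troughs, complete=complete, smoothed=x)


def compute_cbf(peaks, record_duration: float) -> float:
    """Beat frequency: peak count divided by record duration (s)."""
    if record_duration <= 0:
        raise ValueError("record_duration must be > 0")
    n = len(peaks.peaks) if isinstance(peaks, BeatSet) else len(peaks)
    return n / record_duration


def compute_cbd(
    trace: PositionTrace, beats: BeatSet, n_waves: int = 10
) -> tuple[float, np.ndarray]:
    """Mean peak-minus-preceding-trough excursion over the first ``n_waves`` waves.

    Returns ``(cbd, depths)`` where ``depths`` lists the per-wave excursions
    actually used.  With no complete wave the CBD is undefined and returned
    as NaN with an empty depth array (distinct from a genuine 0).
    """
    x = beats.smoothed
    depths = []
    for p, t, ok in zip(beats.peaks, beats.troughs, beats.complete):
        if not ok:
            continue
        depths.append(float(x[p] - x[t]))
        if len(depths) >= n_waves:
            break
    depths = np.asarray(depths)
    if len(depths) == 0:
        return float("nan"), depths
    return float(depths.mean()), depths


def measure_trace(
    trace: PositionTrace,
    record_duration: float | None = None,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    n_waves: int = 10,
) -> tuple[BeatMeasurement, BeatSet]:
    """Full per-cilium quantification of a position trace."""
    beats = detect_beats(trace, min_prominence, min_separation)
    duration = record_duration if record_duration is not None else trace.duration_s
    cbf = compute_cbf(beats, duration)
    cbd, depths = compute_cbd(trace, beats, n_waves)
    meas = BeatMeasurement(
        cbf=cbf,
        cbd=cbd,
        peak_times=trace.times[beats.peaks],
        trough_depths=depths,
        n_waves_used=len(depths),
    )
    return meas, beats


def measure_stack(
    stack: FrameStack, line: ScanLine, **kwargs
) -> tuple[PositionTrace, BeatMeasurement, BeatSet]:
    """Extract the trace from a stack and quantify it in one call."""
    trace = extract_trace(stack, line)
    meas, beats = measure_trace(trace, **kwargs)
    return trace, meas, beats


def suggest_scanline(stack: FrameStack, pad: float = 0.75) -> ScanLine:
    """Suggest a scan line from the temporal-variance map of a stack.

    The line runs through the variance-weighted centroid of the beat
    envelope, along the principal axis of the high-variance region.  This is
    a helper for eyeballing line placement; placement remains user input.
    """
    var = stack.frames.astype(float).var(axis=0)
    thr = var.max() * 0.2
    rows, cols = np.nonzero(var > thr)
    if len(rows) < 2:
        raise NoCrossingError("no moving structure found in the stack")
    wts = var[rows, cols]
    px = stack.config.pixel_size
    cy, cx = np.average(rows, weights=wts), np.average(cols, weights=wts)
    cov = np.cov(np.vstack([cols - cx, rows - cy]), aweights=wts)
    evals, evecs = np.linalg.eigh(cov)
    # the high-variance blob is elongated along the filament; the beat
    # excursion runs across it, so the scan line follows the minor axis
    v = evecs[:, np.argmin(evals)]
    half = 2.0 * math.sqrt(max(evals.min(), 0.0)) * px + pad
    c = (cx * px, cy * px)
    return ScanLine(
        a=(c[0] - half * v[0], c[1] - half * v[1]),
        b=(c[0] + half * v[0], c[1] + half * v[1]),
    )
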