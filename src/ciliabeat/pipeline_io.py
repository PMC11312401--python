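"""Shared plumbing: run configuration, validation, seed streams, logging.

One integer master seed drives every stage; named per-cilium streams are
derived deterministically with :class:`numpy.random.SeedSequence` spawn keys
so any stage can be replayed in isolation.
"""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .beat_kinematics import FRAME_MS
from .video_synth import CiliumGeometry, ImagingConfig

logger = logging.getLogger("ciliabeat")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ConfigValidationError(ValueError):
    """Aggregated, human-readable configuration errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved pipeline configuration; all defaults are self-contained."""

    master_seed: int = 0
    preset_table_path: str | None = None
    record_duration_s: float = 2.0
    min_prominence: float = 0.2      # µm
    min_separation_ms: float = 20.0
    velocity_fraction: float = 0.1
    out_dir: str = "."
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    geometry: CiliumGeometry = field(default_factory=CiliumGeometry)

    @property
    def n_frames(self) -> int:
        return int(round(self.record_duration_s * self.imaging.fps))


_TOP_KEYS = {f.name for f in fields(RunConfig)}
_IMG_KEYS = {f.name for f in fields(ImagingConfig)}
_GEO_KEYS = {f.name for f in fields(CiliumGeometry)}


def validate_config(raw: dict | RunConfig) -> RunConfig:
    """Type- and range-check a configuration mapping.

    Unknown keys are rejected by name; every problem found is reported in one
    aggregated :class:`ConfigValidationError` rather than first-error-only.
    """
    if isinstance(raw, RunConfig):
        raw = config_to_dict(raw)
    errors: list[str] = []
    raw = dict(raw or {})
    for key in sorted(set(raw) - _TOP_KEYS):
        errors.append(f"unknown config key: {key!r}")
    img_raw = dict(raw.get("imaging") or {})
    geo_raw = dict(raw.get("geometry") or {})
    for key in sorted(set(img_raw) - _IMG_KEYS):
        errors.append(f"unknown imaging key: {key!r}")
    for key in sorted(set(geo_raw) - _GEO_KEYS):
        errors.append(f"unknown geometry key: {key!r}")

    def _num(d, key, lo=None, lo_strict=None, cast=float):
        if key not in d:
            return None
        try:
            v = cast(d[key])
        except (TypeError, ValueError):
            errors.append(f"{key}: expected a number, got {d[key]!r}")
            return None
        if lo is not None and v < lo:
            errors.append(f"{key}: must be >= {lo}, got {v}")
        if lo_strict is not None and v <= lo_strict:
            errors.append(f"{key}: must be > {lo_strict}, got {v}")
        return v

    _num(raw, "master_seed", lo=0, cast=int)
    _num(raw, "record_duration_s", lo_strict=0)
    _num(raw, "min_prominence", lo_strict=0)
    _num(raw, "min_separation_ms", lo=0)
    vf = _num(raw, "velocity_fraction", lo_strict=0)
    if vf is not None and vf >= 1:
        errors.append(f"velocity_fraction: must be < 1, got {vf}")
    _num(img_raw, "fps", lo_strict=0)
    _num(img_raw, "pixel_size", lo_strict=0)
    _num(img_raw, "psf_sigma", lo=0)
    _num(img_raw, "noise_sd", lo=0)
    _num(geo_raw, "length", lo_strict=0)
    sf = _num(geo_raw, "scanline_fraction", lo_strict=0)
    if sf is not None and sf > 1:
        errors.append(f"scanline_fraction: must be <= 1, got {sf}")
    if errors:
        raise ConfigValidationError(errors)

    kwargs = {k: v for k, v in raw.items() if k not in ("imaging", "geometry")}
    if "frame_shape" in img_raw:
        img_raw["frame_shape"] = tuple(img_raw["frame_shape"])
    if "anchor" in geo_raw:
        geo_raw["anchor"] = tuple(geo_raw["anchor"])
    return RunConfig(
        imaging=ImagingConfig(**img_raw),
        geometry=CiliumGeometry(**geo_raw),
        **kwargs,
    )


def config_to_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["imaging"]["frame_shape"] = list(d["imaging"]["frame_shape"])
    d["geometry"]["anchor"] = list(d["geometry"]["anchor"])
    return d


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def derive_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic named random stream derived from the master seed.

    Streams with different keys (condition index, cilium index, record index,
    stage) are statistically independent; the same key always replays the
    same stream.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


@contextmanager
def log_stage(stage: str, seed: int | None = None):
    """Structured stage logging (stage, seed, wall time) to stderr."""
    t0 = time.perf_counter()
    logger.info("stage=%s seed=%s start", stage, seed)
    try:
        yield
    finally:
        logger.info("stage=%s seed=%s wall_s=%.2f", stage, seed, time.perf_counter() - t0)
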