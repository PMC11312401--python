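"""Parametric, seeded generation of single-cilium beat trajectories.

A beating airway cilium alternates a fast *effective stroke* (forward sweep,
duration ``t_eff``), a slower *recovery stroke* (return sweep, ``t_rec``) and a
resting *inter-beat interval* during which the axonemal dyneins are presumed
inactive.  At the scan line the beat appears as a one-dimensional excursion of
the cilium's crossing position: a smooth rise from baseline to ``amplitude``
(the generative bend distance, CBD) over the effective stroke and a smooth
fall back over the recovery stroke.

Two simulation modes reconcile independently reported beat frequencies with
independently reported stroke components (which are mutually inconsistent for
the conditions they describe):

``rate_matched``
    all three duration components are rescaled by one common factor so the
    expected cycle length equals ``1 / target_cbf``;
``component_matched``
    the configured durations are used verbatim and the beat rate is whatever
    emerges from ``1 / (t_eff + t_rec + mean interval)``.

Trajectories live on the 4 ms frame grid of a 250 fps high-speed video
recording, and every trajectory carries a ground-truth event log of
(effective-stroke start, peak, recovery-stroke end) times for validating the
downstream quantifiers by parameter recovery.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

#: duration of one video frame, ms (250 fps)
FRAME_MS = 4.0

MODES = ("rate_matched", "component_matched")


class ConfigurationError(ValueError):
    """Raised for invalid kinematic or preset configuration."""


@dataclass(frozen=True)
class BeatParameters:
    """Kinematic description of one beating condition.

    Parameters
    ----------
    t_eff, t_rec:
        Effective- and recovery-stroke durations, ms.
    interval_mean:
        Arithmetic mean of the resting inter-beat interval, ms.
    interval_sigma_log:
        Log-scale standard deviation of the lognormal interval law
        (dimensionless; 0 gives a deterministic interval).
    amplitude:
        Peak-to-baseline excursion at the scan line, µm (the generative CBD).
        ``amplitude == 0`` disables the beat train entirely (null conditions).
    mode:
        ``"rate_matched"`` or ``"component_matched"`` (see module docstring).
    target_cbf:
        Beat frequency to hit in rate_matched mode, Hz.
    fluct_sd, fluct_tau:
        Ornstein-Uhlenbeck baseline fluctuation: stationary sd (µm) and
        correlation time (ms).  Used for unstimulated / null conditions.
    """

    t_eff: float
    t_rec: float
    interval_mean: float
    interval_sigma_log: float = 0.45
    amplitude: float = 1.0
    mode: str = "component_matched"
    target_cbf: float | None = None
    fluct_sd: float = 0.0
    fluct_tau: float = 300.0

    def __post_init__(self) -> None:
        if self.t_eff <= 0:
            raise ConfigurationError(f"t_eff must be > 0, got {self.t_eff}")
        if self.t_rec <= 0:
            raise ConfigurationError(f"t_rec must be > 0, got {self.t_rec}")
        if self.interval_mean < 0:
            raise ConfigurationError(
                f"interval_mean must be >= 0, got {self.interval_mean}"
            )
        if self.amplitude < 0:
            raise ConfigurationError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.interval_sigma_log < 0:
            raise ConfigurationError("interval_sigma_log must be >= 0")
        if self.mode not in MODES:
            raise ConfigurationError(
                f"unknown mode {self.mode!r}; expected one of {MODES}"
            )
        if self.mode == "rate_matched":
            if self.target_cbf is None or self.target_cbf <= 0:
                raise ConfigurationError(
                    "rate_matched mode requires target_cbf > 0"
                )
        if self.fluct_sd < 0 or self.fluct_tau <= 0:
            raise ConfigurationError("fluctuation parameters out of range")

    @property
    def beating(self) -> bool:
        return self.amplitude > 0

    @property
    def scale_factor(self) -> float:
        """Common rescaling of all duration components (1.0 unless rate_matched)."""
        if self.mode != "rate_matched":
            return 1.0
        cycle_ms = 1000.0 / float(self.target_cbf)
        s = cycle_ms / (self.t_eff + self.t_rec + self.interval_mean)
        if s <= 0:
            raise ConfigurationError(
                f"target_cbf {self.target_cbf} Hz yields non-positive scale factor"
            )
        return s

    def realized(self) -> "BeatParameters":
        """Parameters with the mode's rescaling applied to all components."""
        s = self.scale_factor
        if s == 1.0:
            return self
        return replace(
            self,
            t_eff=self.t_eff * s,
            t_rec=self.t_rec * s,
            interval_mean=self.interval_mean * s,
            mode="component_matched",
            target_cbf=None,
        )

    def with_mode(self, mode: str, target_cbf: float | None = None) -> "BeatParameters":
        return replace(
            self, mode=mode, target_cbf=target_cbf if target_cbf is not None else self.target_cbf
        )

    @property
    def expected_cycle_ms(self) -> float:
        p = self.realized()
        return p.t_eff + p.t_rec + p.interval_mean

    @property
    def expected_rate_hz(self) -> float:
        return 1000.0 / self.expected_cycle_ms


@dataclass(frozen=True)
class ConditionPreset:
    """One experimental condition: a label, its kinematics, and cohort size."""

    label: str
    params: BeatParameters
    n_cilia: int
    group: str = ""
    n_intervals: int | None = None

    def __post_init__(self) -> None:
        if self.n_cilia < 1:
            raise ConfigurationError(f"{self.label}: n_cilia must be >= 1")


@dataclass
class BeatTrajectory:
    """Ground-truth crossing position on the scan line, sampled on the 4 ms grid.

    ``event_log`` holds one ``(effective_start, peak_time, recovery_end)``
    triple per generated beat, in ms, all on the frame grid.
    """

    times: np.ndarray
    positions: np.ndarray
    event_log: list[tuple[float, float, float]]
    params: BeatParameters

    @property
    def duration_ms(self) -> float:
        return len(self.times) * FRAME_MS

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([e[1] for e in self.event_log])


def sample_interval(
    params: BeatParameters, rng: np.random.Generator, size: int | None = None
):
    """Draw resting inter-beat interval(s), ms.

    Intervals follow a lognormal law parameterized by its *arithmetic* mean
    ``interval_mean`` and log-sd ``interval_sigma_log``; zero log-sd collapses
    to a point mass at the mean.
    """
    m = params.interval_mean
    if m < 0:
        raise ConfigurationError("interval_mean must be >= 0")
    sig = params.interval_sigma_log
    if m == 0 or sig == 0:
        return m if size is None else np.full(size, float(m))
    # arithmetic mean of lognormal = exp(mu + sig^2/2)
    mu = math.log(m) - 0.5 * sig * sig
    return rng.lognormal(mean=mu, sigma=sig, size=size)


def stroke_waveform(phase_time, params: BeatParameters):
    """Position (µm) within one beat at ``phase_time`` ms after the stroke start.

    Raised-cosine ramps: a smooth monotone rise from 0 to ``amplitude`` over
    the effective stroke, then a smooth monotone fall back over the recovery
    stroke, continuous (with zero velocity) at the peak.
    """
    t = np.asarray(phase_time, dtype=float)
    total = params.t_eff + params.t_rec
    if np.any(t < 0) or np.any(t > total):
        raise ValueError(
            f"phase_time outside [0, {total}] ms for this beat"
        )
    a = params.amplitude
    rise = 0.5 * a * (1.0 - np.cos(np.pi * t / params.t_eff))
    fall = 0.5 * a * (1.0 + np.cos(np.pi * (t - params.t_eff) / params.t_rec))
    out = np.where(t <= params.t_eff, rise, fall)
    return float(out) if np.isscalar(phase_time) else out


def _ou_process(
    n: int, sd: float, tau_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples on the frame grid (exact update)."""
    a = math.exp(-FRAME_MS / tau_ms)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i - 1]
    return x


def build_trajectory(
    params: BeatParameters, duration_s: float, rng: np.random.Generator
) -> BeatTrajectory:
    """Concatenate sampled rest intervals and stereotyped beats on the 4 ms grid.

    The beat train alternates rest interval / beat and is started several
    expected cycles *before* the record opens, so the record samples the
    stationary regime — the expected number of peaks inside a record of
    length ``T`` is then ``T / expected_cycle``, matching how beat frequency
    is read off a finite recording.  (With zero interval variance the burn-in
    is an exact multiple of the cycle, so the record still deterministically
    opens on a full rest interval.)  Continuous segment boundaries are
    carried exactly and only rounded to the frame grid at the end, so grid
    quantization does not accumulate.  In rate_matched mode the components
    are first rescaled by the common factor (see :class:`BeatParameters`).

    A beat straddling the record start is rendered from its in-record frames
    but omitted from ``event_log`` (its effective start is unobservable);
    beats running past the record end are logged with their true boundaries.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration must be > 0")
    p = params.realized()
    n_frames = int(round(duration_s * 1000.0 / FRAME_MS))
    duration_ms = n_frames * FRAME_MS
    times = np.arange(n_frames) * FRAME_MS
    positions = np.zeros(n_frames)
    events: list[tuple[float, float, float]] = []

    if p.beating:
        burn_cycles = 5
        t = -burn_cycles * (p.t_eff + p.t_rec + p.interval_mean)
        prev_i2 = -(10**9)
        while True:
            t += float(sample_interval(p, rng))
            e0, pk, e1 = t, t + p.t_eff, t + p.t_eff + p.t_rec
            t = e1
            if e0 >= duration_ms:
                break
            i0 = max(int(round(e0 / FRAME_MS)), prev_i2)
            i1 = max(int(round(pk / FRAME_MS)), i0 + 1)
            i2 = max(int(round(e1 / FRAME_MS)), i1 + 1)
            prev_i2 = i2
            if i2 < 0:
                continue
            # rise over [i0, i1], fall over [i1, i2]; boundaries exactly at baseline
            jr = np.arange(max(i0, 0), min(i1, n_frames - 1) + 1)
            positions[jr] = 0.5 * p.amplitude * (
                1.0 - np.cos(np.pi * (jr - i0) / (i1 - i0))
            )
            jf = np.arange(max(i1, 0), min(i2, n_frames - 1) + 1)
            positions[jf] = 0.5 * p.amplitude * (
                1.0 + np.cos(np.pi * (jf - i1) / (i2 - i1))
            )
            if 0 <= i0 < n_frames:
                events.append((i0 * FRAME_MS, i1 * FRAME_MS, i2 * FRAME_MS))

    if p.fluct_sd > 0:
        positions = positions + _ou_process(n_frames, p.fluct_sd, p.fluct_tau, rng)

    return BeatTrajectory(times=times, positions=positions, event_log=events, params=params)


# ---------------------------------------------------------------------------
# preset table

_PARAM_KEYS = {
    "t_eff_ms": "t_eff",
    "t_rec_ms": "t_rec",
    "interval_mean_ms": "interval_mean",
    "interval_sigma_log": "interval_sigma_log",
    "amplitude_um": "amplitude",
    "default_mode": "mode",
    "target_cbf_hz": "target_cbf",
    "fluct_sd_um": "fluct_sd",
    "fluct_tau_ms": "fluct_tau",
}
_RECORD_KEYS = {"label", "group", "n_cilia", "n_intervals"} | set(_PARAM_KEYS)
_REQUIRED = {"label", "n_cilia", "t_eff_ms", "t_rec_ms", "interval_mean_ms", "amplitude_um"}


def load_preset_table(path=None) -> list[ConditionPreset]:
    """Load condition presets from a YAML file (bundled table by default)."""
    if path is None:
        text = (
            importlib.resources.files("ciliabeat") / "data" / "presets.yaml"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "presets" not in doc:
        raise ConfigurationError("preset file must contain a top-level 'presets' list")
    records = doc["presets"]
    if not records:
        raise ConfigurationError("preset table is empty")
    presets: list[ConditionPreset] = []
    seen: set[str] = set()
    for rec in records:
        unknown = set(rec) - _RECORD_KEYS
        if unknown:
            raise ConfigurationError(
                f"unknown preset field(s): {sorted(unknown)} in record {rec.get('label')!r}"
            )
        missing = _REQUIRED - set(rec)
        if missing:
            raise ConfigurationError(
                f"preset record {rec.get('label')!r} missing required field(s): {sorted(missing)}"
            )
        label = str(rec["label"])
        if label in seen:
            raise ConfigurationError(f"duplicate preset label {label!r}")
        seen.add(label)
        kwargs = {v: rec[k] for k, v in _PARAM_KEYS.items() if k in rec}
        params = BeatParameters(**kwargs)
        presets.append(
            ConditionPreset(
                label=label,
                params=params,
                n_cilia=int(rec["n_cilia"]),
                group=str(rec.get("group", "")),
                n_intervals=rec.get("n_intervals"),
            )
        )
    return presets


def get_preset(label: str, table: Sequence[ConditionPreset] | None = None) -> ConditionPreset:
    table = load_preset_table() if table is None else table
    for p in table:
        if p.label == label:
            return p
    raise KeyError(f"no preset labelled {label!r}")


def export_trajectory_csv(traj: BeatTrajectory, path, events_path=None) -> None:
    """Write a trajectory as CSV (time_ms, position_um) plus an event sidecar."""
    import pandas as pd

    pd.DataFrame({"time_ms": traj.times, "position_um": traj.positions}).to_csv(
        path, index=False
    )
    if events_path is not None:
        pd.DataFrame(
            traj.event_log,
            columns=["effective_start_ms", "peak_ms", "recovery_end_ms"],
        ).to_csv(events_path, index=False)
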