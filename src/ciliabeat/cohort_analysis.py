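"""Condition-level aggregation: cohort means, ratios, and significance tests.

Per-cilium beat measurements are aggregated into condition summaries
(mean ± sample SD of CBF and CBD, stroke durations, pooled interval
statistics), normalized to the pH 7.4 reference condition, and compared with
Welch t-tests or one-way ANOVA.  ``reproduce_paper`` drives the full
simulate → render → quantify → aggregate pipeline across every bundled
preset in both simulation modes and writes tidy CSV tables, plots and an
acceptance report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import beat_kinematics as bk
from . import kymo_quant as kq
from . import stroke_metrics as sm
from . import video_synth as vs
from .pipeline_io import derive_rng

REFERENCE_LABEL = "pH7.4"


@dataclass
class CiliumResult:
    """Everything measured from one synthetic recording."""

    trace: kq.PositionTrace
    measurement: kq.BeatMeasurement
    beats: kq.BeatSet
    events: list[sm.BeatEvent]
    truth: bk.BeatTrajectory
    line_offset: float


@dataclass
class ConditionSummary:
    """Per-condition cohort statistics."""

    label: str
    n_cilia: int
    cbf_mean: float
    cbf_sd: float
    cbd_mean: float
    cbd_sd: float
    cbf_ratio: float | None = None
    cbd_ratio: float | None = None
    t_eff_mean: float = float("nan")
    t_rec_mean: float = float("nan")
    interval_mean: float = float("nan")
    interval_min: float = float("nan")
    interval_max: float = float("nan")
    n_intervals: int = 0
    fluct_range_um: float = float("nan")


# ---------------------------------------------------------------------------
# simulation + measurement plumbing


def simulate_measure_cilium(
    params: bk.BeatParameters,
    master_seed: int,
    condition_index: int,
    cilium_index: int,
    record_index: int = 0,
    duration_s: float = 2.0,
    geometry: vs.CiliumGeometry | None = None,
    imaging: vs.ImagingConfig | None = None,
    noise: bool = True,
    min_prominence: float = kq.DEFAULT_MIN_PROMINENCE,
    min_separation: float = kq.DEFAULT_MIN_SEPARATION,
    velocity_fraction: float = 0.1,
) -> CiliumResult:
    """Simulate one cilium recording and run the full quantification on it."""
    geometry = geometry or vs.CiliumGeometry()
    imaging = imaging or vs.ImagingConfig()
    if not noise:
        imaging = replace(imaging, noise_sd=0.0, shot_noise=False)
    traj_rng = derive_rng(master_seed, condition_index, cilium_index, record_index, 0)
    noise_rng = derive_rng(master_seed, condition_index, cilium_index, record_index, 1)
    traj = bk.build_trajectory(params, duration_s, traj_rng)
    stack = vs.render_stack(traj, geometry, imaging, noise_rng if noise else None)
    line, offset = kq.scanline_for(geometry, amplitude=max(params.amplitude, 0.5))
    trace = kq.extract_trace(stack, line)
    meas, beats = kq.measure_trace(
        trace,
        record_duration=duration_s,
        min_prominence=min_prominence,
        min_separation=min_separation,
    )
    seg = sm.segment_strokes(trace, beats, velocity_fraction, cilium_id=cilium_index)
    return CiliumResult(
        trace=trace,
        measurement=meas,
        beats=beats,
        events=seg.events,
        truth=traj,
        line_offset=offset,
    )


def simulate_condition(
    preset: bk.ConditionPreset,
    mode: str,
    master_seed: int,
    condition_index: int,
    n_cilia: int | None = None,
    n_records: int = 1,
    duration_s: float = 2.0,
    noise: bool = True,
    **kwargs,
) -> list[CiliumResult]:
    """Simulate and quantify a cohort for one condition preset."""
    params = preset.params if mode is None else preset.params.with_mode(mode)
    n_cilia = preset.n_cilia if n_cilia is None else n_cilia
    results = []
    for ci in range(n_cilia):
        for rec in range(n_records):
            results.append(
                simulate_measure_cilium(
                    params,
                    master_seed,
                    condition_index,
                    ci,
                    record_index=rec,
                    duration_s=duration_s,
                    noise=noise,
                    **kwargs,
                )
            )
    return results


# ---------------------------------------------------------------------------
# aggregation


def summarize_condition(
    results_or_measurements,
    label: str,
    events: list[list[sm.BeatEvent]] | None = None,
) -> ConditionSummary:
    """Cohort means and sample SDs for one condition.

    Accepts a list of :class:`CiliumResult` (events taken from them) or a
    bare list of :class:`~ciliabeat.kymo_quant.BeatMeasurement` plus optional
    per-cilium event lists.  A single cilium gets SD 0 by convention.
    """
    items = list(results_or_measurements)
    if not items:
        raise ValueError("empty condition: nothing to summarize")
    if isinstance(items[0], CiliumResult):
        meas = [r.measurement for r in items]
        ev_lists = [r.events for r in items]
        ranges = [float(np.ptp(r.trace.positions)) for r in items]
    else:
        meas = items
        ev_lists = events or []
        ranges = []

    cbfs = np.array([m.cbf for m in meas])
    cbds = np.array([m.cbd for m in meas])
    defined = ~np.isnan(cbds)

    def _sd(a):
        return float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    # stroke durations: per-cilium mean over up to 10 beats, then cohort mean
    t_effs, t_recs = [], []
    for evs in ev_lists:
        if evs:
            t_effs.append(float(np.mean([e.t_eff_measured for e in evs[:10]])))
            t_recs.append(float(np.mean([e.t_rec_measured for e in evs[:10]])))
    try:
        isum = sm.summarize_intervals(ev_lists)
        imean, imin, imax, n_int = isum.mean_ms, isum.min_ms, isum.max_ms, isum.n
    except ValueError:
        imean = imin = imax = float("nan")
        n_int = 0

    return ConditionSummary(
        label=label,
        n_cilia=len(meas),
        cbf_mean=float(cbfs.mean()),
        cbf_sd=_sd(cbfs),
        cbd_mean=float(cbds[defined].mean()) if defined.any() else float("nan"),
        cbd_sd=_sd(cbds[defined]) if defined.sum() > 1 else 0.0,
        t_eff_mean=float(np.mean(t_effs)) if t_effs else float("nan"),
        t_rec_mean=float(np.mean(t_recs)) if t_recs else float("nan"),
        interval_mean=imean,
        interval_min=imin,
        interval_max=imax,
        n_intervals=n_int,
        fluct_range_um=float(np.mean(ranges)) if ranges else float("nan"),
    )


def normalize_to_reference(
    summaries: list[ConditionSummary], reference_label: str = REFERENCE_LABEL
) -> list[ConditionSummary]:
    """Attach CBF and CBD ratios relative to the reference condition."""
    ref = next((s for s in summaries if s.label == reference_label), None)
    if ref is None:
        raise ValueError(f"reference condition {reference_label!r} not present")
    if not ref.cbf_mean > 0 or not ref.cbd_mean > 0:
        raise ValueError(f"reference condition {reference_label!r} has zero mean")
    out = []
    for s in summaries:
        out.append(
            replace(
                s,
                cbf_ratio=s.cbf_mean / ref.cbf_mean,
                cbd_ratio=s.cbd_mean / ref.cbd_mean,
            )
        )
    return out


# ---------------------------------------------------------------------------
# significance tests (explicit formulas; scipy serves as the test oracle)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class FTestResult:
    F: float
    df_between: int
    df_within: int
    p: float


def welch_t_test(group_a, group_b) -> TTestResult:
    """Unpaired Welch t-test with Satterthwaite degrees of freedom.

    Degenerate inputs (either group smaller than 2, or both groups with zero
    variance and equal means) return the defined outputs t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return TTestResult(t=0.0, df=float(max(na + nb - 2, 1)), p=1.0)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=float(na + nb - 2), p=1.0)
        return TTestResult(t=math.copysign(math.inf, diff), df=float(na + nb - 2), p=0.0)
    t = diff / math.sqrt(se2)
    df = se2 * se2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def paired_t_test(x, y) -> TTestResult:
    """Paired t-test on matched samples; (x, x) pairs give t = 0, p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired test needs equal-length samples")
    d = x - y
    n = len(d)
    if n < 2:
        return TTestResult(t=0.0, df=1.0, p=1.0)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(t=0.0, df=float(n - 1), p=1.0)
        return TTestResult(t=math.copysign(math.inf, d.mean()), df=float(n - 1), p=0.0)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=float(n - 1), p=float(p))


def one_way_anova(groups) -> FTestResult:
    """One-way ANOVA across two or more groups.

    All-identical constant groups (zero within- and between-variance) return
    the defined outputs F = 0, p = 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs at least 2 observations")
    k = len(gs)
    n = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            return FTestResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return FTestResult(F=math.inf, df_between=df_b, df_within=df_w, p=0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(F, df_b, df_w)
    return FTestResult(F=float(F), df_between=df_b, df_within=df_w, p=float(p))


# ---------------------------------------------------------------------------
# headline-number recomputation (acceptance targets) and full reproduction

#: reference values encoded by the bundled presets, for the acceptance report
PRINTED = {
    "t1": ("pH7.0 cohort mean CBF (Hz), rate_matched", 3.4, "±10%"),
    "t2": ("pH8.0 cohort mean CBF (Hz), rate_matched", 15.4, "±10%"),
    "t3": ("pH7.0 cohort mean CBD (µm)", 0.57, "±10%"),
    "t4": ("pH8.0 cohort mean CBD (µm)", 1.45, "±10%"),
    "t5": ("CBF ratio pH7.0 / pH7.4", 0.37, "±0.08"),
    "t6": ("CBD ratio pH7.0 / pH7.4", 0.60, "±0.08"),
    "t7": ("pooled mean interval at pH7.0 (ms), component_matched", 234.0, "±15%"),
    "t8": ("pooled mean interval at pH8.0 (ms), component_matched", 31.0, "±15%"),
    "t9": ("mean effective-stroke duration at pH7.0 (ms)", 136.0, "±8 ms"),
    "t10": ("mean effective-stroke duration at pH7.4 (ms)", 44.0, "±8 ms"),
    "t11": ("representative pH8.0 single-cilium CBF (Hz)", 12.0, "±1 Hz"),
    "t12": ("ATP-only 2.5 mM cohort mean CBF (Hz)", 1.44, "±15%"),
}


def compute_targets(master_seed: int) -> dict[str, dict[str, float]]:
    """Recompute every headline quantity from scratch through the full pipeline.

    Each entry gives the recovered value (on the reported scale/units) and
    the problem size used (cilia for cohort means, pooled intervals or beats
    for duration statistics).
    """
    table = bk.load_preset_table()
    cidx = {p.label: i for i, p in enumerate(table)}

    def preset(label):
        return bk.get_preset(label, table)

    out: dict[str, dict[str, float]] = {}

    # cohort CBF/CBD and ratios: rate_matched, 2 s records, cohort n as reported
    cohorts = {}
    for label in ("pH7.0", "pH8.0", "pH7.4"):
        res = simulate_condition(
            preset(label), "rate_matched", master_seed, cidx[label]
        )
        cohorts[label] = summarize_condition(res, label)
    out["t1"] = {"value": cohorts["pH7.0"].cbf_mean, "n": cohorts["pH7.0"].n_cilia}
    out["t2"] = {"value": cohorts["pH8.0"].cbf_mean, "n": cohorts["pH8.0"].n_cilia}
    out["t3"] = {"value": cohorts["pH7.0"].cbd_mean, "n": cohorts["pH7.0"].n_cilia}
    out["t4"] = {"value": cohorts["pH8.0"].cbd_mean, "n": cohorts["pH8.0"].n_cilia}
    normed = normalize_to_reference(
        [cohorts["pH7.0"], cohorts["pH7.4"], cohorts["pH8.0"]]
    )
    s70 = next(s for s in normed if s.label == "pH7.0")
    out["t5"] = {"value": s70.cbf_ratio, "n": cohorts["pH7.4"].n_cilia}
    out["t6"] = {"value": s70.cbd_ratio, "n": cohorts["pH7.4"].n_cilia}

    # pooled inter-beat intervals: component_matched, 3 cilia, longer records
    for tid, label, n_rec, dur in (
        ("t7", "pH7.0", 2, 5.0),
        ("t8", "pH8.0", 1, 3.5),
    ):
        res = simulate_condition(
            preset(label),
            "component_matched",
            master_seed + 1,
            cidx[label],
            n_cilia=3,
            n_records=n_rec,
            duration_s=dur,
        )
        isum = sm.summarize_intervals([r.events for r in res])
        out[tid] = {"value": isum.mean_ms, "n": isum.n}

    # effective-stroke durations: noise-free renders, zero interval variance
    for tid, label, dur in (("t9", "pH7.0", 5.0), ("t10", "pH7.4", 2.6)):
        p = replace(
            preset(label).params.with_mode("component_matched"),
            interval_sigma_log=0.0,
        )
        r = simulate_measure_cilium(
            p, master_seed + 2, cidx[label], 0, duration_s=dur, noise=False
        )
        t_effs = [e.t_eff_measured for e in r.events[:10]]
        out[tid] = {"value": float(np.mean(t_effs)), "n": len(t_effs)}

    # representative single cilium, pH 8.0
    r = simulate_measure_cilium(
        preset("rep_pH8.0").params,
        master_seed + 3,
        cidx["rep_pH8.0"],
        0,
        duration_s=2.0,
    )
    out["t11"] = {"value": r.measurement.cbf, "n": 1}

    # ATP alone, 2.5 mM, sparse-beat regime: at ~1.4 Hz a single 2 s record
    # holds only ~3 beats, so each cilium is observed over three consecutive
    # 2 s records (6 s total) and its CBF is the mean over records
    n_rec = 3
    res = simulate_condition(
        preset("ATP2.5"),
        "rate_matched",
        master_seed + 4,
        cidx["ATP2.5"],
        n_records=n_rec,
    )
    cbf_per_cilium = [
        float(np.mean([r.measurement.cbf for r in res[i : i + n_rec]]))
        for i in range(0, len(res), n_rec)
    ]
    out["t12"] = {"value": float(np.mean(cbf_per_cilium)), "n": len(cbf_per_cilium)}
    return out


def _summary_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [s.label for s in summaries],
            "n_cilia": [s.n_cilia for s in summaries],
            "cbf_mean_hz": [s.cbf_mean for s in summaries],
            "cbf_sd_hz": [s.cbf_sd for s in summaries],
            "cbd_mean_um": [s.cbd_mean for s in summaries],
            "cbd_sd_um": [s.cbd_sd for s in summaries],
            "cbf_ratio": [s.cbf_ratio for s in summaries],
            "cbd_ratio": [s.cbd_ratio for s in summaries],
            "t_eff_mean_ms": [s.t_eff_mean for s in summaries],
            "t_rec_mean_ms": [s.t_rec_mean for s in summaries],
            "interval_mean_ms": [s.interval_mean for s in summaries],
            "interval_min_ms": [s.interval_min for s in summaries],
            "interval_max_ms": [s.interval_max for s in summaries],
            "n_intervals": [s.n_intervals for s in summaries],
            "fluct_range_um": [s.fluct_range_um for s in summaries],
        }
    )


def reproduce_paper(
    master_seed: int,
    out_dir,
    groups: tuple[str, ...] = ("ph_series", "atp_series", "null", "representative"),
    make_plots: bool = True,
    include_targets: bool = True,
) -> dict:
    """Run the full simulate → quantify → aggregate pipeline for all presets.

    Writes condition-summary CSVs per group and mode, ratio tables,
    significance tests, figure analogues (dose-response, pH response,
    stroke durations, intervals, null conditions) and an acceptance report
    comparing every recovered headline number to its encoded reference value.
    Outputs are deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = [p for p in bk.load_preset_table() if p.group in groups]
    full_table = bk.load_preset_table()
    cidx = {p.label: i for i, p in enumerate(full_table)}

    # rate_matched cohorts at 2 s: CBF/CBD per condition
    rate_summaries: list[ConditionSummary] = []
    percilium_cbf: dict[str, np.ndarray] = {}
    for p in table:
        mode = "rate_matched" if p.params.target_cbf else "component_matched"
        # sparse / null regimes carry few events per 2 s record; observe each
        # cilium over three records there
        n_rec = 3 if p.group in ("atp_series", "null") else 1
        res = simulate_condition(p, mode, master_seed, cidx[p.label], n_records=n_rec)
        s = summarize_condition(res, p.label)
        s = replace(s, n_cilia=p.n_cilia)
        rate_summaries.append(s)
        percilium_cbf[p.label] = np.array([r.measurement.cbf for r in res])
    ph_labels = [p.label for p in table if p.group == "ph_series"]
    if REFERENCE_LABEL in [s.label for s in rate_summaries]:
        rate_summaries = normalize_to_reference(rate_summaries)
    _summary_frame(rate_summaries).to_csv(out / "condition_summaries_rate.csv", index=False)

    # component_matched runs for the pH series: stroke durations + intervals
    comp_summaries: list[ConditionSummary] = []
    for p in table:
        if p.group != "ph_series":
            continue
        cyc = p.params.expected_cycle_ms if p.params.beating else 1000.0
        dur = min(6.0, max(2.0, (12 * cyc + 500) / 1000.0))
        res = simulate_condition(
            p,
            "component_matched",
            master_seed + 10,
            cidx[p.label],
            n_cilia=3,
            duration_s=dur,
        )
        comp_summaries.append(summarize_condition(res, p.label))
    if comp_summaries:
        _summary_frame(comp_summaries).to_csv(
            out / "condition_summaries_component.csv", index=False
        )

    # significance tests
    tests = []
    if len(ph_labels) >= 2:
        anova = one_way_anova([percilium_cbf[l] for l in ph_labels])
        tests.append(
            {
                "test": "one_way_anova_cbf_ph_series",
                "stat": anova.F,
                "df1": anova.df_between,
                "df2": anova.df_within,
                "p": anova.p,
            }
        )
        w = welch_t_test(percilium_cbf[ph_labels[0]], percilium_cbf[ph_labels[-1]])
        tests.append(
            {
                "test": f"welch_cbf_{ph_labels[0]}_vs_{ph_labels[-1]}",
                "stat": w.t,
                "df1": w.df,
                "df2": float("nan"),
                "p": w.p,
            }
        )
    if tests:
        pd.DataFrame(tests).to_csv(out / "significance_tests.csv", index=False)

    # acceptance report against the encoded reference values
    targets: dict = {}
    report = pd.DataFrame()
    if include_targets:
        targets = compute_targets(master_seed)
        rows = []
        for tid, (desc, printed, tol) in PRINTED.items():
            rec = targets.get(tid, {}).get("value", float("nan"))
            if tol.endswith("%"):
                band = abs(printed) * float(tol.strip("±%")) / 100.0
            else:
                band = float(tol.strip("± ").split()[0])
            rows.append(
                {
                    "target": tid,
                    "description": desc,
                    "recovered": rec,
                    "reference": printed,
                    "tolerance": tol,
                    "pass": bool(abs(rec - printed) <= band),
                }
            )
        report = pd.DataFrame(rows)
        report.to_csv(out / "acceptance_report.csv", index=False)

    if make_plots:
        _make_plots(rate_summaries, comp_summaries, out)

    return {
        "rate_summaries": rate_summaries,
        "component_summaries": comp_summaries,
        "targets": targets,
        "report": report,
    }


def _make_plots(rate_summaries, comp_summaries, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by = {s.label: s for s in rate_summaries}

    def _series(labels, attr):
        return [getattr(by[l], attr) for l in labels if l in by]

    ph = [l for l in ("pH7.0", "pH7.2", "pH7.4", "pH7.6", "pH7.8", "pH8.0") if l in by]
    if ph:
        phx = [float(l[2:]) for l in ph]
        fig, ax = plt.subplots(1, 2, figsize=(8, 3.2))
        ax[0].errorbar(phx, _series(ph, "cbf_mean"), yerr=_series(ph, "cbf_sd"), marker="o")
        ax[0].set(xlabel="pH", ylabel="CBF (Hz)")
        ax[1].errorbar(phx, _series(ph, "cbd_mean"), yerr=_series(ph, "cbd_sd"), marker="o", color="C1")
        ax[1].set(xlabel="pH", ylabel="CBD (µm)")
        fig.tight_layout()
        fig.savefig(out / "ph_cbf_cbd.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4.2, 3.2))
        ax.plot(phx, _series(ph, "cbf_ratio"), marker="o", label="CBF ratio")
        ax.plot(phx, _series(ph, "cbd_ratio"), marker="s", label="CBD ratio")
        ax.axhline(1.0, color="gray", lw=0.8)
        ax.set(xlabel="pH", ylabel="ratio vs pH 7.4")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "ph_ratios.png", dpi=120)
        plt.close(fig)

    atp = [l for l in ("ATP0.5", "ATP2.5", "ATP7.5", "ATP10") if l in by]
    if atp:
        conc = [float(l[3:]) for l in atp]
        fig, ax = plt.subplots(figsize=(4.2, 3.2))
        ax.errorbar(conc, _series(atp, "cbf_mean"), yerr=_series(atp, "cbf_sd"), marker="o")
        ax.set(xlabel="ATP (mM)", ylabel="CBF (Hz)")
        fig.tight_layout()
        fig.savefig(out / "atp_dose_response.png", dpi=120)
        plt.close(fig)

    nulls = [l for l in ("unstimulated", "ATPgS", "PKI_pre") if l in by]
    if nulls:
        fig, ax = plt.subplots(figsize=(4.2, 3.2))
        ax.bar(nulls, _series(nulls, "cbf_mean"))
        ax.set(ylabel="CBF (Hz)")
        fig.tight_layout()
        fig.savefig(out / "null_conditions.png", dpi=120)
        plt.close(fig)

    cby = {s.label: s for s in comp_summaries}
    cph = [l for l in ("pH7.0", "pH7.2", "pH7.4", "pH7.6", "pH7.8", "pH8.0") if l in cby]
    if cph:
        phx = [float(l[2:]) for l in cph]
        fig, ax = plt.subplots(1, 2, figsize=(8, 3.2))
        ax[0].plot(phx, [cby[l].t_eff_mean for l in cph], marker="o", label="effective")
        ax[0].plot(phx, [cby[l].t_rec_mean for l in cph], marker="s", label="recovery")
        ax[0].set(xlabel="pH", ylabel="stroke duration (ms)")
        ax[0].legend()
        ax[1].plot(phx, [cby[l].interval_mean for l in cph], marker="o", color="C2")
        ax[1].set(xlabel="pH", ylabel="inter-beat interval (ms)")
        fig.tight_layout()
        fig.savefig(out / "stroke_durations_intervals.png", dpi=120)
        plt.close(fig)
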