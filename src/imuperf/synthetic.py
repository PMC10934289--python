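"""Seeded synthetic IMU traces and cohort tables with known ground truth.

Two generators back the rest of the package:

* :func:`generate_trace` builds a tri-axial accelerometer/gyroscope trace for
  one clinical test (30 s Sit-to-Stand, six-minute walk, Timed Up and Go) as a
  gravity-inclusive vertical baseline plus one raised-cosine pulse per motion
  event, preceded by a static lead-in.  The realized event times and peak
  values are returned alongside the trace so feature extraction can be checked
  against truth.
* :func:`generate_cohort` draws an older-adult cohort whose per-group feature
  distributions follow three latent physical-performance levels, with faller
  and frailty-phenotype labels drawn at stated per-group probabilities.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_COLUMNS, ImuTrace

__all__ = [
    "TraceSpec",
    "TraceTruth",
    "GroupSpec",
    "generate_trace",
    "generate_cohort",
    "sts_trace_spec",
    "gait_trace_spec",
    "tug_trace_spec",
    "default_cohort_spec",
    "write_trace",
    "read_trace",
    "write_truth",
    "read_truth",
    "write_cohort",
    "read_cohort",
]

PROTOCOLS = ("STS30", "SIXMWT", "TUG")

#: nominal active duration (s) appended after the static lead-in, per protocol
_NOMINAL_DURATION = {"STS30": 30.0, "SIXMWT": 360.0, "TUG": 0.0}

COHORT_COLUMNS = [
    "participant_id",
    "group_truth",
    "sex",
    "age",
    "height_cm",
    "body_mass_kg",
    "faller",
    "frailty",
    *FEATURE_COLUMNS,
]

#: physiologic floors for truncated resampling (value must be > floor,
#: or >= floor for counts)
_FEATURE_FLOORS = {
    "sts_count": 0.0,
    "sts_peak_accel_mean": 0.0,
    "six_mwt_distance": 0.0,
    "step_duration_mean": 0.0,
    "step_length_mean": 0.0,
    "tug_comfort_s": 0.0,
    "tug_fast_s": 0.0,
}


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    """Recipe for one synthetic test recording.

    ``event_times`` are pulse centers in seconds (snapped to the sample grid
    unless ``snap_to_grid`` is off); ``peak_amplitudes`` are pulse heights
    above the vertical baseline, so the recorded vertical maximum of event *i*
    is ``gravity_offset + peak_amplitudes[i]``.
    """

    protocol: str
    event_times: tuple[float, ...] = ()
    peak_amplitudes: tuple[float, ...] = ()
    sampling_rate: float = 26.0
    static_lead_s: float = 10.0
    tail_s: float = 5.0
    pulse_width_s: float = 0.6
    noise_sd: float = 0.0
    gravity_offset: float = 9.81
    seed: int = 0
    snap_to_grid: bool = True

    def validate(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}; expected one of {PROTOCOLS}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pulse_width_s <= 0:
            raise ValueError("pulse_width_s must be > 0")
        ev = np.asarray(self.event_times, dtype=float)
        if len(self.peak_amplitudes) != ev.size:
            raise ValueError("event_times and peak_amplitudes must have equal length")
        if ev.size:
            if np.any(np.diff(ev) <= 0):
                raise ValueError("event_times must be strictly increasing")
            if np.any(np.diff(ev) < 2.0 / self.sampling_rate):
                raise ValueError("events closer together than 2 samples are rejected")
            if ev[0] <= self.static_lead_s:
                raise ValueError("all event_times must fall after the static lead-in")


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth emitted with every generated trace."""

    protocol: str
    event_times: tuple[float, ...]
    peak_values: tuple[float, ...]  # absolute vertical acceleration at the peaks
    onset_time: float  # start of the first pulse
    termination_time: float  # end of the last pulse
    sampling_rate: float

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "event_times": list(self.event_times),
            "peak_values": list(self.peak_values),
            "onset_time": self.onset_time,
            "termination_time": self.termination_time,
            "sampling_rate": self.sampling_rate,
        }


def _snap(times: np.ndarray, fs: float) -> np.ndarray:
    return np.round(np.asarray(times, dtype=float) * fs) / fs


def generate_trace(spec: TraceSpec) -> tuple[ImuTrace, TraceTruth]:
    """Synthesize one IMU trace plus its ground truth.

    The vertical (z) channel is ``gravity_offset`` plus Gaussian noise, with a
    raised-cosine pulse of width ``pulse_width_s`` per event.  Horizontal
    accelerometer channels and the gyroscope carry zero-mean noise only; no
    downstream feature reads them.
    """
    spec.validate()
    fs = spec.sampling_rate
    events = np.asarray(spec.event_times, dtype=float)
    if spec.snap_to_grid and events.size:
        events = _snap(events, fs)
        if np.any(np.diff(events) < 2.0 / fs - 1e-12):
            raise ValueError("events closer together than 2 samples after grid snapping")
    amps = np.asarray(spec.peak_amplitudes, dtype=float)

    w = spec.pulse_width_s
    last = events[-1] + w / 2.0 if events.size else spec.static_lead_s
    duration = max(last, spec.static_lead_s + _NOMINAL_DURATION[spec.protocol]) + spec.tail_s
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    z = np.full(n, spec.gravity_offset, dtype=float)
    for c, a in zip(events, amps):
        lo = max(0, int(math.ceil((c - w / 2.0) * fs)))
        hi = min(n - 1, int(math.floor((c + w / 2.0) * fs)))
        seg = t[lo : hi + 1]
        z[lo : hi + 1] += a / 2.0 * (1.0 + np.cos(2.0 * np.pi * (seg - c) / w))

    rng = np.random.default_rng(spec.seed)
    accel = np.empty((n, 3))
    accel[:, 0] = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else 0.0
    accel[:, 1] = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else 0.0
    accel[:, 2] = z + (rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd else 0.0)
    gyro = rng.normal(0.0, spec.noise_sd * 10.0, (n, 3)) if spec.noise_sd else np.zeros((n, 3))

    trace = ImuTrace(t=t, accel=accel, gyro=gyro, sampling_rate=fs)
    truth = TraceTruth(
        protocol=spec.protocol,
        event_times=tuple(events.tolist()),
        peak_values=tuple((spec.gravity_offset + amps).tolist()),
        onset_time=float(events[0] - w / 2.0) if events.size else float("nan"),
        termination_time=float(events[-1] + w / 2.0) if events.size else float("nan"),
        sampling_rate=fs,
    )
    return trace, truth


def sts_trace_spec(
    n_sts: int = 11,
    *,
    mean_peak: float = 13.0,
    peak_sd: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    window_s: float = 30.0,
    gravity_offset: float = 9.81,
    sampling_rate: float = 26.0,
    static_lead_s: float = 10.0,
) -> TraceSpec:
    """Spec for a 30 s Sit-to-Stand test with ``n_sts`` evenly spaced rises.

    ``mean_peak`` is the absolute vertical acceleration at the pulse maxima
    (gravity-inclusive, so 13 m/s^2 is ~3.2 m/s^2 above standing baseline).
    """
    rng = np.random.default_rng(seed)
    if n_sts > 0:
        first = static_lead_s + 1.5
        span = window_s - 3.0
        times = first + np.arange(n_sts) * (span / max(n_sts - 1, 1) if n_sts > 1 else 0.0)
        amps = np.maximum(mean_peak - gravity_offset + rng.normal(0.0, peak_sd, n_sts), 0.3)
    else:
        times, amps = np.array([]), np.array([])
    return TraceSpec(
        protocol="STS30",
        event_times=tuple(times.tolist()),
        peak_amplitudes=tuple(amps.tolist()),
        sampling_rate=sampling_rate,
        static_lead_s=static_lead_s,
        pulse_width_s=0.6,
        noise_sd=noise_sd,
        gravity_offset=gravity_offset,
        seed=seed,
    )


def gait_trace_spec(
    distance_m: float = 430.0,
    *,
    step_length_m: float = 0.68,
    step_duration_s: float = 0.48,
    step_peak_above_baseline: float = 2.5,
    shuttle_length_m: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    gravity_offset: float = 9.81,
    sampling_rate: float = 26.0,
    static_lead_s: float = 10.0,
) -> tuple[TraceSpec, list[float], int, float]:
    """Spec for a shuttle-walk trace (six-minute walk protocol).

    Returns ``(spec, shuttle_marks, n_full_shuttles, partial_m)``.  The walker
    advances ``step_length_m`` at each step peak; a shuttle mark is placed at
    the peak time of the step that completes each ``shuttle_length_m`` leg, so
    a boundary step belongs to the shuttle it closes.
    """
    if distance_m < 0 or step_length_m <= 0 or step_duration_s <= 0:
        raise ValueError("distance, step length and step duration must be positive")
    n_steps = int(math.floor(distance_m / step_length_m))
    times = static_lead_s + 0.5 + np.arange(n_steps) * step_duration_s
    if (times.size and times[-1] + step_duration_s > static_lead_s + _NOMINAL_DURATION["SIXMWT"]):
        # walker slower than the 6 min budget: truncate to the time window
        keep = times + step_duration_s <= static_lead_s + _NOMINAL_DURATION["SIXMWT"]
        times = times[keep]
        n_steps = times.size
    fs = sampling_rate
    snapped = _snap(times, fs)
    positions = (np.arange(n_steps) + 1) * step_length_m
    n_full = int(math.floor(positions[-1] / shuttle_length_m)) if n_steps else 0
    marks = []
    for j in range(1, n_full + 1):
        idx = int(np.searchsorted(positions, j * shuttle_length_m - 1e-9))
        marks.append(float(snapped[idx]))
    partial_m = float(positions[-1] - n_full * shuttle_length_m) if n_steps else 0.0
    spec = TraceSpec(
        protocol="SIXMWT",
        event_times=tuple(snapped.tolist()),
        peak_amplitudes=tuple(np.full(n_steps, step_peak_above_baseline).tolist()),
        sampling_rate=fs,
        static_lead_s=static_lead_s,
        pulse_width_s=0.25,
        noise_sd=noise_sd,
        gravity_offset=gravity_offset,
        seed=seed,
    )
    return spec, marks, n_full, partial_m


def tug_trace_spec(
    duration_s: float = 8.9,
    *,
    start_offset_s: float = 0.5,
    stand_peak_above_baseline: float = 3.0,
    step_peak_above_baseline: float = 2.0,
    step_duration_s: float = 0.55,
    noise_sd: float = 0.0,
    seed: int = 0,
    gravity_offset: float = 9.81,
    sampling_rate: float = 26.0,
    static_lead_s: float = 10.0,
) -> TraceSpec:
    """Spec for a Timed Up and Go trace of total movement time ``duration_s``.

    A stand pulse opens the movement, a sit pulse closes it, and walking step
    pulses fill the interval; motion onset is the stand-pulse start and
    termination the sit-pulse end, ``duration_s`` apart.
    """
    if duration_s <= 2.0:
        raise ValueError("TUG duration must exceed the stand+sit pulse span")
    w = 0.6
    t0 = static_lead_s + start_offset_s
    stand_c = t0 + w / 2.0
    sit_c = t0 + duration_s - w / 2.0
    walk_lo, walk_hi = stand_c + w, sit_c - w
    steps = []
    c = walk_lo
    while c <= walk_hi:
        steps.append(c)
        c += step_duration_s
    times = np.array([stand_c, *steps, sit_c])
    amps = np.array(
        [stand_peak_above_baseline]
        + [step_peak_above_baseline] * len(steps)
        + [stand_peak_above_baseline]
    )
    return TraceSpec(
        protocol="TUG",
        event_times=tuple(times.tolist()),
        peak_amplitudes=tuple(amps.tolist()),
        sampling_rate=sampling_rate,
        static_lead_s=static_lead_s,
        pulse_width_s=w,
        noise_sd=noise_sd,
        gravity_offset=gravity_offset,
        seed=seed,
        snap_to_grid=False,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Distributional recipe for one latent performance group."""

    label: str
    n: int
    feature_means: dict = field(default_factory=dict)
    feature_sds: dict = field(default_factory=dict)
    faller_prob: float = 0.4
    frailty_probs: tuple[float, float, float] = (0.3, 0.5, 0.2)  # robust, pre-frail, frail
    female_prob: float = 0.7
    age_mean: float = 74.0
    age_sd: float = 5.5
    height_mean_cm: float = 165.7
    height_sd_cm: float = 8.2
    mass_mean_kg: float = 68.9
    mass_sd_kg: float = 13.5

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        missing = [c for c in FEATURE_COLUMNS if c not in self.feature_means]
        if missing:
            raise ValueError(f"feature_means missing entries for {missing}")
        for c in FEATURE_COLUMNS:
            if self.feature_sds.get(c, 0.0) < 0:
                raise ValueError(f"negative SD for {c}")
            if self.feature_means[c] <= _FEATURE_FLOORS[c] and c != "sts_count":
                raise ValueError(f"non-physiologic mean for {c}: {self.feature_means[c]}")
        if abs(sum(self.frailty_probs) - 1.0) > 1e-9:
            raise ValueError("frailty_probs must sum to 1")
        if not 0.0 <= self.faller_prob <= 1.0:
            raise ValueError("faller_prob must be a probability")


def _truncated_normal(rng, mean, sd, size, floor, strict=True):
    """Resample (never clip) Gaussian draws until all clear the floor."""
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = (out <= floor) if strict else (out < floor)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError(f"truncated sampling did not converge (mean={mean}, sd={sd})")


def generate_cohort(groups: list[GroupSpec], seed: int = 0) -> pd.DataFrame:
    """Draw a cohort table from per-group independent Gaussians.

    Feature draws are truncated at physiologic floors by resampling; the
    Sit-to-Stand count is rounded to the nearest non-negative integer.  Faller
    and Fried-phenotype labels are Bernoulli/categorical at the per-group
    probabilities.  The latent group label is kept in ``group_truth``.
    """
    if not groups:
        raise ValueError("at least one GroupSpec is required")
    for g in groups:
        g.validate()
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for g in groups:
        feats = {}
        for c in FEATURE_COLUMNS:
            sd = g.feature_sds.get(c, 0.0)
            strict = c != "sts_count"
            if sd == 0.0:
                vals = np.full(g.n, float(g.feature_means[c]))
            else:
                vals = _truncated_normal(rng, g.feature_means[c], sd, g.n,
                                         _FEATURE_FLOORS[c], strict=strict)
            if c == "sts_count":
                vals = np.maximum(np.floor(vals + 0.5), 0.0)
            feats[c] = vals
        faller = rng.random(g.n) < g.faller_prob
        frailty = rng.choice(["robust", "pre-frail", "frail"], size=g.n,
                             p=list(g.frailty_probs))
        sex = np.where(rng.random(g.n) < g.female_prob, "F", "M")
        age = _truncated_normal(rng, g.age_mean, g.age_sd, g.n, 65.0, strict=False)
        height = _truncated_normal(rng, g.height_mean_cm, g.height_sd_cm, g.n, 120.0)
        mass = _truncated_normal(rng, g.mass_mean_kg, g.mass_sd_kg, g.n, 30.0)
        for i in range(g.n):
            rows.append({
                "participant_id": f"P{pid:03d}",
                "group_truth": g.label,
                "sex": sex[i],
                "age": float(age[i]),
                "height_cm": float(height[i]),
                "body_mass_kg": float(mass[i]),
                "faller": "yes" if faller[i] else "no",
                "frailty": str(frailty[i]),
                **{c: float(feats[c][i]) for c in FEATURE_COLUMNS},
            })
            pid += 1
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def default_cohort_spec() -> list[GroupSpec]:
    """The packaged three-group cohort recipe (synthetic; see data/synthetic_cohort.yaml)."""
    ref = importlib.resources.files("imuperf").joinpath("data/synthetic_cohort.yaml")
    cfg = yaml.safe_load(ref.read_text())
    return [
        GroupSpec(
            label=g["label"],
            n=int(g["n"]),
            feature_means={k: float(v) for k, v in g["feature_means"].items()},
            feature_sds={k: float(v) for k, v in g["feature_sds"].items()},
            faller_prob=float(g["faller_prob"]),
            frailty_probs=tuple(float(p) for p in g["frailty_probs"]),
            female_prob=float(g.get("female_prob", 0.7)),
            age_mean=float(g.get("age_mean", 74.0)),
            age_sd=float(g.get("age_sd", 5.5)),
        )
        for g in cfg["groups"]
    ]


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ["t_s", "ax", "ay", "az", "gx", "gy", "gz"]


def write_trace(path, trace: ImuTrace) -> None:
    """Write a trace as delimited text (columns t_s, ax..az, gx..gz)."""
    df = pd.DataFrame(
        np.column_stack([trace.t, trace.accel, trace.gyro]), columns=TRACE_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace(path) -> ImuTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} is missing columns {missing}")
    t = df["t_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"trace file {path} has fewer than 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ImuTrace(
        t=t,
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        sampling_rate=fs,
    )


def write_truth(path, truth: TraceTruth) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path) -> TraceTruth:
    with open(path) as fh:
        d = json.load(fh)
    return TraceTruth(
        protocol=d["protocol"],
        event_times=tuple(d["event_times"]),
        peak_values=tuple(d["peak_values"]),
        onset_time=d["onset_time"],
        termination_time=d["termination_time"],
        sampling_rate=d["sampling_rate"],
    )


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False, float_format="%.9g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns {missing}")
    return df
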