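"""Feature extraction from head-worn IMU traces of three clinical tests.

The seven functional/biomechanical parameters are

====================  =========  ==============================================
field                 unit       derivation
====================  =========  ==============================================
sts_count             count      vertical-acceleration peaks in the 30 s
                                 Sit-to-Stand window
sts_peak_accel_mean   m/s^2      mean vertical acceleration at those peaks
six_mwt_distance      m          full shuttles x shuttle length + partial metres
step_duration_mean    s          mean time between consecutive step peaks
step_length_mean      m          shuttle length / steps per shuttle, averaged
tug_comfort_s         s          Timed Up and Go, comfortable pace
tug_fast_s            s          Timed Up and Go, fast pace
====================  =========  ==============================================

Every test recording opens with a static lead-in (10 s by default) from which
a vertical-axis baseline (gravity-inclusive) is measured; motion onset and
termination are sustained departures from that baseline.  Peak detection runs
on a zero-phase low-passed copy of the vertical channel, but peak amplitudes
are always read back from the raw signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

__all__ = [
    "FEATURE_COLUMNS",
    "REQUIRED_PROTOCOLS",
    "ImuTrace",
    "PeakSet",
    "FeatureVector",
    "TestRecording",
    "detect_baseline",
    "detect_motion_onset",
    "detect_vertical_peaks",
    "sts_features",
    "gait_features",
    "six_mwt_distance",
    "tug_duration",
    "extract_features",
    "features_to_frame",
]

#: canonical feature ordering used by cohort tables and clustering
FEATURE_COLUMNS = [
    "sts_count",
    "sts_peak_accel_mean",
    "six_mwt_distance",
    "step_duration_mean",
    "step_length_mean",
    "tug_comfort_s",
    "tug_fast_s",
]

#: one recording of each is needed for a complete feature vector
REQUIRED_PROTOCOLS = ("STS30", "6MWT", "TUG_COMFORT", "TUG_FAST")

# onset-detection defaults: threshold max(K_SD * baseline SD, ABS_FLOOR m/s^2)
# sustained for SUSTAIN samples
K_SD = 4.0
ABS_FLOOR = 0.5
SUSTAIN = 3

# low-pass cutoffs (Hz) ahead of peak detection; 26 Hz sampling -> 13 Hz Nyquist
STS_CUTOFF_HZ = 5.0
GAIT_CUTOFF_HZ = 3.0

# peak-detection defaults per movement type
STS_MIN_SEPARATION_S = 1.0
STS_MIN_PROMINENCE = 1.0
STEP_MIN_SEPARATION_S = 0.3
STEP_MIN_PROMINENCE = 0.3


@dataclass(frozen=True)
class ImuTrace:
    """Uniformly sampled tri-axial accelerometer + gyroscope trace.

    Axes follow the device convention: x medio-lateral (left), y
    anterior-posterior (forward), z vertical (up); accelerations in m/s^2
    (gravity-inclusive on z), angular rates in deg/s.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("trace needs at least two samples")
        if self.accel.shape != (t.size, 3) or self.gyro.shape != (t.size, 3):
            raise ValueError("accel and gyro must be (n, 3) matching t")
        step = 1.0 / self.sampling_rate
        if np.any(np.abs(np.diff(t) - step) > 1e-6):
            raise ValueError("t must be a uniform grid at 1/sampling_rate")

    @property
    def vertical(self) -> np.ndarray:
        return self.accel[:, 2]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class PeakSet:
    """Detected vertical-acceleration peaks (amplitudes from the raw channel)."""

    indices: np.ndarray
    times: np.ndarray
    amplitudes: np.ndarray

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class FeatureVector:
    """The seven per-participant parameters."""

    sts_count: int
    sts_peak_accel_mean: float
    six_mwt_distance: float
    step_duration_mean: float
    step_length_mean: float
    tug_comfort_s: float
    tug_fast_s: float

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in FEATURE_COLUMNS}

    def as_array(self) -> np.ndarray:
        return np.array([float(getattr(self, c)) for c in FEATURE_COLUMNS])


@dataclass(frozen=True)
class TestRecording:
    """A trace bound to its test protocol plus protocol annotations.

    ``shuttle_marks`` (6MWT) are the times the walker completes each shuttle
    leg; ``n_full_shuttles``/``partial_m`` give the walked distance.  The
    shuttle course length and chair height are protocol constants.
    """

    protocol: str
    trace: ImuTrace
    shuttle_marks: tuple[float, ...] = ()
    n_full_shuttles: int = 0
    partial_m: float = 0.0
    shuttle_length_m: float = 10.0
    chair_height_m: float = 0.45

    def __post_init__(self):
        if self.protocol not in REQUIRED_PROTOCOLS:
            raise ValueError(
                f"unknown protocol {self.protocol!r}; expected one of {REQUIRED_PROTOCOLS}"
            )


# ---------------------------------------------------------------------------
# baseline / onset / termination
# ---------------------------------------------------------------------------

def detect_baseline(trace: ImuTrace, lead_s: float = 10.0) -> tuple[float, float]:
    """Mean and SD of the vertical channel over the static lead-in [0, lead_s)."""
    if trace.duration < lead_s:
        raise ValueError(
            f"trace of {trace.duration:.2f}s is shorter than the required "
            f"{lead_s:.2f}s static lead-in"
        )
    sel = trace.t - trace.t[0] < lead_s
    z = trace.vertical[sel]
    return float(np.mean(z)), float(np.std(z))


def _onset_index(
    z: np.ndarray,
    base_mean: float,
    base_sd: float,
    k_sd: float,
    abs_floor: float,
    sustain: int,
) -> float:
    """Fractional index of a sustained departure from baseline.

    Finds the first run of ``sustain`` samples beyond the detection threshold,
    backtracks to where the signal last sat inside the baseline noise band,
    and returns the midpoint between that quiet sample and the first active
    one (the true movement start lies between them, so the half-sample
    convention removes most of the late bias of the crossing itself).
    """
    thr = max(k_sd * base_sd, abs_floor)
    above = np.abs(z - base_mean) > thr
    # first run of `sustain` consecutive True
    run = 0
    start = -1
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= sustain:
            start = i - sustain + 1
            break
    if start < 0:
        raise ValueError("no motion detected")
    # floor keeps the backtrack out of zero-phase filter ringing (<<0.02 m/s^2)
    eps = max(2.0 * base_sd, 0.02)
    i = start
    while i > 0 and abs(z[i - 1] - base_mean) > eps:
        i -= 1
    return i - 0.5 if i > 0 else float(i)


def detect_motion_onset(
    trace: ImuTrace,
    baseline: tuple[float, float] | None = None,
    k_sd: float = K_SD,
    *,
    lead_s: float = 10.0,
    abs_floor: float = ABS_FLOOR,
    sustain: int = SUSTAIN,
    cutoff_hz: float | None = STS_CUTOFF_HZ,
) -> float:
    """Time of the first sustained departure of the vertical channel from baseline.

    Detection runs on a zero-phase low-passed copy of the signal (``cutoff_hz``,
    None to disable), which shrinks the baseline noise band and sharpens the
    departure point.  The departure must exceed ``max(k_sd * baseline_sd,
    abs_floor)`` for ``sustain`` consecutive samples; the returned time is
    backtracked to where the excursion leaves the noise band.  A ``baseline``
    (mean, SD) may be supplied, and is then applied to the filtered copy;
    by default it is measured on the filtered lead-in.
    """
    zf = _lowpass(trace.vertical, trace.sampling_rate, cutoff_hz)
    if baseline is None:
        if trace.duration < lead_s:
            raise ValueError(
                f"trace of {trace.duration:.2f}s is shorter than the required "
                f"{lead_s:.2f}s static lead-in"
            )
        lead = zf[trace.t - trace.t[0] < lead_s]
        baseline = float(np.mean(lead)), float(np.std(lead))
    base_mean, base_sd = baseline
    i = _onset_index(zf, base_mean, base_sd, k_sd, abs_floor, sustain)
    return float(trace.t[0] + i / trace.sampling_rate)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _lowpass(z: np.ndarray, fs: float, cutoff_hz: float | None, order: int = 4) -> np.ndarray:
    if cutoff_hz is None or cutoff_hz >= fs / 2.0:
        return z
    b, a = butter(order, cutoff_hz / (fs / 2.0), btype="low")
    return filtfilt(b, a, z)


def detect_vertical_peaks(
    trace: ImuTrace,
    min_separation_s: float,
    min_prominence: float,
    *,
    cutoff_hz: float | None = None,
) -> PeakSet:
    """Local maxima of the vertical channel with prominence and spacing floors.

    Peaks are located on a zero-phase low-passed copy when ``cutoff_hz`` is
    given (prominence is then measured on the filtered signal, making the
    detector invariant to constant offsets); amplitudes are read from the raw
    channel at the detected indices.  When two candidate peaks violate the
    spacing floor the higher one wins, then the earlier one.
    """
    fs = trace.sampling_rate
    if min_separation_s < 2.0 / fs:
        raise ValueError("min_separation_s must be at least 2 samples")
    zf = _lowpass(trace.vertical, fs, cutoff_hz)
    distance = max(1, int(math.ceil(min_separation_s * fs)))
    idx, _ = find_peaks(zf, prominence=min_prominence, distance=distance)
    return PeakSet(
        indices=idx,
        times=trace.t[idx],
        amplitudes=trace.vertical[idx],
    )


# ---------------------------------------------------------------------------
# per-test features
# ---------------------------------------------------------------------------

def sts_features(
    trace: ImuTrace,
    window_s: float = 30.0,
    *,
    lead_s: float = 10.0,
    min_separation_s: float = STS_MIN_SEPARATION_S,
    min_prominence: float = STS_MIN_PROMINENCE,
    cutoff_hz: float | None = STS_CUTOFF_HZ,
) -> tuple[int, float | None]:
    """Sit-to-Stand count and mean peak vertical acceleration over the test window.

    Peaks are restricted to ``[onset, onset + window_s)``.  With zero peaks the
    count is 0 and the mean is returned as None (missing).
    """
    detect_baseline(trace, lead_s)  # validates the lead-in is present
    try:
        onset = detect_motion_onset(trace, lead_s=lead_s, cutoff_hz=cutoff_hz)
    except ValueError:
        return 0, None
    peaks = detect_vertical_peaks(trace, min_separation_s, min_prominence, cutoff_hz=cutoff_hz)
    sel = (peaks.times >= onset) & (peaks.times < onset + window_s)
    count = int(np.count_nonzero(sel))
    if count == 0:
        return 0, None
    return count, float(np.mean(peaks.amplitudes[sel]))


def gait_features(
    trace: ImuTrace,
    shuttle_marks,
    shuttle_length_m: float = 10.0,
    *,
    lead_s: float = 10.0,
    min_separation_s: float = STEP_MIN_SEPARATION_S,
    min_prominence: float = STEP_MIN_PROMINENCE,
    cutoff_hz: float | None = GAIT_CUTOFF_HZ,
    weighted: bool = False,
) -> tuple[float, float, int]:
    """Mean step duration, mean step length, and step count from a shuttle walk.

    Step events are vertical-acceleration peaks between motion onset and the
    last shuttle mark; durations are successive peak-time differences.  Each
    completed shuttle contributes a length estimate ``shuttle_length_m /
    n_steps`` where a step landing exactly on a shuttle boundary closes that
    shuttle (attribution intervals are (previous mark, mark]).  The default
    step-length mean is unweighted across shuttles; ``weighted=True`` weights
    by steps per shuttle.  Shuttles containing no step are excluded with a
    warning.
    """
    marks = np.asarray(shuttle_marks, dtype=float)
    if marks.size < 1:
        raise ValueError("at least one completed shuttle is required")
    if np.any(np.diff(marks) <= 0):
        raise ValueError("shuttle_marks must be strictly increasing")
    onset = detect_motion_onset(trace, lead_s=lead_s, cutoff_hz=cutoff_hz)
    peaks = detect_vertical_peaks(trace, min_separation_s, min_prominence, cutoff_hz=cutoff_hz)
    sel = (peaks.times >= onset) & (peaks.times <= marks[-1])
    times = peaks.times[sel]
    if times.size < 2:
        raise ValueError("fewer than two step peaks detected during the walk")
    durations = np.diff(times)

    bounds = np.concatenate([[onset - 1e-9], marks])
    lengths, weights = [], []
    for j in range(marks.size):
        n_in = int(np.count_nonzero((times > bounds[j]) & (times <= bounds[j + 1])))
        if n_in == 0:
            warnings.warn(f"shuttle {j + 1} contains no step peaks; excluded")
            continue
        lengths.append(shuttle_length_m / n_in)
        weights.append(n_in)
    if not lengths:
        raise ValueError("no shuttle contained any step peaks")
    lengths = np.asarray(lengths)
    if weighted:
        step_length = float(np.average(lengths, weights=np.asarray(weights, dtype=float)))
    else:
        step_length = float(np.mean(lengths))
    return float(np.mean(durations)), step_length, int(times.size)


def six_mwt_distance(
    n_full_shuttles: int, partial_m: float, shuttle_length_m: float = 10.0
) -> float:
    """Total six-minute-walk distance from shuttle count plus partial metres."""
    if n_full_shuttles < 0 or partial_m < 0 or shuttle_length_m <= 0:
        raise ValueError("shuttle counts and distances must be non-negative")
    if partial_m >= shuttle_length_m:
        raise ValueError("partial_m must be smaller than one shuttle length")
    return float(n_full_shuttles * shuttle_length_m + partial_m)


def tug_duration(
    trace: ImuTrace,
    *,
    lead_s: float = 10.0,
    tail_s: float = 5.0,
    k_sd: float = K_SD,
    abs_floor: float = ABS_FLOOR,
    sustain: int = SUSTAIN,
    cutoff_hz: float | None = STS_CUTOFF_HZ,
) -> float:
    """Timed Up and Go duration: movement termination minus movement onset.

    Onset comes from the static lead-in baseline; termination runs the same
    sustained-departure rule backwards from the trace end, with its own
    baseline measured over the final ``tail_s`` static seconds.  Both ends are
    detected on the same zero-phase low-passed copy of the vertical channel.
    """
    if trace.duration < lead_s:
        raise ValueError(
            f"trace of {trace.duration:.2f}s is shorter than the required "
            f"{lead_s:.2f}s static lead-in"
        )
    if trace.duration < tail_s:
        raise ValueError(f"trace shorter than the {tail_s:.2f}s static tail")
    zf = _lowpass(trace.vertical, trace.sampling_rate, cutoff_hz)
    rel = trace.t - trace.t[0]
    head = zf[rel < lead_s]
    i_on = _onset_index(zf, float(np.mean(head)), float(np.std(head)),
                        k_sd, abs_floor, sustain)
    tail = zf[rel >= trace.duration - tail_s]
    i_off_rev = _onset_index(zf[::-1], float(np.mean(tail)), float(np.std(tail)),
                             k_sd, abs_floor, sustain)
    i_off = zf.size - 1 - i_off_rev
    if i_off <= i_on:
        raise ValueError("no motion detected")
    return float((i_off - i_on) / trace.sampling_rate)


def extract_features(recordings) -> FeatureVector:
    """Assemble the seven-parameter vector from one recording per protocol.

    ``recordings`` is an iterable of :class:`TestRecording` (or a mapping
    protocol -> TestRecording) covering STS30, 6MWT, TUG_COMFORT and TUG_FAST.
    """
    if isinstance(recordings, dict):
        by_protocol = dict(recordings)
    else:
        by_protocol = {}
        for rec in recordings:
            by_protocol[rec.protocol] = rec
    missing = [p for p in REQUIRED_PROTOCOLS if p not in by_protocol]
    if missing:
        raise ValueError(f"missing recordings for protocol(s): {', '.join(missing)}")

    sts = by_protocol["STS30"]
    count, peak_mean = sts_features(sts.trace)
    if peak_mean is None:
        raise ValueError("no Sit-to-Stand peaks detected; cannot assemble features")

    walk = by_protocol["6MWT"]
    dur_mean, len_mean, _ = gait_features(
        walk.trace, walk.shuttle_marks, walk.shuttle_length_m
    )
    distance = six_mwt_distance(walk.n_full_shuttles, walk.partial_m, walk.shuttle_length_m)

    return FeatureVector(
        sts_count=count,
        sts_peak_accel_mean=peak_mean,
        six_mwt_distance=distance,
        step_duration_mean=dur_mean,
        step_length_mean=len_mean,
        tug_comfort_s=tug_duration(by_protocol["TUG_COMFORT"].trace),
        tug_fast_s=tug_duration(by_protocol["TUG_FAST"].trace),
    )


def features_to_frame(vectors, ids=None) -> pd.DataFrame:
    """Stack FeatureVectors into a participant x feature table."""
    rows = [fv.as_dict() for fv in vectors]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if ids is not None:
        df.insert(0, "participant_id", list(ids))
    return df
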