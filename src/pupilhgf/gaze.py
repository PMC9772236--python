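"""Anticipatory gaze processing: from raw pitch/yaw traces to the binary
per-trial response series used as HGF responses.

Per trial (segmented from ball release to ball contact) the steps are

1. three-frame median smooth + zero-phase 2nd-order 15 Hz Butterworth
   low-pass on pitch and yaw,
2. trial QC: drop trials with > 20 % invalid samples or any contiguous
   invalid run > 100 ms,
3. I-DT fixation detection (sum-of-ranges dispersion <= 3 deg, minimum
   duration 100 ms),
4. selection of the fixation ending within 400 ms before the bounce;
   its pitch is the trial's anticipatory response,
5. participant-level outlier flagging (|z| > 3.29) and exclusion when
   missing + outliers exceed 15 % of trials,
6. discretization of trial-to-trial pitch changes (> 1 SD of the change
   distribution) into y = 1 (gaze shifted lower: higher expectation of a
   normal bounce) / y = 0 (shifted higher), carrying the previous response
   through sub-threshold changes.

Pitch is head-centred and negative downward, so "lower spatial location"
means a more negative pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "GazeTrace",
    "Fixation",
    "median_smooth3",
    "butter_lowpass",
    "preprocess_trace",
    "trial_gaze_qc",
    "detect_fixations",
    "select_prebounce_fixation",
    "discretize_pitch",
    "participant_gaze_qc",
    "process_gaze",
]

GAZE_CUTOFF_HZ = 15.0
DISPERSION_DEG = 3.0
MIN_FIX_DUR_S = 0.100
PREBOUNCE_WINDOW_S = 0.400
MAX_MISSING_FRACTION = 0.20
MAX_GAP_S = 0.100
OUTLIER_Z = 3.29
MAX_PARTICIPANT_MISSING = 0.15


@dataclass
class GazeTrace:
    """One trial's gaze samples: t (s from ball release), pitch and yaw in
    degrees, validity flags; plus the bounce and contact event times."""

    t: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    valid: np.ndarray
    rate: float
    bounce_time: float
    contact_time: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.pitch) == len(self.yaw) == len(self.valid)):
            raise ValueError("trace columns must share one length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.bounce_time >= self.contact_time:
            raise ValueError("bounce_time must precede contact_time")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "pitch": self.pitch, "yaw": self.yaw,
             "valid": self.valid.astype(int)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate: float, bounce_time: float,
                   contact_time: float) -> "GazeTrace":
        return cls(df["t"].to_numpy(), df["pitch"].to_numpy(), df["yaw"].to_numpy(),
                   df["valid"].to_numpy().astype(bool), rate, bounce_time, contact_time)


@dataclass(frozen=True)
class Fixation:
    onset: float
    offset: float
    centroid_pitch: float
    centroid_yaw: float
    n_samples: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def median_smooth3(series) -> np.ndarray:
    """Three-frame running median; endpoints pass through unchanged."""
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = np.median(np.column_stack([x[:-2], x[1:-1], x[2:]]), axis=1)
    return out


def butter_lowpass(series, rate: float, cutoff: float = GAZE_CUTOFF_HZ,
                   order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The dual pass squares the magnitude response, so a sinusoid at the
    cutoff frequency comes out at half its input amplitude.
    """
    x = np.asarray(series, dtype=float)
    if cutoff >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must lie below Nyquist {rate / 2} Hz")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    b, a = signal.butter(order, cutoff, fs=rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen:
        return x.copy()
    return signal.filtfilt(b, a, x)


def preprocess_trace(trace: GazeTrace, cutoff: float = GAZE_CUTOFF_HZ,
                     order: int = 2) -> GazeTrace:
    """Median-smooth then low-pass both gaze angles."""
    pitch = butter_lowpass(median_smooth3(trace.pitch), trace.rate, cutoff, order)
    yaw = butter_lowpass(median_smooth3(trace.yaw), trace.rate, cutoff, order)
    return replace(trace, pitch=pitch, yaw=yaw)


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of invalid samples as (start, stop) index pairs."""
    runs = []
    in_run = False
    for i, v in enumerate(valid):
        if not v and not in_run:
            start, in_run = i, True
        elif v and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(valid)))
    return runs


def trial_gaze_qc(trace: GazeTrace,
                  max_missing_fraction: float = MAX_MISSING_FRACTION,
                  max_gap_s: float = MAX_GAP_S) -> tuple[bool, str | None]:
    """Keep/exclude decision for one trial.

    Excludes when the invalid-sample fraction exceeds 20 % (poor tracking)
    or any contiguous invalid run lasts more than 100 ms (a gap long
    enough to corrupt fixation detection).
    """
    n = len(trace.valid)
    frac = 1.0 - trace.valid.mean() if n else 1.0
    if frac > max_missing_fraction:
        return False, "missing_fraction"
    for start, stop in _invalid_runs(trace.valid):
        if (stop - start) / trace.rate > max_gap_s:
            return False, "tracking_gap"
    return True, None


def _dispersion(pitch, yaw) -> float:
    return (pitch.max() - pitch.min()) + (yaw.max() - yaw.min())


def detect_fixations(trace: GazeTrace, dispersion_deg: float = DISPERSION_DEG,
                     min_dur_s: float = MIN_FIX_DUR_S) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    Within each maximal run of valid samples, from the current start index
    the window grows to the largest end index keeping sum-of-ranges
    dispersion (pitch range + yaw range) <= ``dispersion_deg``.  If the
    window spans at least ``min_dur_s`` it becomes a fixation (centroid =
    mean of member samples) and scanning resumes after it; otherwise the
    start advances by one sample.
    """
    fixations: list[Fixation] = []
    valid_idx = np.flatnonzero(trace.valid)
    if len(valid_idx) == 0:
        return fixations
    # split into maximal contiguous valid runs
    breaks = np.flatnonzero(np.diff(valid_idx) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_stops = np.concatenate([breaks + 1, [len(valid_idx)]])
    for rs, re_ in zip(run_starts, run_stops):
        idx = valid_idx[rs:re_]
        t = trace.t[idx]
        pitch = trace.pitch[idx]
        yaw = trace.yaw[idx]
        n = len(idx)
        i = 0
        while i < n:
            pmin = pmax = pitch[i]
            ymin = ymax = yaw[i]
            j = i
            while j + 1 < n:
                npmin = min(pmin, pitch[j + 1])
                npmax = max(pmax, pitch[j + 1])
                nymin = min(ymin, yaw[j + 1])
                nymax = max(ymax, yaw[j + 1])
                if (npmax - npmin) + (nymax - nymin) <= dispersion_deg:
                    pmin, pmax, ymin, ymax = npmin, npmax, nymin, nymax
                    j += 1
                else:
                    break
            if t[j] - t[i] >= min_dur_s:
                fixations.append(
                    Fixation(
                        onset=float(t[i]), offset=float(t[j]),
                        centroid_pitch=float(pitch[i:j + 1].mean()),
                        centroid_yaw=float(yaw[i:j + 1].mean()),
                        n_samples=j - i + 1,
                    )
                )
                i = j + 1
            else:
                i += 1
    return fixations


def select_prebounce_fixation(fixations: list[Fixation], bounce_time: float,
                              window_s: float = PREBOUNCE_WINDOW_S) -> Fixation | None:
    """Latest fixation whose offset falls within ``window_s`` before the
    bounce; None when no fixation qualifies."""
    candidates = [f for f in fixations
                  if bounce_time - window_s <= f.offset <= bounce_time]
    return candidates[-1] if candidates else None


def discretize_pitch(pitch, sd_mult: float = 1.0, carry: bool = True):
    """Convert per-trial fixation pitches into the binary response series.

    A trial-to-trial pitch change below -sd_mult * SD(changes) (gaze moved
    to a lower location) maps to y = 1 (higher expectation of a normal
    bounce); a change above +threshold maps to y = 0.  Sub-threshold
    changes carry the previous trial's response forward (``carry=False``
    leaves them missing).  The first trial, trials with missing pitch, and
    trials whose predecessor pitch is missing yield missing-per-carry.

    Returns ``(y, sigma_delta)`` with y in {0.0, 1.0, NaN}.
    """
    p = np.asarray(pitch, dtype=float)
    if np.sum(~np.isnan(p)) < 2:
        raise ValueError("need >= 2 non-missing pitch values")
    both = ~np.isnan(p[1:]) & ~np.isnan(p[:-1])
    deltas = (p[1:] - p[:-1])[both]
    if len(deltas) < 2:
        raise ValueError("need >= 2 consecutive non-missing pitch pairs")
    sigma = float(np.std(deltas, ddof=1))
    if sigma == 0:
        raise ValueError("pitch changes have zero variance")
    thr = sd_mult * sigma
    n = len(p)
    y = np.full(n, np.nan)
    for k in range(1, n):
        if np.isnan(p[k]) or np.isnan(p[k - 1]):
            if not np.isnan(p[k]) and carry:
                y[k] = y[k - 1]
            continue
        d = p[k] - p[k - 1]
        if d < -thr:
            y[k] = 1.0
        elif d > thr:
            y[k] = 0.0
        elif carry:
            y[k] = y[k - 1]
    return y, sigma


def participant_gaze_qc(pitch, outlier_z: float = OUTLIER_Z,
                        max_missing: float = MAX_PARTICIPANT_MISSING):
    """Flag outlying pitches and decide participant inclusion.

    Pitches with |z| > 3.29 against the participant's own mean/SD become
    missing; the participant is excluded when missing + outliers exceed
    15 % of trials.  Returns ``(include, cleaned_pitch, fractions)``.
    """
    p = np.asarray(pitch, dtype=float).copy()
    total = len(p)
    missing = np.isnan(p)
    obs = p[~missing]
    outliers = np.zeros(total, dtype=bool)
    if len(obs) >= 2 and obs.std(ddof=1) > 0:
        z = (p - obs.mean()) / obs.std(ddof=1)
        outliers = ~missing & (np.abs(z) > outlier_z)
        p[outliers] = np.nan
    fractions = {
        "missing": float(missing.mean()) if total else 1.0,
        "outliers": float(outliers.mean()) if total else 0.0,
    }
    fractions["total"] = fractions["missing"] + fractions["outliers"]
    include = fractions["total"] <= max_missing
    return include, p, fractions


def process_gaze(traces: list[GazeTrace], sd_mult: float = 1.0, carry: bool = True,
                 dispersion_deg: float = DISPERSION_DEG,
                 min_dur_s: float = MIN_FIX_DUR_S,
                 window_s: float = PREBOUNCE_WINDOW_S,
                 cutoff: float = GAZE_CUTOFF_HZ) -> tuple[pd.DataFrame, bool, dict]:
    """Full per-participant gaze pipeline.

    Returns ``(table, include, fractions)`` where ``table`` has one row per
    trial (trial, pitch, y, exclusion_reason) and ``include`` is the
    participant-level QC verdict.
    """
    n = len(traces)
    pitch = np.full(n, np.nan)
    reasons: list[str | None] = [None] * n
    for k, trace in enumerate(traces):
        keep, reason = trial_gaze_qc(trace)
        if not keep:
            reasons[k] = reason
            continue
        filt = preprocess_trace(trace, cutoff=cutoff)
        fixations = detect_fixations(filt, dispersion_deg, min_dur_s)
        fix = select_prebounce_fixation(fixations, trace.bounce_time, window_s)
        if fix is None:
            reasons[k] = "no_prebounce_fixation"
        else:
            pitch[k] = fix.centroid_pitch
    include, cleaned, fractions = participant_gaze_qc(pitch)
    for k in range(n):
        if np.isnan(cleaned[k]) and not np.isnan(pitch[k]):
            reasons[k] = "outlier"
    y, _sigma = discretize_pitch(cleaned, sd_mult=sd_mult, carry=carry)
    table = pd.DataFrame(
        {"trial": np.arange(1, n + 1), "pitch": cleaned, "y": y,
         "exclusion_reason": reasons}
    )
    return table, include, fractions
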