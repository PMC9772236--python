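"""Task-evoked pupil response (TEPR) extraction.

Binocular pupil diameter (mm, 90 Hz) is processed per trial:

1. blink detection - maximal runs of zero diameter, padded by 150 ms and
   merged,
2. trial QC on the *pre-interpolation* missingness (padded blink samples
   are not data): > 20 % missing or any raw zero-run > 100 ms excludes
   the trial,
3. linear least-squares interpolation across blink intervals (lines fitted
   to 100 ms flanks; edge gaps hold the nearest valid value),
4. zero-phase 2nd-order 10 Hz Butterworth low-pass, each eye separately,
5. binocular average (monocular fallback when one eye is wholly missing),
6. TEPR = max diameter over the 3 s post-onset window minus the mean over
   the 200 ms pre-onset baseline,
7. within-participant normalization by the sample SD of the TEPRs, and
   outlier/participant QC with the same 3.29 SD / 15 % rules as gaze.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze import butter_lowpass

__all__ = [
    "PupilTrace",
    "TrialPupilFeature",
    "detect_blinks",
    "interpolate_gaps",
    "butter_lowpass_pupil",
    "binocular_average",
    "trial_pupil_qc",
    "extract_tepr",
    "normalize_by_sd",
    "participant_pupil_qc",
    "process_pupil",
]

PUPIL_RATE_HZ = 90.0
PUPIL_CUTOFF_HZ = 10.0
BLINK_PAD_S = 0.150
BASELINE_WINDOW_S = 0.200
RESPONSE_WINDOW_S = 3.000
FLANK_S = 0.100
MAX_MISSING_FRACTION = 0.20
MAX_GAP_S = 0.100
OUTLIER_Z = 3.29
MAX_PARTICIPANT_MISSING = 0.15


@dataclass
class PupilTrace:
    """One trial's binocular pupil samples; t in seconds from ball release."""

    t: np.ndarray
    left_mm: np.ndarray
    right_mm: np.ndarray
    rate: float = PUPIL_RATE_HZ

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.left_mm = np.asarray(self.left_mm, dtype=float)
        self.right_mm = np.asarray(self.right_mm, dtype=float)
        if not (len(self.t) == len(self.left_mm) == len(self.right_mm)):
            raise ValueError("trace columns must share one length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.left_mm < 0) or np.any(self.right_mm < 0):
            raise ValueError("diameters must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "left_mm": self.left_mm,
                             "right_mm": self.right_mm})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate: float = PUPIL_RATE_HZ) -> "PupilTrace":
        return cls(df["t"].to_numpy(), df["left_mm"].to_numpy(),
                   df["right_mm"].to_numpy(), rate)


@dataclass
class TrialPupilFeature:
    baseline_mm: float
    peak_response_mm: float
    normalized_response: float = np.nan
    exclusion_reason: str | None = None
    monocular: bool = False


def detect_blinks(diameter, t, pad_s: float = BLINK_PAD_S) -> list[tuple[float, float]]:
    """Blink intervals: maximal zero-diameter runs padded by ``pad_s`` on
    both sides, clipped to the trace and merged when overlapping."""
    d = np.asarray(diameter, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.all(d == 0):
        raise ValueError("entire trace is zero: trial wholly missing")
    zero = d == 0
    intervals = []
    i = 0
    n = len(d)
    while i < n:
        if zero[i]:
            j = i
            while j + 1 < n and zero[j + 1]:
                j += 1
            intervals.append((max(t[i] - pad_s, t[0]), min(t[j] + pad_s, t[-1])))
            i = j + 1
        else:
            i += 1
    merged: list[tuple[float, float]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interpolate_gaps(diameter, t, intervals, flank_s: float = FLANK_S) -> np.ndarray:
    """Replace samples inside each interval by the least-squares line
    through the valid samples in the 100 ms flanks on either side.

    Edge gaps (no flank on one side) hold the nearest valid value.
    """
    d = np.asarray(diameter, dtype=float).copy()
    t = np.asarray(t, dtype=float)
    in_any = np.zeros(len(d), dtype=bool)
    for s, e in intervals:
        in_any |= (t >= s) & (t <= e)
    if in_any.all():
        raise ValueError("no valid samples outside the gap intervals")
    for s, e in intervals:
        inside = (t >= s) & (t <= e)
        left = (~in_any) & (t < s) & (t >= s - flank_s)
        right = (~in_any) & (t > e) & (t <= e + flank_s)
        flank_t = np.concatenate([t[left], t[right]])
        flank_d = np.concatenate([d[left], d[right]])
        if len(flank_t) >= 2 and (left.any() and right.any()):
            slope, intercept = np.polyfit(flank_t, flank_d, 1)
            d[inside] = slope * t[inside] + intercept
        else:
            # edge gap: hold nearest valid value
            valid_idx = np.flatnonzero(~in_any)
            for i in np.flatnonzero(inside):
                nearest = valid_idx[np.argmin(np.abs(t[valid_idx] - t[i]))]
                d[i] = d[nearest]
    return d


def butter_lowpass_pupil(diameter, rate: float = PUPIL_RATE_HZ,
                         cutoff: float = PUPIL_CUTOFF_HZ, order: int = 2) -> np.ndarray:
    return butter_lowpass(diameter, rate, cutoff, order)


def binocular_average(left, right) -> tuple[np.ndarray, bool]:
    """Per-sample mean of the two (already repaired + filtered) eyes.

    An eye that is wholly missing (all zero) triggers the monocular
    fallback: the other eye is returned and flagged.
    Returns ``(series, monocular)``.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if len(left) != len(right):
        raise ValueError("left and right series must have equal length")
    left_dead = np.all(left == 0)
    right_dead = np.all(right == 0)
    if left_dead and right_dead:
        raise ValueError("both eyes wholly missing")
    if left_dead:
        return right.copy(), True
    if right_dead:
        return left.copy(), True
    return 0.5 * (left + right), False


def trial_pupil_qc(trace: PupilTrace,
                   max_missing_fraction: float = MAX_MISSING_FRACTION,
                   max_gap_s: float = MAX_GAP_S) -> tuple[bool, str | None]:
    """Trial QC on raw (pre-interpolation) missingness.

    A sample is missing when either eye reads zero; > 20 % missing or any
    contiguous missing run > 100 ms excludes the trial.
    """
    missing = (trace.left_mm == 0) | (trace.right_mm == 0)
    # a wholly-dead eye is handled by the monocular fallback, not trial QC
    if np.all(trace.left_mm == 0) != np.all(trace.right_mm == 0):
        alive = trace.right_mm if np.all(trace.left_mm == 0) else trace.left_mm
        missing = alive == 0
    if missing.all():
        return False, "all_missing"
    if missing.mean() > max_missing_fraction:
        return False, "missing_fraction"
    run = 0
    for v in missing:
        run = run + 1 if v else 0
        if run / trace.rate > max_gap_s:
            return False, "tracking_gap"
    return True, None


def repair_and_filter(trace: PupilTrace, pad_s: float = BLINK_PAD_S,
                      cutoff: float = PUPIL_CUTOFF_HZ) -> tuple[np.ndarray, bool]:
    """Blink-repair and low-pass each eye, then average binocularly.

    Returns ``(diameter series, monocular flag)``.
    """
    eyes = []
    monocular = False
    for eye in (trace.left_mm, trace.right_mm):
        if np.all(eye == 0):
            eyes.append(eye)
            continue
        blinks = detect_blinks(eye, trace.t, pad_s)
        repaired = interpolate_gaps(eye, trace.t, blinks)
        eyes.append(butter_lowpass_pupil(repaired, trace.rate, cutoff))
    return binocular_average(eyes[0], eyes[1])


def extract_tepr(diameter, t, onset: float = 0.0,
                 baseline_window: float = BASELINE_WINDOW_S,
                 response_window: float = RESPONSE_WINDOW_S) -> TrialPupilFeature:
    """Baseline-corrected peak pupil response.

    baseline = mean over [onset - 200 ms, onset); peak response = max over
    [onset, onset + 3 s] minus baseline (may be negative).
    """
    d = np.asarray(diameter, dtype=float)
    t = np.asarray(t, dtype=float)
    if t[0] > onset - baseline_window or t[-1] < onset + response_window:
        return TrialPupilFeature(np.nan, np.nan, exclusion_reason="window_coverage")
    base_mask = (t >= onset - baseline_window) & (t < onset)
    resp_mask = (t >= onset) & (t <= onset + response_window)
    baseline = float(d[base_mask].mean())
    peak = float(d[resp_mask].max() - baseline)
    return TrialPupilFeature(baseline_mm=baseline, peak_response_mm=peak)


def normalize_by_sd(peak_responses) -> np.ndarray:
    """Divide each trial's peak response by the participant's sample SD
    (n-1) of peak responses, so values count standard deviations; missing
    entries pass through."""
    x = np.asarray(peak_responses, dtype=float)
    obs = x[~np.isnan(x)]
    if len(obs) < 2:
        raise ValueError("need >= 2 non-missing peak responses")
    sd = float(obs.std(ddof=1))
    if sd == 0:
        raise ValueError("zero SD of peak responses: participant excluded")
    return x / sd


def participant_pupil_qc(normalized, outlier_z: float = OUTLIER_Z,
                         max_missing: float = MAX_PARTICIPANT_MISSING):
    """Outlier-flag normalized responses (|z| > 3.29 -> missing) and
    exclude the participant when missing + outliers exceed 15 %.

    Returns ``(include, cleaned, fractions)``.
    """
    x = np.asarray(normalized, dtype=float).copy()
    total = len(x)
    missing = np.isnan(x)
    obs = x[~missing]
    outliers = np.zeros(total, dtype=bool)
    if len(obs) >= 2 and obs.std(ddof=1) > 0:
        z = (x - obs.mean()) / obs.std(ddof=1)
        outliers = ~missing & (np.abs(z) > outlier_z)
        x[outliers] = np.nan
    fractions = {
        "missing": float(missing.mean()) if total else 1.0,
        "outliers": float(outliers.mean()) if total else 0.0,
    }
    fractions["total"] = fractions["missing"] + fractions["outliers"]
    include = fractions["total"] <= max_missing
    return include, x, fractions


def process_pupil(traces: list[PupilTrace], onset: float = 0.0,
                  pad_s: float = BLINK_PAD_S, cutoff: float = PUPIL_CUTOFF_HZ,
                  baseline_window: float = BASELINE_WINDOW_S,
                  response_window: float = RESPONSE_WINDOW_S
                  ) -> tuple[pd.DataFrame, bool, dict]:
    """Full per-participant pupil pipeline.

    Returns ``(table, include, fractions)``; ``table`` has one row per
    trial (trial, baseline_mm, peak_response_mm, normalized_response,
    monocular, exclusion_reason).
    """
    n = len(traces)
    rows = []
    for k, trace in enumerate(traces):
        keep, reason = trial_pupil_qc(trace)
        if not keep:
            rows.append(TrialPupilFeature(np.nan, np.nan, exclusion_reason=reason))
            continue
        series, monocular = repair_and_filter(trace, pad_s, cutoff)
        feat = extract_tepr(series, trace.t, onset, baseline_window, response_window)
        feat.monocular = monocular
        rows.append(feat)
    peaks = np.array([r.peak_response_mm for r in rows])
    normalized = normalize_by_sd(peaks)
    include, cleaned, fractions = participant_pupil_qc(normalized)
    for k, r in enumerate(rows):
        if np.isnan(cleaned[k]) and not np.isnan(normalized[k]):
            r.exclusion_reason = "outlier"
        r.normalized_response = cleaned[k]
    table = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "baseline_mm": [r.baseline_mm for r in rows],
            "peak_response_mm": [r.peak_response_mm for r in rows],
            "normalized_response": [r.normalized_response for r in rows],
            "monocular": [r.monocular for r in rows],
            "exclusion_reason": [r.exclusion_reason for r in rows],
        }
    )
    return table, include, fractions
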