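"""Synthetic study generator: volatile trial schedules, HGF agents, raw
gaze and pupil traces with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes so that every downstream stage is testable without real data:

* trial schedules with p(normal) shifting among 0.5 / 0.67 / 0.83,
* agents running the 3-level binary HGF forward and emitting binary
  anticipatory responses through the unit-square sigmoid,
* 120 Hz gaze traces containing a stationary pre-bounce fixation whose
  pitch encodes the response (lower gaze = expecting a normal bounce),
  embedded in faster pursuit segments, with optional dropout gaps,
* 90 Hz binocular pupil traces: a 3 mm baseline, slow drift, zero-valued
  blink gaps, and a gamma-shaped event kernel peaking ~1 s after ball
  release whose amplitude couples linearly to the standardized |eps2| and
  learning-rate trajectories with known coefficients.

`simulate_feature_cohort` is the trace-free fast path used for
replicate-heavy statistical calibration: it produces the same per-trial
ground truth and realized response amplitudes without synthesising or
re-extracting 90 Hz traces (trace synthesis + peak extraction is the
identity up to sample discretization, verified separately).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import TrialSchedule, generate_schedule
from .gaze import GazeTrace
from .hgf import HGFParams, HGFTrajectory, hgf_filter, unitsq_sigmoid_prob
from .pupil import PupilTrace

__all__ = [
    "Coupling",
    "BlinkSpec",
    "SyntheticParticipant",
    "SyntheticDataset",
    "simulate_agent_responses",
    "simulate_gaze_trace",
    "simulate_pupil_trace",
    "make_dataset",
    "simulate_feature_cohort",
]

GAZE_RATE_HZ = 120.0
PUPIL_RATE_HZ = 90.0
PITCH_HIGH_DEG = -10.0  # gaze aimed high (bouncy-ball expectation)
PITCH_LOW_DEG = -20.0   # gaze aimed low (normal-bounce expectation)
BOUNCE_TIME_S = 1.2
CONTACT_TIME_S = 1.8
PUPIL_T0_S = -0.3
PUPIL_T1_S = 3.2
BASELINE_MM = 3.0
KERNEL_MODE_S = 1.0
KERNEL_SHAPE = 3.0
AMP_SCALE_MM = 0.1


@dataclass(frozen=True)
class Coupling:
    """Linear pupil-amplitude coupling, in amplitude SD-units per SD of the
    standardized predictor."""

    beta_eps: float = 0.5
    beta_alpha: float = 0.0
    base_amp: float = 2.0


@dataclass(frozen=True)
class BlinkSpec:
    """Blinks as zero-diameter runs: Poisson count per trial, uniform
    durations (s)."""

    rate: float = 0.1
    min_dur_s: float = 0.060
    max_dur_s: float = 0.200


@dataclass
class SyntheticParticipant:
    participant_id: str
    params: HGFParams
    coupling: Coupling
    pupil_noise_sd: float
    gaze_noise_sd: float
    blink_spec: BlinkSpec
    seed: int


def simulate_agent_responses(schedule_or_u, params: HGFParams,
                             seed: int = 0) -> tuple[np.ndarray, HGFTrajectory]:
    """Run the 3-level HGF forward and sample binary responses.

    ``y(k) ~ Bernoulli(P(y=1 | mu1hat(k), zeta))`` via the unit-square
    sigmoid.  Returns ``(y, generating trajectory)``.
    """
    u = schedule_or_u.u if isinstance(schedule_or_u, TrialSchedule) else schedule_or_u
    traj = hgf_filter(u, params, levels=3)
    p1 = unitsq_sigmoid_prob(traj.mu1hat, np.ones(len(traj)), params.zeta)
    rng = np.random.default_rng(seed)
    y = (rng.random(len(traj)) < p1).astype(float)
    return y, traj


def _gamma_kernel(t: np.ndarray, mode_s: float = KERNEL_MODE_S,
                  shape: float = KERNEL_SHAPE) -> np.ndarray:
    """Gamma density rescaled to unit peak, mode at ``mode_s`` after onset."""
    scale = mode_s / (shape - 1.0)
    k = sps.gamma.pdf(np.clip(t, 0.0, None), a=shape, scale=scale)
    peak = sps.gamma.pdf(mode_s, a=shape, scale=scale)
    return k / peak


def simulate_gaze_trace(position: float, gaze_noise_sd: float = 0.3,
                        dropouts: list[tuple[float, float]] | None = None,
                        seed: int = 0, rate: float = GAZE_RATE_HZ,
                        bounce_time: float = BOUNCE_TIME_S,
                        contact_time: float = CONTACT_TIME_S,
                        pitch_high: float = PITCH_HIGH_DEG,
                        pitch_low: float = PITCH_LOW_DEG) -> GazeTrace:
    """One trial's gaze trace with a pre-bounce fixation encoding ``position``.

    ``position`` in [0, 1] (1 = expecting a normal bounce) maps linearly to
    fixation pitch ``pitch_high - (pitch_high - pitch_low) * position``.
    The fixation spans [bounce - 0.45 s, bounce - 0.15 s]; before it the
    eyes pursue the approaching ball (fast pitch/yaw ramps), after it they
    chase the post-bounce ball.  ``dropouts`` is a list of (start_s,
    duration_s) invalid intervals.
    """
    if not (0.0 <= position <= 1.0):
        raise ValueError("position must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, contact_time, 1.0 / rate)
    target = pitch_high - (pitch_high - pitch_low) * position
    fix_on = bounce_time - 0.45
    fix_off = bounce_time - 0.15
    pitch = np.empty_like(t)
    yaw = np.empty_like(t)
    pre = t < fix_on
    fix = (t >= fix_on) & (t <= fix_off)
    post = t > fix_off
    # pursuit of the approaching ball: pitch descends from 0 deg, yaw sweeps in
    pitch[pre] = -6.0 + (target + 6.0) * (t[pre] / fix_on)
    yaw[pre] = -25.0 + 25.0 * (t[pre] / fix_on)
    pitch[fix] = target
    yaw[fix] = 0.0
    # post-bounce chase: fast upward sweep breaks any dispersion window
    pitch[post] = target + 40.0 * (t[post] - fix_off)
    yaw[post] = 10.0 * (t[post] - fix_off)
    if gaze_noise_sd > 0:
        pitch = pitch + rng.normal(0.0, gaze_noise_sd, len(t))
        yaw = yaw + rng.normal(0.0, gaze_noise_sd, len(t))
    valid = np.ones(len(t), dtype=bool)
    for start, dur in dropouts or []:
        valid[(t >= start) & (t < start + dur)] = False
    return GazeTrace(t=t, pitch=pitch, yaw=yaw, valid=valid, rate=rate,
                     bounce_time=bounce_time, contact_time=contact_time)


def simulate_pupil_trace(amplitude_sd_units: float, seed: int = 0,
                         blink_spec: BlinkSpec | None = None,
                         rate: float = PUPIL_RATE_HZ,
                         t0: float = PUPIL_T0_S, t1: float = PUPIL_T1_S,
                         baseline_mm: float = BASELINE_MM,
                         amp_scale_mm: float = AMP_SCALE_MM,
                         drift_mm: float = 0.02,
                         sample_noise_mm: float = 0.0) -> PupilTrace:
    """One trial's binocular pupil trace.

    ``diameter = baseline + slow sinusoidal drift + amplitude * kernel``
    with the gamma kernel peaking 1 s after ball release, plus zero-valued
    blink gaps; the realized event amplitude in mm is
    ``amplitude_sd_units * amp_scale_mm``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(t0, t1, 1.0 / rate)
    amp_mm = amplitude_sd_units * amp_scale_mm
    drift = drift_mm * np.sin(2.0 * np.pi * t / 20.0 + rng.uniform(0, 2 * np.pi))
    d = baseline_mm + drift + amp_mm * _gamma_kernel(t)
    eyes = []
    for _ in range(2):
        eye = d.copy()
        if sample_noise_mm > 0:
            eye = eye + rng.normal(0.0, sample_noise_mm, len(t))
        eyes.append(eye)
    if blink_spec is not None and blink_spec.rate > 0:
        n_blinks = rng.poisson(blink_spec.rate)
        for _ in range(n_blinks):
            start = rng.uniform(t0, t1 - blink_spec.max_dur_s)
            dur = rng.uniform(blink_spec.min_dur_s, blink_spec.max_dur_s)
            mask = (t >= start) & (t < start + dur)
            for eye in eyes:
                eye[mask] = 0.0
    clipped = False
    for eye in eyes:
        neg = eye < 0
        if neg.any():
            eye[neg] = 0.0
            clipped = True
    trace = PupilTrace(t=t, left_mm=eyes[0], right_mm=eyes[1], rate=rate)
    trace.clipped = clipped
    return trace


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


@dataclass
class SyntheticParticipantData:
    participant: SyntheticParticipant
    schedule: TrialSchedule
    y: np.ndarray
    trajectory: HGFTrajectory
    amplitudes: np.ndarray  # realized per-trial amplitude, SD-units
    gaze_traces: list[GazeTrace] = field(default_factory=list)
    pupil_traces: list[PupilTrace] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    participants: list[SyntheticParticipantData]
    seed: int

    def __len__(self) -> int:
        return len(self.participants)

    def write(self, outdir) -> None:
        """Write per-trial sample CSVs plus a ground-truth JSON per participant."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for pdata in self.participants:
            pid = pdata.participant.participant_id
            pdir = outdir / pid
            (pdir / "gaze").mkdir(parents=True, exist_ok=True)
            (pdir / "pupil").mkdir(parents=True, exist_ok=True)
            pdata.schedule.to_csv(pdir / "schedule.csv")
            events = pdata.schedule.trials[["trial", "u"]].copy()
            events["release_time"] = 0.0
            events["bounce_time"] = BOUNCE_TIME_S
            events["contact_time"] = CONTACT_TIME_S
            events.to_csv(pdir / "events.csv", index=False)
            for k, trace in enumerate(pdata.gaze_traces, start=1):
                trace.to_frame().to_csv(pdir / "gaze" / f"trial_{k:03d}.csv", index=False)
            for k, trace in enumerate(pdata.pupil_traces, start=1):
                trace.to_frame().to_csv(pdir / "pupil" / f"trial_{k:03d}.csv", index=False)
            truth = {
                "participant_id": pid,
                "params": asdict(pdata.participant.params),
                "coupling": asdict(pdata.participant.coupling),
                "pupil_noise_sd": pdata.participant.pupil_noise_sd,
                "gaze_noise_sd": pdata.participant.gaze_noise_sd,
                "seed": pdata.participant.seed,
                "y": pdata.y.tolist(),
                "amplitudes_sd_units": pdata.amplitudes.tolist(),
                "events": {"bounce_time": BOUNCE_TIME_S, "contact_time": CONTACT_TIME_S},
            }
            with open(pdir / "ground_truth.json", "w") as fh:
                json.dump(truth, fh, indent=2)


def _draw_participant(i: int, rng: np.random.Generator, coupling: Coupling,
                      pupil_noise_sd: float, gaze_noise_sd: float,
                      blink_spec: BlinkSpec, omega_mean: float,
                      omega_sd: float, zeta_log_mean: float,
                      zeta_log_sd: float) -> SyntheticParticipant:
    params = HGFParams(
        omega=float(rng.normal(omega_mean, omega_sd)),
        zeta=float(np.exp(rng.normal(zeta_log_mean, zeta_log_sd))),
    )
    return SyntheticParticipant(
        participant_id=f"sub-{i + 1:03d}",
        params=params,
        coupling=coupling,
        pupil_noise_sd=pupil_noise_sd,
        gaze_noise_sd=gaze_noise_sd,
        blink_spec=blink_spec,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_dataset(n_participants: int = 3, seed: int = 0,
                 coupling: Coupling = Coupling(),
                 pupil_noise_sd: float = 0.2,
                 gaze_noise_sd: float = 0.3,
                 blink_spec: BlinkSpec = BlinkSpec(),
                 omega_mean: float = -5.6, omega_sd: float = 1.0,
                 zeta_log_mean: float = np.log(3.0), zeta_log_sd: float = 0.3,
                 with_traces: bool = True,
                 n_blocks: int = 2, block_length: int = 72) -> SyntheticDataset:
    """Generate a full synthetic cohort.

    Participant parameters are drawn per participant (omega ~ Normal,
    zeta log-normal; couplings fixed across the experiment); schedules use
    the two counterbalanced default orders.  The gaze fixation position is
    driven by the agent's own binary response (its behavioural commitment
    to a high or low bounce) and the pupil event amplitude by the agent's
    standardized |eps2| and learning-rate trajectories.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if pupil_noise_sd < 0 or gaze_noise_sd < 0 or blink_spec.rate < 0:
        raise ValueError("noise and blink rates must be >= 0")
    rng = np.random.default_rng(seed)
    participants = []
    for i in range(n_participants):
        part = _draw_participant(i, rng, coupling, pupil_noise_sd, gaze_noise_sd,
                                 blink_spec, omega_mean, omega_sd,
                                 zeta_log_mean, zeta_log_sd)
        prng = np.random.default_rng(part.seed)
        schedule = generate_schedule(order_id="A" if i % 2 == 0 else "B",
                                     n_blocks=n_blocks, block_length=block_length,
                                     seed=int(prng.integers(0, 2**31 - 1)))
        y, traj = simulate_agent_responses(schedule, part.params,
                                           seed=int(prng.integers(0, 2**31 - 1)))
        amps = (coupling.base_amp
                + coupling.beta_eps * _standardize(traj.abs_eps2)
                + coupling.beta_alpha * _standardize(traj.alpha_lr))
        if pupil_noise_sd > 0:
            amps = amps + prng.normal(0.0, pupil_noise_sd, len(amps))
        pdata = SyntheticParticipantData(
            participant=part, schedule=schedule, y=y, trajectory=traj,
            amplitudes=amps,
        )
        if with_traces:
            for k in range(len(schedule)):
                pdata.gaze_traces.append(
                    simulate_gaze_trace(float(y[k]), gaze_noise_sd,
                                        seed=int(prng.integers(0, 2**31 - 1)))
                )
                pdata.pupil_traces.append(
                    simulate_pupil_trace(float(amps[k]), blink_spec=blink_spec,
                                         seed=int(prng.integers(0, 2**31 - 1)))
                )
        participants.append(pdata)
    return SyntheticDataset(participants=participants, seed=seed)


def simulate_feature_cohort(n_participants: int = 35, seed: int = 0,
                            coupling: Coupling = Coupling(),
                            pupil_noise_sd: float = 1.0,
                            omega_mean: float = -5.6, omega_sd: float = 1.0,
                            zeta_log_mean: float = np.log(3.0),
                            zeta_log_sd: float = 0.3,
                            n_blocks: int = 2, block_length: int = 72
                            ) -> SyntheticDataset:
    """Trace-free cohort (ground-truth trajectories + realized amplitudes)."""
    return make_dataset(n_participants, seed, coupling, pupil_noise_sd,
                        gaze_noise_sd=0.0, blink_spec=BlinkSpec(rate=0.0),
                        omega_mean=omega_mean, omega_sd=omega_sd,
                        zeta_log_mean=zeta_log_mean, zeta_log_sd=zeta_log_sd,
                        with_traces=False, n_blocks=n_blocks,
                        block_length=block_length)
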