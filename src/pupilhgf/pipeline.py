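"""End-to-end pipeline: raw traces -> responses/TEPRs -> model fits ->
model comparison -> surprise regressions -> group statistics.

The orchestrator adds no computation of its own; every number it writes is
recomputable by invoking the individual modules with the same
configuration.  Exclusions (trial- and participant-level) are logged with
the rule that fired.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gaze as gz
from . import pupil as pp
from . import stats as st
from .design import TrialSchedule
from .fitting import compare_models, model_from_id
from .gaze import GazeTrace
from .hgf import simulate_bayes_optimal
from .pupil import PupilTrace
from .synthetic import BlinkSpec, Coupling, make_dataset

log = logging.getLogger("pupilhgf")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

PREDICTORS = ("mu2", "mu3", "eps2", "alpha_lr")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with the study's stated constants as
    defaults (15/10 Hz cutoffs, 3 deg / 100 ms fixations, 400 ms pre-bounce
    window, 200 ms baseline / 3000 ms response windows, 150 ms blink pad,
    20 % / 100 ms / 3.29 SD / 15 % QC rules)."""

    mode: str = "synthetic"  # or "paths"
    input_dir: str | None = None
    outdir: str = "pupilhgf_out"
    seed: int = 0
    # synthetic-mode generator settings
    n_participants: int = 3
    beta_eps: float = 0.5
    beta_alpha: float = 0.0
    pupil_noise_sd: float = 0.2
    gaze_noise_sd: float = 0.3
    blink_rate: float = 0.1
    # gaze pipeline
    gaze_cutoff_hz: float = 15.0
    dispersion_deg: float = 3.0
    min_fix_dur_s: float = 0.100
    prebounce_window_s: float = 0.400
    sd_mult: float = 1.0
    carry: bool = True
    # pupil pipeline
    pupil_cutoff_hz: float = 10.0
    blink_pad_s: float = 0.150
    baseline_window_s: float = 0.200
    response_window_s: float = 3.000
    # modelling
    models: tuple = ("hgf3", "hgf4", "rw")
    n_restarts: int = 3
    eps_mode: str = "abs"  # |eps2| (default) or "signed"
    personalised_model: str = "hgf3"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "paths"):
            raise ValueError("mode must be 'synthetic' or 'paths'")
        if self.mode == "paths" and not self.input_dir:
            raise ValueError("paths mode requires input_dir")
        if self.gaze_cutoff_hz >= 120.0 / 2 or self.pupil_cutoff_hz >= 90.0 / 2:
            raise ValueError("filter cutoff at or above Nyquist")
        if self.eps_mode not in ("abs", "signed"):
            raise ValueError("eps_mode must be 'abs' or 'signed'")
        for m in self.models:
            if m not in ("hgf3", "hgf4", "rw"):
                raise ValueError(f"unknown model {m!r}")


def _predictor_series(traj, name: str, eps_mode: str) -> np.ndarray:
    if name == "eps2":
        return traj.abs_eps2 if eps_mode == "abs" else traj.eps2
    return getattr(traj, name)


def _load_participant(pdir: Path):
    schedule = TrialSchedule.read_csv(pdir / "schedule.csv")
    events = pd.read_csv(pdir / "events.csv")
    gaze_traces, pupil_traces = [], []
    for _, row in events.iterrows():
        k = int(row["trial"])
        gdf = pd.read_csv(pdir / "gaze" / f"trial_{k:03d}.csv")
        rate = 1.0 / np.median(np.diff(gdf["t"]))
        gaze_traces.append(GazeTrace.from_frame(
            gdf, rate=rate, bounce_time=float(row["bounce_time"]),
            contact_time=float(row["contact_time"])))
        pdf = pd.read_csv(pdir / "pupil" / f"trial_{k:03d}.csv")
        prate = 1.0 / np.median(np.diff(pdf["t"]))
        pupil_traces.append(PupilTrace.from_frame(pdf, rate=prate))
    return schedule, gaze_traces, pupil_traces


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle (also written
    to ``config.outdir``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exclusions: list[dict] = []

    # ------------------------------------------------------------------ load
    if config.mode == "synthetic":
        dataset = make_dataset(
            n_participants=config.n_participants, seed=config.seed,
            coupling=Coupling(beta_eps=config.beta_eps, beta_alpha=config.beta_alpha),
            pupil_noise_sd=config.pupil_noise_sd,
            gaze_noise_sd=config.gaze_noise_sd,
            blink_spec=BlinkSpec(rate=config.blink_rate),
        )
        records = [
            (p.participant.participant_id, p.schedule, p.gaze_traces, p.pupil_traces)
            for p in dataset.participants
        ]
    else:
        root = Path(config.input_dir)
        pdirs = sorted(d for d in root.iterdir() if d.is_dir())
        if not pdirs:
            raise FileNotFoundError(f"no participant directories under {root}")
        records = []
        for pdir in pdirs:
            schedule, gtr, ptr = _load_participant(pdir)
            records.append((pdir.name, schedule, gtr, ptr))

    # ------------------------------------------------- per-participant stage
    participants: dict[str, dict] = {}
    for pid, schedule, gaze_traces, pupil_traces in records:
        gaze_tbl, gaze_ok, gaze_frac = gz.process_gaze(
            gaze_traces, sd_mult=config.sd_mult, carry=config.carry,
            dispersion_deg=config.dispersion_deg, min_dur_s=config.min_fix_dur_s,
            window_s=config.prebounce_window_s, cutoff=config.gaze_cutoff_hz,
        )
        pupil_tbl, pupil_ok, pupil_frac = pp.process_pupil(
            pupil_traces, pad_s=config.blink_pad_s, cutoff=config.pupil_cutoff_hz,
            baseline_window=config.baseline_window_s,
            response_window=config.response_window_s,
        )
        for tbl, stage in ((gaze_tbl, "gaze"), (pupil_tbl, "pupil")):
            for _, row in tbl[tbl["exclusion_reason"].notna()].iterrows():
                exclusions.append({"participant": pid, "stage": stage,
                                   "trial": int(row["trial"]),
                                   "rule": row["exclusion_reason"]})
        if not gaze_ok or not pupil_ok:
            exclusions.append({
                "participant": pid, "stage": "participant", "trial": None,
                "rule": ("gaze_missing_outliers" if not gaze_ok
                         else "pupil_missing_outliers"),
            })
            log.info("excluding participant %s (gaze_ok=%s pupil_ok=%s)",
                     pid, gaze_ok, pupil_ok)
            continue
        participants[pid] = {
            "schedule": schedule, "gaze": gaze_tbl, "pupil": pupil_tbl,
            "fractions": {"gaze": gaze_frac, "pupil": pupil_frac},
        }
        gaze_tbl.to_csv(outdir / f"{pid}_responses.csv", index=False)
        pupil_tbl.to_csv(outdir / f"{pid}_tepr.csv", index=False)
    if not participants:
        raise RuntimeError("zero participants passed QC (stage: preprocessing)")

    # ------------------------------------------------------------ model fits
    fits: dict[str, dict] = {m: {} for m in config.models}
    for pid, rec in participants.items():
        u = rec["schedule"].u
        y = rec["gaze"]["y"].to_numpy(dtype=float)
        for m in config.models:
            try:
                fits[m][pid] = model_from_id(m, u, y).fit(
                    n_restarts=config.n_restarts, seed=config.seed)
            except ValueError as exc:
                log.warning("fit %s/%s failed: %s", pid, m, exc)
    comparison = compare_models(fits)
    comparison.lme_table.to_csv(outdir / "lme_table.csv")
    comparison.pairwise_bf.to_csv(outdir / "model_comparison_bf.csv")

    for m, by_pid in fits.items():
        for pid, res in by_pid.items():
            res.to_json(outdir / f"{pid}_{m}_fit.json")

    # ----------------------------------------------------------- regressions
    beta_rows = []
    for pid, rec in participants.items():
        pupil_y = rec["pupil"]["normalized_response"].to_numpy(dtype=float)
        sources = {}
        if config.personalised_model in fits and pid in fits[config.personalised_model]:
            traj = fits[config.personalised_model][pid].trajectory
            sources["personalised"] = traj
            if hasattr(traj, "abs_eps2"):  # HGF-family trajectory
                traj.to_frame(y=rec["gaze"]["y"].to_numpy(dtype=float)).to_csv(
                    outdir / f"{pid}_trajectory.csv", index=False)
        sources["simulated"] = simulate_bayes_optimal(rec["schedule"].u)
        for source, traj in sources.items():
            for pred in PREDICTORS:
                x = _predictor_series(traj, pred, config.eps_mode)
                try:
                    beta = st.robust_regress(pupil_y, x)
                except ValueError as exc:
                    log.warning("regression %s/%s/%s skipped: %s",
                                pid, source, pred, exc)
                    beta = np.nan
                beta_rows.append({"participant": pid, "source": source,
                                  "predictor": pred, "beta": beta})
    betas = pd.DataFrame(beta_rows)
    betas.to_csv(outdir / "beta_weights.csv", index=False)
    group = st.group_beta_table(betas)
    # personalised vs simulated contrast per predictor
    contrast_rows = []
    wide = betas.pivot_table(index=["participant", "predictor"], columns="source",
                             values="beta").reset_index()
    if {"personalised", "simulated"} <= set(wide.columns):
        for pred, grp in wide.groupby("predictor"):
            try:
                gs = st.paired_t(grp["personalised"], grp["simulated"])
                contrast_rows.append({"predictor": pred, **gs.to_dict()})
            except ValueError as exc:
                log.warning("paired contrast %s skipped: %s", pred, exc)
    contrast = pd.DataFrame(contrast_rows)
    group.to_csv(outdir / "group_stats.csv", index=False)
    contrast.to_csv(outdir / "personalised_vs_simulated.csv", index=False)

    qc_report = {
        "n_input_participants": len(records),
        "n_included_participants": len(participants),
        "exclusions": exclusions,
    }
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(qc_report, fh, indent=2)
    summary = {
        "config": asdict(config),
        "model_comparison": {
            "summed_lme": comparison.group_lme.to_dict(),
            "best_model": comparison.best_model,
        },
        "group_stats": group.to_dict(orient="records"),
        "personalised_vs_simulated": contrast.to_dict(orient="records"),
        "qc": {"n_included": len(participants),
               "n_excluded": len(records) - len(participants)},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return {
        "participants": participants, "fits": fits, "comparison": comparison,
        "betas": betas, "group_stats": group, "contrast": contrast,
        "qc_report": qc_report, "summary": summary,
    }


def validate_inputs(input_dir) -> pd.DataFrame:
    """Schema checks for a participant-directory tree; reports per file."""
    root = Path(input_dir)
    rows = []

    def check(path, required, t_col="t"):
        if not path.exists():
            rows.append({"file": str(path), "ok": False, "detail": "missing file"})
            return
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            rows.append({"file": str(path), "ok": False, "detail": f"unreadable: {exc}"})
            return
        missing = sorted(set(required) - set(df.columns))
        if missing:
            rows.append({"file": str(path), "ok": False,
                         "detail": f"missing columns: {missing}"})
            return
        if t_col is not None and len(df) > 1:
            bad = np.flatnonzero(np.diff(df[t_col].to_numpy()) <= 0)
            if len(bad):
                rows.append({"file": str(path), "ok": False,
                             "detail": f"non-monotone {t_col} at row {int(bad[0]) + 1}"})
                return
        rows.append({"file": str(path), "ok": True, "detail": ""})

    for pdir in sorted(d for d in root.iterdir() if d.is_dir()):
        check(pdir / "schedule.csv", {"trial", "block", "u", "p_normal"}, t_col=None)
        check(pdir / "events.csv", {"trial", "u", "bounce_time", "contact_time"},
              t_col=None)
        for sub, cols in (("gaze", {"t", "pitch", "yaw", "valid"}),
                          ("pupil", {"t", "left_mm", "right_mm"})):
            for f in sorted((pdir / sub).glob("trial_*.csv")):
                check(f, cols)
    return pd.DataFrame(rows)
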