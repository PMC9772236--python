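"""MAP fitting of perceptual + response models, Laplace model evidence,
and model comparison.

Models are fitted per participant to the pair (``u``: trial-wise binary
inputs, ``y``: trial-wise binary anticipatory responses, NaN = missing).
Estimation follows the usual approximate-Bayesian recipe:

* every free parameter carries an independent Gaussian prior in an
  unconstrained *estimation space* (identity for means and omegas, log
  for variances / ``theta`` / ``zeta``, logit for the Rescorla-Wagner
  ``alpha`` and ``v0``),
* the posterior mode is found with a quasi-Newton optimizer (BFGS) from
  the prior mean plus perturbed restarts,
* the log-model evidence (LME) is the Laplace approximation
  ``lme = -nlj* + (d/2) log(2 pi) - (1/2) log det H`` with ``H`` the
  Hessian of the negative log joint at the mode,
* group-level comparison sums LMEs over participants (fixed effects) and
  exponentiates differences into Bayes factors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .hgf import (
    HGFParams,
    InstabilityError,
    hgf_filter,
    rw_filter,
    unitsq_sigmoid_loglik,
)

__all__ = [
    "ParamSpec",
    "LearningModel",
    "BinaryHGF",
    "RescorlaWagner",
    "LearningModelResults",
    "ModelComparison",
    "hessian_fd",
    "compute_lme",
    "compare_models",
    "identifiability_matrix",
    "model_from_id",
]


def _identity(x):
    return x


def _logit(p):
    return math.log(p / (1.0 - p))


_TRANSFORMS = {
    "identity": (_identity, _identity),
    "log": (math.exp, math.log),
    "logit": (lambda x: 1.0 / (1.0 + math.exp(-x)), _logit),
}


@dataclass(frozen=True)
class ParamSpec:
    """Prior for one parameter, stated in estimation space.

    ``prior_var == 0`` marks the parameter as fixed at ``prior_mean``.
    ``transform`` maps estimation space -> native space.
    """

    name: str
    prior_mean: float
    prior_var: float
    transform: str = "identity"

    def to_native(self, x: float) -> float:
        return _TRANSFORMS[self.transform][0](x)

    def to_estimation(self, x: float) -> float:
        return _TRANSFORMS[self.transform][1](x)

    @property
    def fixed(self) -> bool:
        return self.prior_var == 0


def _default_hgf_specs(levels: int) -> list[ParamSpec]:
    specs = [
        ParamSpec("kappa", 1.0, 0.0),
        ParamSpec("omega", -5.6, 8.0),
        ParamSpec("log_theta", -4.0, 0.0),
        ParamSpec("mu2_0", 0.0, 8.0),
        ParamSpec("sigma2_0", math.log(0.1), 1.0, "log"),
        ParamSpec("mu3_0", 1.0, 8.0),
        ParamSpec("sigma3_0", 0.0, 1.0, "log"),
    ]
    if levels == 4:
        specs += [
            ParamSpec("kappa3", 1.0, 0.0),
            ParamSpec("omega3", -5.6, 8.0),
            ParamSpec("log_theta4", -4.0, 0.0),
            ParamSpec("mu4_0", 1.0, 8.0),
            ParamSpec("sigma4_0", 0.0, 1.0, "log"),
        ]
    specs.append(ParamSpec("zeta", math.log(48.0), 1.0, "log"))
    return specs


def _default_rw_specs() -> list[ParamSpec]:
    return [
        ParamSpec("alpha", 0.0, 1.0, "logit"),  # native prior mean 0.5
        ParamSpec("v0", 0.0, 1.0, "logit"),
        ParamSpec("zeta", math.log(48.0), 1.0, "log"),
    ]


class LearningModel:
    """Base class binding one participant's (u, y) series to a model family.

    Subclasses define ``param_specs`` and ``_trajectory``; everything else
    (negative log joint, MAP fit, Laplace evidence) is shared.
    """

    model_id: str = "base"

    def __init__(self, u, y=None, param_specs: list[ParamSpec] | None = None):
        self.u = np.asarray(u, dtype=float)
        if y is None:
            y = np.full(len(self.u), np.nan)
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != len(self.u):
            raise ValueError("u and y must have equal length")
        if param_specs is not None:
            self.param_specs = list(param_specs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, u_col: str = "u", y_col: str = "y", **kw):
        """Build a model from a trial table with input and response columns."""
        return cls(df[u_col].to_numpy(), df[y_col].to_numpy(), **kw)

    # -- parameter bookkeeping ------------------------------------------
    @property
    def free_specs(self) -> list[ParamSpec]:
        return [s for s in self.param_specs if not s.fixed]

    @property
    def free_names(self) -> list[str]:
        return [s.name for s in self.free_specs]

    @property
    def k_free(self) -> int:
        return len(self.free_specs)

    def _native_params(self, free_vec) -> dict:
        vals = {}
        i = 0
        for s in self.param_specs:
            x = s.prior_mean if s.fixed else float(free_vec[i])
            if not s.fixed:
                i += 1
            vals[s.name] = s.to_native(x)
        return vals

    def start_vector(self) -> np.ndarray:
        return np.array([s.prior_mean for s in self.free_specs])

    # -- model-specific pieces ------------------------------------------
    def _trajectory(self, native: dict):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- objective -------------------------------------------------------
    def loglike(self, native: dict) -> float:
        traj = self._trajectory(native)
        return float(np.sum(unitsq_sigmoid_loglik(traj.mu1hat, self.y, native["zeta"])))

    def neg_log_joint(self, free_vec) -> float:
        """Negative log joint: -(response log-likelihood + Gaussian log priors).

        Filter instability makes the parameter point invalid and returns +inf.
        """
        free_vec = np.asarray(free_vec, dtype=float)
        if not np.all(np.isfinite(free_vec)):
            return np.inf
        native = self._native_params(free_vec)
        try:
            ll = self.loglike(native)
        except (InstabilityError, OverflowError):
            return np.inf
        lp = 0.0
        for s, x in zip(self.free_specs, free_vec):
            lp += -0.5 * math.log(2 * math.pi * s.prior_var) \
                - 0.5 * (x - s.prior_mean) ** 2 / s.prior_var
        val = -(ll + lp)
        return val if np.isfinite(val) else np.inf

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        n_restarts: int = 5,
        seed: int = 0,
        perturb_sd: float = 0.5,
        gtol: float = 1e-5,
        require_min_responses: int = 10,
    ) -> "LearningModelResults":
        """MAP estimation by BFGS from the prior mean plus perturbed restarts.

        The best converged optimum wins; ties break on lower negative log
        joint, then on smaller parameter-vector norm. Deterministic given
        ``seed``.
        """
        n_obs = int(np.sum(~np.isnan(self.y)))
        if n_obs < require_min_responses:
            raise ValueError(
                f"need >= {require_min_responses} non-missing responses, got {n_obs}"
            )
        rng = np.random.default_rng(seed)
        x0 = self.start_vector()
        starts = [x0] + [
            x0 + rng.normal(0.0, perturb_sd, size=len(x0)) for _ in range(n_restarts - 1)
        ]
        best = None
        any_converged = False
        for x_start in starts:
            if not np.isfinite(self.neg_log_joint(x_start)):
                continue
            res = optimize.minimize(
                self.neg_log_joint, x_start, method="BFGS", options={"gtol": gtol}
            )
            ok = bool(res.success) and np.isfinite(res.fun)
            if not np.isfinite(res.fun):
                continue
            key = (round(float(res.fun), 10), float(np.linalg.norm(res.x)))
            if best is None or (ok and not best[2]) or (ok == best[2] and key < best[0]):
                best = (key, res, ok)
            any_converged = any_converged or ok
        if best is None:
            x_map = x0
            nlj = self.neg_log_joint(x0)
        else:
            x_map = np.asarray(best[1].x, dtype=float)
            nlj = float(best[1].fun)
        lme, cov, pd_fixed = (np.nan, None, False)
        if np.isfinite(nlj) and self.k_free > 0:
            H = None
            for h in (1e-4, 1e-5, 1e-3):
                H = hessian_fd(self.neg_log_joint, x_map, h=h)
                if np.all(np.isfinite(H)):
                    break
            if not np.all(np.isfinite(H)):
                # MAP sits against an instability boundary: keep the finite
                # curvature entries, neutralise the rest, and flag it
                d = H.shape[0]
                diag = np.where(np.isfinite(np.diag(H)), np.diag(H), 1.0)
                Hf = np.where(np.isfinite(H), H, 0.0)
                Hf[np.diag_indices(d)] = np.clip(diag, 1e-6, None)
                H, pd_fixed = Hf, True
            lme, cov, jittered = compute_lme(nlj, H, return_cov=True)
            pd_fixed = pd_fixed or jittered
        elif self.k_free == 0:
            lme = -nlj
        native = self._native_params(x_map)
        return LearningModelResults(
            model=self,
            model_id=self.model_id,
            params_estimation=dict(zip(self.free_names, x_map)),
            params=native,
            neg_log_joint_=nlj,
            lme=lme,
            laplace_cov=cov,
            converged=any_converged,
            hessian_jittered=pd_fixed,
            n_obs=n_obs,
            trajectory=self._trajectory(native),
        )


class BinaryHGF(LearningModel):
    """3- or 4-level binary HGF with unit-square sigmoid responses."""

    def __init__(self, u, y=None, levels: int = 3, param_specs=None):
        if levels not in (3, 4):
            raise ValueError("levels must be 3 or 4")
        self.levels = levels
        self.model_id = f"hgf{levels}"
        self.param_specs = _default_hgf_specs(levels)
        super().__init__(u, y, param_specs)

    def _trajectory(self, native: dict):
        params = HGFParams(**{k: v for k, v in native.items() if k != "zeta"},
                           zeta=native["zeta"])
        return hgf_filter(self.u, params, levels=self.levels)


class RescorlaWagner(LearningModel):
    """Fixed-learning-rate delta-rule model with unit-square sigmoid responses."""

    model_id = "rw"

    def __init__(self, u, y=None, param_specs=None):
        self.param_specs = _default_rw_specs()
        super().__init__(u, y, param_specs)

    def _trajectory(self, native: dict):
        return rw_filter(self.u, native["alpha"], native["v0"])


def model_from_id(model_id: str, u, y=None) -> LearningModel:
    if model_id == "hgf3":
        return BinaryHGF(u, y, levels=3)
    if model_id == "hgf4":
        return BinaryHGF(u, y, levels=4)
    if model_id == "rw":
        return RescorlaWagner(u, y)
    raise ValueError(f"unknown model_id {model_id!r}")


@dataclass
class LearningModelResults:
    """MAP fit of one model to one participant."""

    model: LearningModel
    model_id: str
    params_estimation: dict
    params: dict
    neg_log_joint_: float
    lme: float
    laplace_cov: pd.DataFrame | None
    converged: bool
    hessian_jittered: bool
    n_obs: int
    trajectory: object

    def summary(self) -> str:
        rows = []
        free = set(self.model.free_names)
        for s in self.model.param_specs:
            rows.append(
                {
                    "parameter": s.name,
                    "estimate": self.params[s.name],
                    "space": s.transform,
                    "status": "free" if s.name in free else "fixed",
                    "prior_mean": s.prior_mean,
                    "prior_var": s.prior_var,
                }
            )
        tbl = pd.DataFrame(rows).to_string(index=False, float_format=lambda v: f"{v: .4f}")
        head = (
            f"Model: {self.model_id}   trials: {len(self.model.u)}   "
            f"responses: {self.n_obs}\n"
            f"neg log joint: {self.neg_log_joint_:.4f}   LME (Laplace): {self.lme:.4f}   "
            f"converged: {self.converged}\n"
        )
        return head + tbl

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params_native": self.params,
            "params_estimation": self.params_estimation,
            "neg_log_joint": self.neg_log_joint_,
            "lme": self.lme,
            "converged": bool(self.converged),
            "hessian_jittered": bool(self.hessian_jittered),
            "n_obs": self.n_obs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def hessian_fd(f, x, h: float = 1e-4) -> np.ndarray:
    """Hessian by central finite differences with step ``h`` per coordinate."""
    x = np.asarray(x, dtype=float)
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h**2)
    return H


def compute_lme(nlj_star: float, hessian: np.ndarray, return_cov: bool = False):
    """Laplace log-model evidence from the optimum and its Hessian.

    ``lme = -nlj* + (d/2) log(2 pi) - (1/2) log det H``. A non-positive-
    definite Hessian is jittered to the nearest usable matrix and flagged.
    """
    H = np.asarray(hessian, dtype=float)
    H = 0.5 * (H + H.T)
    d = H.shape[0]
    if d == 0:
        return (-nlj_star, None, False) if return_cov else -nlj_star
    jittered = False
    try:
        L = np.linalg.cholesky(H)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Huse = H
    except np.linalg.LinAlgError:
        # nearest usable matrix: clip the eigenspectrum to a positive floor
        jittered = True
        w, V = np.linalg.eigh(H)
        floor = max(w.max(), 1.0) * 1e-8
        w = np.clip(w, floor, None)
        Huse = (V * w) @ V.T
        logdet = float(np.sum(np.log(w)))
    lme = -nlj_star + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdet
    if not return_cov:
        return lme
    cov = np.linalg.inv(Huse)
    return lme, cov, jittered


@dataclass
class ModelComparison:
    """Fixed-effects (summed-LME) comparison across participants."""

    group_lme: pd.Series  # index: model_id
    lme_table: pd.DataFrame  # participants x models
    n_dropped: int = 0

    def bayes_factor(self, a: str, b: str) -> float:
        return float(np.exp(self.group_lme[a] - self.group_lme[b]))

    @property
    def pairwise_bf(self) -> pd.DataFrame:
        ids = list(self.group_lme.index)
        return pd.DataFrame(
            [[self.bayes_factor(a, b) for b in ids] for a in ids], index=ids, columns=ids
        )

    @property
    def best_model(self) -> str:
        return str(self.group_lme.idxmax())

    def summary(self) -> str:
        df = pd.DataFrame({"summed_lme": self.group_lme})
        df["delta_lme"] = df["summed_lme"] - df["summed_lme"].max()
        return (
            f"Model comparison over {len(self.lme_table)} participants "
            f"(fixed effects, {self.n_dropped} dropped)\n"
            + df.to_string(float_format=lambda v: f"{v: .2f}")
        )


def compare_models(fits: dict[str, dict]) -> ModelComparison:
    """Compare models by summed LME.

    Parameters
    ----------
    fits : mapping model_id -> mapping participant_id -> LearningModelResults

    Participants missing any model's fit are excluded pairwise with a count.
    """
    models = list(fits)
    common = set.intersection(*(set(v) for v in fits.values()))
    all_pids = set.union(*(set(v) for v in fits.values()))
    n_dropped = len(all_pids) - len(common)
    pids = sorted(common)
    tbl = pd.DataFrame(
        {m: [fits[m][p].lme for p in pids] for m in models},
        index=pd.Index(pids, name="participant"),
    )
    return ModelComparison(group_lme=tbl.sum(axis=0), lme_table=tbl, n_dropped=n_dropped)


def identifiability_matrix(results: list, flag_threshold: float = 0.8):
    """Average Laplace-posterior correlation matrices across participants.

    Returns ``(mean_corr: DataFrame, flags: list[(name_i, name_j, r)])``
    where flags mark |r| above ``flag_threshold`` — a warning that the two
    parameters may not be independently identifiable.
    """
    results = [r for r in results if r.converged and r.laplace_cov is not None]
    if len(results) < 2:
        raise ValueError("need >= 2 converged fits")
    names = results[0].model.free_names
    acc = np.zeros((len(names), len(names)))
    for r in results:
        cov = np.asarray(r.laplace_cov, dtype=float)
        sd = np.sqrt(np.diag(cov))
        acc += cov / np.outer(sd, sd)
    mean_corr = pd.DataFrame(acc / len(results), index=names, columns=names)
    flags = [
        (names[i], names[j], float(mean_corr.iat[i, j]))
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(mean_corr.iat[i, j]) > flag_threshold
    ]
    return mean_corr, flags
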