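"""Binary Hierarchical Gaussian Filters and the Rescorla-Wagner comparator.

The perceptual models implemented here describe an agent learning the
probability of a binary environmental outcome (here: whether an oncoming
ball is a "normal" bounce, ``u = 1``) whose generating probability drifts
over time.  The 3-level HGF tracks

* level 1 - the outcome itself; the prediction is ``mu1hat = s(mu2)``,
* level 2 - a Gaussian random walk on the logit-probability ("tendency")
  ``x2`` with step variance ``exp(kappa * mu3 + omega)``,
* level 3 - a Gaussian random walk on the log-volatility of ``x2`` with
  step variance ``theta = exp(log_theta)``.

The 4-level variant adds one more volatility level on top of level 3.
Belief updating is variational/quadratic, which yields the closed-form
per-trial update equations coded in the numba kernels below.  Two derived
quantities drive the downstream pupillometry analyses:

* ``eps2 = sigma2(k) * delta1(k)`` - the precision-weighted prediction
  error about the outcome (the level-2 update step), and
* ``alpha = sigma2(k)`` - the trial-specific learning rate (the gain on
  ``delta1`` in the level-2 mean update).

Responses are linked to beliefs through the unit-square sigmoid
``P(y=1) = mu1hat**zeta / (mu1hat**zeta + (1 - mu1hat)**zeta)`` with
decision noise ``zeta > 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "HGFParams",
    "HGFTrajectory",
    "RWParams",
    "RWTrajectory",
    "InstabilityError",
    "sigmoid",
    "hgf_filter",
    "rw_filter",
    "unitsq_sigmoid_prob",
    "unitsq_sigmoid_loglik",
    "simulate_bayes_optimal",
]

_CLIP = 1e-12


class InstabilityError(ValueError):
    """Raised when a filter update produces a non-positive precision or a
    non-finite state; carries the offending 1-based trial index."""

    def __init__(self, trial: int, message: str | None = None):
        self.trial = int(trial)
        super().__init__(message or f"filter became unstable at trial {self.trial}")


@dataclass
class HGFParams:
    """Perceptual + response parameters of the binary HGF.

    ``log_theta`` stores the top-level random-walk variance in log space
    (native value ``exp(log_theta)``).  The level-4 fields are ignored by
    the 3-level filter.
    """

    kappa: float = 1.0
    omega: float = -5.6
    log_theta: float = -4.0
    mu2_0: float = 0.0
    sigma2_0: float = 0.1
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    # 4-level extension: level-3 step variance becomes exp(kappa3*mu4 + omega3)
    kappa3: float = 1.0
    omega3: float = -5.6
    log_theta4: float = -4.0
    mu4_0: float = 1.0
    sigma4_0: float = 1.0
    zeta: float = 48.0

    def validate(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be > 0")
        for name in ("sigma2_0", "sigma3_0", "sigma4_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class HGFTrajectory:
    """Per-trial belief trajectory of a binary HGF run.

    All arrays have one entry per trial (posterior values *after* seeing
    that trial's input).  ``mu4``/``sigma4`` are NaN for the 3-level model.
    """

    u: np.ndarray
    mu1hat: np.ndarray
    delta1: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    delta2: np.ndarray
    mu3: np.ndarray
    sigma3: np.ndarray
    mu4: np.ndarray
    sigma4: np.ndarray
    mu2_0: float
    levels: int = 3

    @property
    def eps2(self) -> np.ndarray:
        """Precision-weighted prediction error sigma2(k) * delta1(k)."""
        return self.sigma2 * self.delta1

    @property
    def abs_eps2(self) -> np.ndarray:
        return np.abs(self.eps2)

    @property
    def alpha_lr(self) -> np.ndarray:
        """Trial-wise learning rate (the gain on delta1), here sigma2(k)."""
        return self.sigma2

    def __len__(self) -> int:
        return len(self.u)

    def to_frame(self, y: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "u": self.u,
                "mu1hat": self.mu1hat,
                "mu2": self.mu2,
                "sigma2": self.sigma2,
                "mu3": self.mu3,
                "sigma3": self.sigma3,
                "delta1": self.delta1,
                "delta2": self.delta2,
                "eps2": self.eps2,
                "abs_eps2": self.abs_eps2,
                "alpha_lr": self.alpha_lr,
            }
        )
        if self.levels == 4:
            df["mu4"] = self.mu4
            df["sigma4"] = self.sigma4
        if y is not None:
            df.insert(2, "y", y)
        return df


@dataclass
class RWParams:
    alpha: float = 0.5
    v0: float = 0.5
    zeta: float = 48.0

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 <= self.v0 <= 1):
            raise ValueError("v0 must be in [0, 1]")
        if self.zeta <= 0:
            raise ValueError("zeta must be > 0")


@dataclass
class RWTrajectory:
    """Rescorla-Wagner value/prediction-error trajectory. ``v`` holds the
    post-update value; ``vhat`` the pre-update prediction used on trial k."""

    u: np.ndarray
    vhat: np.ndarray
    v: np.ndarray
    delta: np.ndarray

    # expose the prediction under the same name the response model uses
    @property
    def mu1hat(self) -> np.ndarray:
        return self.vhat

    def __len__(self) -> int:
        return len(self.u)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "u": self.u,
                "vhat": self.vhat,
                "v": self.v,
                "delta": self.delta,
            }
        )


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# numba kernels: one row per trial, status code 0 = ok, k>0 = unstable at k
# ---------------------------------------------------------------------------


@njit(cache=False)
def _hgf3_kernel(u, kappa, omega, log_theta, mu2, sa2, mu3, sa3, out):  # pragma: no cover
    n = u.shape[0]
    theta = math.exp(log_theta)
    for k in range(n):
        # prediction and outcome prediction error
        if mu2 >= 0.0:
            mu1hat = 1.0 / (1.0 + math.exp(-mu2))
        else:
            e = math.exp(mu2)
            mu1hat = e / (1.0 + e)
        d1 = u[k] - mu1hat
        v2 = math.exp(kappa * mu3 + omega)  # predicted level-2 step variance
        pih2 = 1.0 / (sa2 + v2)
        pi2 = pih2 + mu1hat * (1.0 - mu1hat)
        if pi2 <= 0.0 or not math.isfinite(pi2):
            return k + 1
        sa2n = 1.0 / pi2
        mu2n = mu2 + sa2n * d1
        # volatility prediction error and level-3 update
        d2 = (sa2n + (mu2n - mu2) ** 2) * pih2 - 1.0
        pih3 = 1.0 / (sa3 + theta)
        w2 = v2 * pih2
        pi3 = pih3 + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
        if pi3 <= 0.0 or not math.isfinite(pi3):
            return k + 1
        sa3n = 1.0 / pi3
        mu3n = mu3 + sa3n * 0.5 * kappa * w2 * d2
        if not (math.isfinite(mu2n) and math.isfinite(mu3n)):
            return k + 1
        mu2, sa2, mu3, sa3 = mu2n, sa2n, mu3n, sa3n
        out[k, 0] = mu1hat
        out[k, 1] = d1
        out[k, 2] = mu2
        out[k, 3] = sa2
        out[k, 4] = d2
        out[k, 5] = mu3
        out[k, 6] = sa3
    return 0


@njit(cache=False)
def _hgf4_kernel(u, kappa, omega, kappa3, omega3, log_theta4,
                 mu2, sa2, mu3, sa3, mu4, sa4, out):  # pragma: no cover
    n = u.shape[0]
    theta4 = math.exp(log_theta4)
    for k in range(n):
        if mu2 >= 0.0:
            mu1hat = 1.0 / (1.0 + math.exp(-mu2))
        else:
            e = math.exp(mu2)
            mu1hat = e / (1.0 + e)
        d1 = u[k] - mu1hat
        v2 = math.exp(kappa * mu3 + omega)
        pih2 = 1.0 / (sa2 + v2)
        pi2 = pih2 + mu1hat * (1.0 - mu1hat)
        if pi2 <= 0.0 or not math.isfinite(pi2):
            return k + 1
        sa2n = 1.0 / pi2
        mu2n = mu2 + sa2n * d1
        d2 = (sa2n + (mu2n - mu2) ** 2) * pih2 - 1.0
        # level 3: step variance now governed by the level-4 belief
        v3 = math.exp(kappa3 * mu4 + omega3)
        pih3 = 1.0 / (sa3 + v3)
        w2 = v2 * pih2
        pi3 = pih3 + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
        if pi3 <= 0.0 or not math.isfinite(pi3):
            return k + 1
        sa3n = 1.0 / pi3
        mu3n = mu3 + sa3n * 0.5 * kappa * w2 * d2
        # level 4: same functional form, closed by theta4
        d3 = (sa3n + (mu3n - mu3) ** 2) * pih3 - 1.0
        pih4 = 1.0 / (sa4 + theta4)
        w3 = v3 * pih3
        pi4 = pih4 + 0.5 * kappa3 * kappa3 * w3 * (w3 + (2.0 * w3 - 1.0) * d3)
        if pi4 <= 0.0 or not math.isfinite(pi4):
            return k + 1
        sa4n = 1.0 / pi4
        mu4n = mu4 + sa4n * 0.5 * kappa3 * w3 * d3
        if not (math.isfinite(mu2n) and math.isfinite(mu3n) and math.isfinite(mu4n)):
            return k + 1
        mu2, sa2, mu3, sa3, mu4, sa4 = mu2n, sa2n, mu3n, sa3n, mu4n, sa4n
        out[k, 0] = mu1hat
        out[k, 1] = d1
        out[k, 2] = mu2
        out[k, 3] = sa2
        out[k, 4] = d2
        out[k, 5] = mu3
        out[k, 6] = sa3
        out[k, 7] = mu4
        out[k, 8] = sa4
    return 0


@njit(cache=False)
def _rw_kernel(u, alpha, v0, out):  # pragma: no cover
    v = v0
    for k in range(u.shape[0]):
        d = u[k] - v
        vn = v + alpha * d
        out[k, 0] = v
        out[k, 1] = vn
        out[k, 2] = d
        v = vn
    return 0


def _as_u(u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or len(u) == 0:
        raise ValueError("input series u must be a non-empty 1-D array")
    if not np.isin(u, (0.0, 1.0)).all():
        raise ValueError("inputs u must be binary (0/1)")
    return u


def hgf_filter(u, params: HGFParams, levels: int = 3) -> HGFTrajectory:
    """Run the binary HGF forward over an input sequence.

    Parameters
    ----------
    u : array-like of {0, 1}
        Trial-wise inputs (1 = normal bounce).
    params : HGFParams
    levels : {3, 4}

    Raises
    ------
    InstabilityError
        If any update yields a non-positive precision or non-finite state.
    """
    u = _as_u(u)
    params.validate()
    n = len(u)
    if levels == 3:
        out = np.empty((n, 7))
        status = _hgf3_kernel(
            u, params.kappa, params.omega, params.log_theta,
            params.mu2_0, params.sigma2_0, params.mu3_0, params.sigma3_0, out,
        )
        mu4 = np.full(n, np.nan)
        sa4 = np.full(n, np.nan)
    elif levels == 4:
        out = np.empty((n, 9))
        status = _hgf4_kernel(
            u, params.kappa, params.omega, params.kappa3, params.omega3,
            params.log_theta4, params.mu2_0, params.sigma2_0,
            params.mu3_0, params.sigma3_0, params.mu4_0, params.sigma4_0, out,
        )
        mu4 = out[:, 7]
        sa4 = out[:, 8]
    else:
        raise ValueError("levels must be 3 or 4")
    if status != 0:
        raise InstabilityError(status)
    return HGFTrajectory(
        u=u, mu1hat=out[:, 0], delta1=out[:, 1], mu2=out[:, 2], sigma2=out[:, 3],
        delta2=out[:, 4], mu3=out[:, 5], sigma3=out[:, 6], mu4=mu4, sigma4=sa4,
        mu2_0=params.mu2_0, levels=levels,
    )


def rw_filter(u, alpha: float, v0: float = 0.5) -> RWTrajectory:
    """Rescorla-Wagner delta rule: v(k) = v(k-1) + alpha * (u(k) - v(k-1))."""
    u = _as_u(u)
    RWParams(alpha=alpha, v0=v0).validate()
    out = np.empty((len(u), 3))
    _rw_kernel(u, float(alpha), float(v0), out)
    return RWTrajectory(u=u, vhat=out[:, 0], v=out[:, 1], delta=out[:, 2])


def unitsq_sigmoid_prob(mu1hat, y, zeta: float):
    """Unit-square sigmoid response probability P(y | mu1hat, zeta).

    ``P(y=1) = m**zeta / (m**zeta + (1-m)**zeta)`` with ``m`` clipped away
    from {0, 1}.  Missing responses (NaN) get probability 1, i.e. they
    contribute nothing to the likelihood.
    """
    if zeta <= 0:
        raise ValueError("zeta must be > 0")
    return np.exp(unitsq_sigmoid_loglik(mu1hat, y, zeta))


def unitsq_sigmoid_loglik(mu1hat, y, zeta: float):
    """Elementwise log P(y | mu1hat, zeta); 0 for missing (NaN) y."""
    m = np.clip(np.asarray(mu1hat, dtype=float), _CLIP, 1.0 - _CLIP)
    y = np.asarray(y, dtype=float)
    # log P(y=1) = zeta*log m - logaddexp(zeta*log m, zeta*log(1-m))
    a = zeta * np.log(m)
    b = zeta * np.log1p(-m)
    norm = np.logaddexp(a, b)
    logp1 = a - norm
    logp0 = b - norm
    out = np.where(y == 1.0, logp1, logp0)
    out = np.where(np.isnan(y), 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def simulate_bayes_optimal(u, params: HGFParams | None = None, levels: int = 3) -> HGFTrajectory:
    """Forward-filter an input sequence with fixed (prior-mean) parameters.

    This is the "simulated Bayesian observer": no fitting, just optimal
    belief updating under the default parameterisation, used to build the
    theoretical predictor set (mu2, mu3, |eps2|, alpha).
    """
    if params is None:
        params = HGFParams()
    return hgf_filter(u, params, levels=levels)
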