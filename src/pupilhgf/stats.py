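"""Group-level statistics: robust regression of pupil responses on
model-derived surprise quantities, Winsorized one-sample / paired t-tests
with Cohen's d, default (JZS) Bayes factors, and the sensitivity analysis.

The per-participant regression slope ("beta weight") measures SD-units of
pupil response per SD of predictor; robust (bisquare) estimation guards
against the heavy-tailed trajectories the hierarchical model produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, optimize, stats

__all__ = [
    "GroupStats",
    "robust_regress",
    "winsorize_betas",
    "one_sample_t",
    "paired_t",
    "jzs_bf",
    "sensitivity_d",
    "bf_category",
    "normal_outlier_threshold",
]

WINSOR_Z = 3.29
BISQUARE_C = 4.685
JZS_SCALE = 0.707


@dataclass
class GroupStats:
    """One-sample (or paired-difference) t-test summary."""

    t: float
    df: int
    p: float
    cohens_d: float
    bf10: float
    n: int
    mean: float

    def summary(self) -> str:
        return (
            f"t({self.df}) = {self.t:.2f}, p = {self.p:.3g}, d = {self.cohens_d:.2f}, "
            f"BF10 = {self.bf10:.2f} ({bf_category(self.bf10)}), n = {self.n}"
        )

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p, "cohens_d": self.cohens_d,
            "bf10": self.bf10, "n": self.n, "mean": self.mean,
            "bf_category": bf_category(self.bf10),
        }


def robust_regress(y, x, c: float = BISQUARE_C, tol: float = 1e-6,
                   maxiter: int = 50) -> float:
    """Robust slope of normalized pupil response on a standardized predictor.

    The predictor is z-scored, then intercept + slope are fitted by IRLS
    with Tukey bisquare weights (tuning constant 4.685).  Missing entries
    in either series are dropped pairwise.  Returns the slope.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError(f"need >= 10 complete pairs, got {len(x)}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("predictor is constant")
    xs = (x - x.mean()) / sd
    X = sm.add_constant(xs)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=c))
    res = model.fit(conv="coefs", tol=tol, maxiter=maxiter)
    return float(res.params[1])


def winsorize_betas(values, z_threshold: float = WINSOR_Z) -> np.ndarray:
    """Replace values beyond ``z_threshold`` SDs of the input's mean with a
    score 1 % more extreme than the next most extreme value on that side.

    Applied once, with z computed from the original sample.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 values")
    mean, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return x.copy()
    z = (x - mean) / sd
    out = x.copy()
    high = z > z_threshold
    low = z < -z_threshold
    if high.any():
        rest = x[~high]
        nxt = rest.max()
        out[high] = nxt + 0.01 * abs(nxt)
    if low.any():
        rest = x[~low]
        nxt = rest.min()
        out[low] = nxt - 0.01 * abs(nxt)
    return out


def one_sample_t(values, mu: float = 0.0, cauchy_scale: float = JZS_SCALE) -> GroupStats:
    """Two-sided one-sample t-test with Cohen's d = t / sqrt(n) and a JZS
    Bayes factor."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    t = float((x.mean() - mu) / (sd / math.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    d = t / math.sqrt(n)
    return GroupStats(t=t, df=df, p=p, cohens_d=d,
                      bf10=jzs_bf(t, n, cauchy_scale), n=n, mean=float(x.mean()))


def paired_t(a, b, cauchy_scale: float = JZS_SCALE) -> GroupStats:
    """Paired t-test on pairwise-complete differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired inputs must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    return one_sample_t(a[ok] - b[ok], 0.0, cauchy_scale)


def jzs_bf(t: float, n: int, cauchy_scale: float = JZS_SCALE) -> float:
    """Default two-sided JZS Bayes factor for a one-sample/paired design.

    Marginal likelihood under a Cauchy(0, r) prior on the standardized
    effect size against the point null, by numerical integration over the
    mixing variance g (the Cauchy written as a scale mixture of normals).
    Symmetric in +/- t.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    r = cauchy_scale
    nu = n - 1
    t2 = float(t) ** 2

    def integrand(g):
        return (
            (1.0 + n * g) ** -0.5
            * (1.0 + t2 / ((1.0 + n * g) * nu)) ** (-(nu + 1.0) / 2.0)
            * r / math.sqrt(2.0 * math.pi)
            * g ** -1.5
            * math.exp(-r * r / (2.0 * g))
        )

    alt, err = integrate.quad(integrand, 0.0, np.inf)
    if not np.isfinite(alt) or (alt > 0 and err / alt > 1e-4):
        raise RuntimeError(f"JZS integration unreliable (value {alt}, abserr {err})")
    null = (1.0 + t2 / nu) ** (-(nu + 1.0) / 2.0)
    return float(alt / null)


def sensitivity_d(n: int, alpha: float = 0.05, power: float = 0.80,
                  tails: int = 1, xtol: float = 1e-6) -> float:
    """Minimal detectable Cohen's d of a one-sample t-test.

    Inverts the noncentral-t power function: finds d with
    ``P(reject at level alpha | ncp = d sqrt(n), df = n-1) = power``.
    One-tailed by default.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    nu = n - 1
    if tails == 1:
        tcrit = stats.t.ppf(1.0 - alpha, nu)

        def power_fn(d):
            return stats.nct.sf(tcrit, nu, d * math.sqrt(n))
    elif tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, nu)

        def power_fn(d):
            ncp = d * math.sqrt(n)
            upper = stats.nct.sf(tcrit, nu, ncp)
            lower = stats.nct.cdf(-tcrit, nu, ncp)
            # far tails can underflow to NaN; they contribute ~0 power there
            if not np.isfinite(upper):
                upper = 1.0 if ncp > tcrit else 0.0
            if not np.isfinite(lower):
                lower = 0.0
            return upper + lower
    else:
        raise ValueError("tails must be 1 or 2")
    if power <= power_fn(0.0):
        return 0.0
    return float(optimize.brentq(lambda d: power_fn(d) - power, 0.0, 10.0, xtol=xtol))


def bf_category(bf10: float) -> str:
    """Conventional evidence labels at cut points 0.1, 0.33, 3 and 10."""
    if bf10 <= 0:
        raise ValueError("bf10 must be > 0")
    if bf10 < 0.1:
        return "strong_null"
    if bf10 < 0.33:
        return "moderate_null"
    if bf10 <= 3.0:
        return "anecdotal"
    if bf10 <= 10.0:
        return "moderate_alt"
    return "strong_alt"


def normal_outlier_threshold(p: float = 0.001) -> float:
    """Two-sided standard-normal critical value; p = 0.001 gives the 3.29 SD
    outlier rule."""
    if not (0 < p < 1):
        raise ValueError("p must lie in (0, 1)")
    return float(stats.norm.ppf(1.0 - p / 2.0))


def group_beta_table(betas: pd.DataFrame, winsorize: bool = True) -> pd.DataFrame:
    """One-sample group tests per (predictor, source) column group.

    ``betas`` is a tidy frame with columns participant, source, predictor,
    beta. Returns one row per predictor x source with t, df, p, d, BF10.
    """
    rows = []
    for (source, predictor), grp in betas.groupby(["source", "predictor"]):
        vals = grp["beta"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 3:
            continue  # too few participants for a group test
        if winsorize:
            vals = winsorize_betas(vals)
        gs = one_sample_t(vals)
        rows.append({"source": source, "predictor": predictor,
                     "mean_beta": gs.mean, **gs.to_dict()})
    return pd.DataFrame(rows)
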