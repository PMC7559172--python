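"""Small-study / publication-bias diagnostics.

Egger's regression test regresses the standardized effect ``y_i / se_i`` on
precision ``1 / se_i`` (ordinary least squares with intercept); absent
small-study effects the intercept is zero, and the test statistic is the
intercept divided by its standard error, referred to a t distribution with
``k - 2`` df.

Begg–Mazumdar's rank-correlation test computes Kendall's tau between the
variance-stabilized deviations ``u_i = (y_i - mu_fixed) / sqrt(v_i - 1/sum w)``
and the variances ``v_i``; the normalized statistic is
``z = (P - Q) / sqrt(k (k-1) (2k+5) / 18)`` with a continuity correction of
one unit on ``|P - Q|`` when nonzero (tied pairs are excluded from both
counts).

:func:`funnel_data` exports the effect-vs-precision scatter plus the
pseudo-confidence funnel boundaries around the fixed-effect mean.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectEstimate
from .meta import pool_fixed

__all__ = ["BiasTestResult", "egger_test", "begg_test", "funnel_data"]


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of a publication-bias test."""

    method: str  # "egger" or "begg"
    statistic: float  # Egger intercept t, or Begg normalized z
    p: float
    k: int
    egger_intercept: float | None = None
    egger_slope: float | None = None
    kendall_tau: float | None = None

    def to_dict(self) -> dict:
        d = {"method": self.method, "statistic": self.statistic, "p": self.p, "k": self.k}
        if self.method == "egger":
            d["intercept"] = self.egger_intercept
            d["slope"] = self.egger_slope
        else:
            d["kendall_tau"] = self.kendall_tau
        return d


def egger_test(estimates: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's regression asymmetry test (classic standardized-effect form)."""
    estimates = list(estimates)
    k = len(estimates)
    if k < 3:
        raise ValueError("Egger's test requires at least 3 studies")
    y = np.array([e.y for e in estimates])
    se = np.array([e.se for e in estimates])
    t_std = y / se  # standardized effects
    prec = 1.0 / se  # precisions (the regressor)
    if np.ptp(prec) == 0:
        raise ValueError("Egger's test needs varying precision across studies")
    X = np.column_stack([np.ones(k), prec])
    beta, *_ = np.linalg.lstsq(X, t_std, rcond=None)
    resid = t_std - X @ beta
    df = k - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se_intercept = math.sqrt(cov[0, 0])
    t_stat = float(beta[0] / se_intercept)
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return BiasTestResult(
        method="egger",
        statistic=t_stat,
        p=p,
        k=k,
        egger_intercept=float(beta[0]),
        egger_slope=float(beta[1]),
    )


def begg_test(
    estimates: Sequence[EffectEstimate], continuity_correction: bool = True
) -> BiasTestResult:
    """Begg–Mazumdar rank correlation test for funnel asymmetry."""
    estimates = list(estimates)
    k = len(estimates)
    if k < 3:
        raise ValueError("Begg's test requires at least 3 studies")
    y = np.array([e.y for e in estimates])
    v = np.array([e.se for e in estimates]) ** 2
    w_sum = float(np.sum(1.0 / v))
    mu_fixed = pool_fixed(estimates).mu
    # variance of (y_i - mu_fixed): v_i minus the pooled-mean variance
    v_star = v - 1.0 / w_sum
    u = (y - mu_fixed) / np.sqrt(v_star)
    P = Q = 0
    for i, j in itertools.combinations(range(k), 2):
        du, dv = u[j] - u[i], v[j] - v[i]
        if du == 0 or dv == 0:  # tied pair: excluded
            continue
        if du * dv > 0:
            P += 1
        else:
            Q += 1
    n_pairs = k * (k - 1) // 2
    tau = (P - Q) / n_pairs
    diff = P - Q
    if continuity_correction and diff != 0:
        diff = math.copysign(abs(diff) - 1, diff)
    z = diff / math.sqrt(k * (k - 1) * (2 * k + 5) / 18.0)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BiasTestResult(
        method="begg", statistic=float(z), p=p, k=k, kendall_tau=float(tau)
    )


def funnel_data(
    estimates: Sequence[EffectEstimate],
    levels: Sequence[float] = (0.95, 0.99),
    n_grid: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Funnel-plot points and pseudo-CI boundary polylines.

    Returns ``(points, boundaries)``: one point per study ``(study_id, y,
    se)``; boundaries trace ``mu_fixed ± z(level) * se`` over an SE grid from
    0 (the apex at the fixed-effect mean) to the largest observed SE.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("funnel_data requires at least 1 study")
    points = pd.DataFrame(
        {
            "study_id": [e.study_id for e in estimates],
            "y": [e.y for e in estimates],
            "se": [e.se for e in estimates],
        }
    )
    mu = (
        pool_fixed(estimates).mu
        if len(estimates) > 1
        else estimates[0].y
    )
    se_grid = np.linspace(0.0, max(e.se for e in estimates), n_grid)
    rows = []
    for level in levels:
        z = stats.norm.ppf(0.5 + level / 2.0)
        for s in se_grid:
            rows.append(
                {"level": level, "se": s, "lower": mu - z * s, "upper": mu + z * s}
            )
    return points, pd.DataFrame(rows)
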