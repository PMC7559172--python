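"""Inverse-variance meta-analysis of log hazard ratios.

The model pools study-level effect estimates ``y_i`` (log HRs) with known
sampling variances ``v_i = se_i^2`` under either

* the **fixed-effect** model — one common true effect, weights ``1/v_i``; or
* the **random-effects** model — study effects ``theta_i ~ N(mu, tau2)``,
  with the between-study variance ``tau2`` estimated by the
  DerSimonian–Laird method of moments, weights ``1/(v_i + tau2)``.

Heterogeneity is quantified by Cochran's ``Q`` (the inverse-variance-weighted
sum of squared deviations from the fixed-effect mean, chi-square with
``k - 1`` df under homogeneity) and Higgins' ``I^2 = max(0, (Q - df)/Q)``.
The ``auto`` model applies the conventional gate: random effects when the
heterogeneity test rejects at ``alpha_het`` (default 0.05), fixed otherwise.

The entry point is :class:`MetaAnalysis` (constructed from effect estimates,
study records or a DataFrame) whose :meth:`~MetaAnalysis.fit` returns a
:class:`MetaAnalysisResults` carrying the pooled effect, CI, heterogeneity
statistics, per-study weights and a ``summary()`` table.  Module-level
helpers (:func:`pool_fixed`, :func:`pool_random_dl`, :func:`pool_auto`,
:func:`subgroup_analysis`, :func:`leave_one_out`, :func:`meta_regression`)
are thin wrappers over the model classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectEstimate, effects_from_records
from .io import StudyRecord

__all__ = [
    "MetaAnalysis",
    "MetaAnalysisResults",
    "MetaRegression",
    "MetaRegressionResults",
    "SubgroupTable",
    "heterogeneity",
    "tau2_dl",
    "pool_fixed",
    "pool_random_dl",
    "pool_auto",
    "subgroup_analysis",
    "leave_one_out",
    "meta_regression",
]

SUBGROUP_FACTORS = ("specimen", "ethnicity", "size_class")


@dataclass(frozen=True)
class Heterogeneity:
    """Cochran Q, its df and p-value, and Higgins I^2 (percent)."""

    Q: float
    df: int
    p_Q: float
    i2: float

    def __iter__(self):
        return iter((self.Q, self.df, self.p_Q, self.i2))


def _as_arrays(estimates: Sequence[EffectEstimate]):
    y = np.array([e.y for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    return y, se


def heterogeneity(estimates: Sequence[EffectEstimate]) -> Heterogeneity:
    """Cochran's Q about the fixed-effect mean and Higgins' I^2.

    Requires at least two studies (heterogeneity is undefined for one).
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("heterogeneity requires at least 2 studies")
    y, se = _as_arrays(estimates)
    w = 1.0 / se**2
    mu_fixed = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mu_fixed) ** 2))
    df = len(y) - 1
    p_Q = float(stats.chi2.sf(Q, df))
    i2 = 100.0 * max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return Heterogeneity(Q=Q, df=df, p_Q=p_Q, i2=i2)


def tau2_dl(estimates: Sequence[EffectEstimate]) -> float:
    """DerSimonian–Laird between-study variance: ``max(0, (Q - df) / C)``
    with ``C = sum(w) - sum(w^2)/sum(w)`` over fixed-effect weights."""
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("tau2 estimation requires at least 2 studies")
    y, se = _as_arrays(estimates)
    w = 1.0 / se**2
    het = heterogeneity(estimates)
    C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return max(0.0, (het.Q - het.df) / C)


class MetaAnalysis:
    """Inverse-variance pooling model for study-level log hazard ratios.

    Parameters
    ----------
    estimates
        Effect estimates (log HR + SE), one per study.
    ci_level
        Confidence level for the pooled CI (default 0.95).
    """

    def __init__(self, estimates: Iterable[EffectEstimate], ci_level: float = 0.95):
        self.estimates: list[EffectEstimate] = list(estimates)
        if not self.estimates:
            raise ValueError("at least one effect estimate is required")
        if not (0 < ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        self.ci_level = ci_level

    @classmethod
    def from_records(cls, records: Iterable[StudyRecord], ci_level: float = 0.95):
        """Build the model from study records (HR + CI rows)."""
        return cls(effects_from_records(records), ci_level=ci_level)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        hr: str = "hr",
        ci_lower: str = "ci_lower",
        ci_upper: str = "ci_upper",
        study_id: str | None = "study_id",
        ci_level: float = 0.95,
    ):
        """Build the model from a DataFrame of published HR / CI columns."""
        from .effects import effect_from_hr_ci

        ests = []
        for i, row in df.reset_index(drop=True).iterrows():
            sid = str(row[study_id]) if study_id and study_id in df else f"study_{i+1}"
            ests.append(
                effect_from_hr_ci(
                    float(row[hr]), float(row[ci_lower]), float(row[ci_upper]),
                    level=ci_level, study_id=sid,
                )
            )
        return cls(ests, ci_level=ci_level)

    @property
    def k(self) -> int:
        return len(self.estimates)

    def fit(self, model: str = "auto", alpha_het: float = 0.05) -> "MetaAnalysisResults":
        """Pool the estimates.

        ``model`` is ``"fixed"``, ``"random"`` (DerSimonian–Laird) or
        ``"auto"`` (random when the Q-test p-value is below ``alpha_het``).
        A single study is returned as-is under the fixed-effect identity.
        """
        if model not in ("fixed", "random", "auto"):
            raise ValueError(f"unknown model {model!r}")
        y, se = _as_arrays(self.estimates)
        k = self.k
        if k == 1:
            het = Heterogeneity(Q=0.0, df=0, p_Q=1.0, i2=0.0)
            tau2 = 0.0
            chosen = "fixed"
        else:
            het = heterogeneity(self.estimates)
            tau2 = tau2_dl(self.estimates)
            if model == "auto":
                chosen = "random" if het.p_Q < alpha_het else "fixed"
            else:
                chosen = model
        if chosen == "random" and k >= 2:
            w = 1.0 / (se**2 + tau2)
        else:
            w = 1.0 / se**2
        mu = float(np.sum(w * y) / np.sum(w))
        se_mu = float(np.sum(w) ** -0.5)
        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        z_stat = mu / se_mu
        p = float(2.0 * stats.norm.sf(abs(z_stat)))
        weights_pct = 100.0 * w / np.sum(w)
        return MetaAnalysisResults(
            model=chosen,
            requested_model=model,
            k=k,
            mu=mu,
            se_mu=se_mu,
            ci_level=self.ci_level,
            hr=math.exp(mu),
            ci_lo=math.exp(mu - z * se_mu),
            ci_hi=math.exp(mu + z * se_mu),
            z_stat=float(z_stat),
            p=p,
            Q=het.Q,
            df=het.df,
            p_Q=het.p_Q,
            i2=het.i2,
            tau2=tau2,
            weights_pct=dict(zip((e.study_id for e in self.estimates), weights_pct)),
            estimates=self.estimates,
        )


@dataclass
class MetaAnalysisResults:
    """Pooled effect with heterogeneity diagnostics and per-study weights.

    ``mu`` is the pooled log HR, ``hr``/``ci_lo``/``ci_hi`` its exponentiated
    point estimate and CI, ``p`` the two-sided normal test of ``mu = 0``.
    ``Q``/``p_Q``/``i2``/``tau2`` describe between-study heterogeneity and are
    computed from the fixed-effect stage regardless of the pooling model.
    """

    model: str
    requested_model: str
    k: int
    mu: float
    se_mu: float
    ci_level: float
    hr: float
    ci_lo: float
    ci_hi: float
    z_stat: float
    p: float
    Q: float
    df: int
    p_Q: float
    i2: float
    tau2: float
    weights_pct: dict[str, float]
    estimates: list[EffectEstimate] = field(repr=False, default_factory=list)

    def forest_frame(self) -> pd.DataFrame:
        """Per-study rows for a forest plot: HR, CI, percentage weight."""
        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        rows = [
            {
                "study_id": e.study_id,
                "hr": math.exp(e.y),
                "ci_lo": math.exp(e.y - z * e.se),
                "ci_hi": math.exp(e.y + z * e.se),
                "weight_pct": self.weights_pct[e.study_id],
            }
            for e in self.estimates
        ]
        rows.append(
            {
                "study_id": f"pooled ({self.model})",
                "hr": self.hr,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "weight_pct": 100.0,
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "k": self.k,
            "mu": self.mu,
            "se_mu": self.se_mu,
            "hr": self.hr,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "ci_level": self.ci_level,
            "z": self.z_stat,
            "p": self.p,
            "Q": self.Q,
            "df": self.df,
            "p_Q": self.p_Q,
            "i2": self.i2,
            "tau2": self.tau2,
            "weights_pct": self.weights_pct,
        }

    def summary(self) -> str:
        """Plain-text summary table (HR/CI to 2 decimals, I^2 to 1)."""
        lines = [
            f"Meta-analysis of {self.k} studies ({self.model}-effect model)",
            "-" * 58,
            f"Pooled HR            {self.hr:8.2f}  "
            f"({self.ci_lo:.2f}-{self.ci_hi:.2f}, {self.ci_level:.0%} CI)",
            f"z = {self.z_stat:.3f}, p = {self.p:.3g}",
            f"Heterogeneity: Q = {self.Q:.2f} (df {self.df}), "
            f"p_Q = {self.p_Q:.3g}, I2 = {self.i2:.1f}%, tau2 = {self.tau2:.4f}",
            "-" * 58,
            f"{'study':<24}{'HR':>7}{'95% CI':>16}{'weight':>9}",
        ]
        for _, row in self.forest_frame().iterrows():
            lines.append(
                f"{row['study_id']:<24}{row['hr']:>7.2f}"
                f"{'(' + format(row['ci_lo'], '.2f') + '-' + format(row['ci_hi'], '.2f') + ')':>16}"
                f"{row['weight_pct']:>8.1f}%"
            )
        return "\n".join(lines)


def pool_fixed(estimates: Sequence[EffectEstimate], ci_level: float = 0.95) -> MetaAnalysisResults:
    """Fixed-effect (inverse-variance) pooling."""
    return MetaAnalysis(estimates, ci_level=ci_level).fit(model="fixed")


def pool_random_dl(estimates: Sequence[EffectEstimate], ci_level: float = 0.95) -> MetaAnalysisResults:
    """DerSimonian–Laird random-effects pooling (requires k >= 2)."""
    if len(list(estimates)) < 2:
        raise ValueError("random-effects pooling requires at least 2 studies")
    return MetaAnalysis(estimates, ci_level=ci_level).fit(model="random")


def pool_auto(
    estimates: Sequence[EffectEstimate],
    alpha_het: float = 0.05,
    ci_level: float = 0.95,
) -> MetaAnalysisResults:
    """Heterogeneity-gated pooling: random effects when ``p_Q < alpha_het``."""
    if len(list(estimates)) < 2:
        raise ValueError("model selection requires at least 2 studies")
    return MetaAnalysis(estimates, ci_level=ci_level).fit(model="auto", alpha_het=alpha_het)


@dataclass
class SubgroupTable:
    """Per-level pooled results for one stratifying factor."""

    factor: str
    levels: dict[str, MetaAnalysisResults]
    meta_regression_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, res in self.levels.items():
            rows.append(
                {
                    "factor": self.factor,
                    "level": level,
                    "k": res.k,
                    "model": res.model,
                    "hr": res.hr,
                    "ci_lo": res.ci_lo,
                    "ci_hi": res.ci_hi,
                    "p": res.p,
                    "i2": res.i2,
                    "p_Q": res.p_Q,
                }
            )
        return pd.DataFrame(rows)


def _factor_level(record: StudyRecord, factor: str) -> str:
    if factor == "size_class":
        level = record.size_class
    elif factor in ("specimen", "ethnicity"):
        level = getattr(record, factor)
    else:
        raise ValueError(
            f"unknown subgroup factor {factor!r}; expected one of {SUBGROUP_FACTORS}"
        )
    if level is None:
        raise ValueError(
            f"study {record.study_id!r} has no value for factor {factor!r}"
        )
    return str(level)


def subgroup_analysis(
    records: Sequence[StudyRecord],
    factor: str,
    alpha_het: float = 0.05,
    ci_level: float = 0.95,
    with_meta_regression: bool = True,
) -> SubgroupTable:
    """Stratified pooling by ``specimen``, ``ethnicity`` or ``size_class``.

    Each level is pooled with the heterogeneity-gated rule; single-study
    levels pass through unchanged.  When the factor is binary and there are
    enough studies, a meta-regression p-value for the factor is attached.
    """
    records = list(records)
    levels: dict[str, list[StudyRecord]] = {}
    for rec in records:
        levels.setdefault(_factor_level(rec, factor), []).append(rec)
    pooled: dict[str, MetaAnalysisResults] = {}
    for level in sorted(levels):
        model = MetaAnalysis.from_records(levels[level], ci_level=ci_level)
        pooled[level] = model.fit(
            model="auto" if model.k >= 2 else "fixed", alpha_het=alpha_het
        )
    mr_p = None
    if with_meta_regression and len(levels) == 2 and len(records) >= 4:
        ests = effects_from_records(records)
        level_names = sorted(levels)
        codes = [
            1.0 if _factor_level(r, factor) == level_names[1] else 0.0
            for r in records
        ]
        try:
            mr = meta_regression(ests, {factor: codes})
            mr_p = float(mr.pvalues[factor])
        except ValueError:
            mr_p = None
    return SubgroupTable(factor=factor, levels=pooled, meta_regression_p=mr_p)


def leave_one_out(
    estimates: Sequence[EffectEstimate],
    alpha_het: float = 0.05,
    ci_level: float = 0.95,
) -> list[tuple[str, MetaAnalysisResults]]:
    """Sensitivity analysis: re-pool after omitting each study in turn."""
    estimates = list(estimates)
    if len(estimates) < 3:
        raise ValueError("leave-one-out requires at least 3 studies")
    out = []
    for i, omitted in enumerate(estimates):
        rest = estimates[:i] + estimates[i + 1 :]
        out.append((omitted.study_id, pool_auto(rest, alpha_het, ci_level)))
    return out


class MetaRegression:
    """Random-effects meta-regression of log HRs on study-level covariates.

    The residual between-study variance is estimated by the method of
    moments (the regression generalisation of DerSimonian–Laird): with
    fixed-effect weights ``W`` and hat-complement
    ``P = W - W X (X'WX)^-1 X'W``, ``tau2 = max(0, (Q_E - (k - p)) / tr(P))``
    where ``Q_E`` is the weighted residual sum of squares.  Coefficients are
    then fitted by WLS with weights ``1/(v_i + tau2)`` and tested with
    two-sided normal z tests.
    """

    def __init__(
        self,
        estimates: Sequence[EffectEstimate],
        covariates: Mapping[str, Sequence[float]] | pd.DataFrame,
    ):
        self.estimates = list(estimates)
        cov = pd.DataFrame(covariates)
        if len(cov) != len(self.estimates):
            raise ValueError("covariate rows must match the number of studies")
        self.exog_names = ["intercept", *cov.columns.astype(str)]
        X = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
        k, p = X.shape
        if k < p + 2:
            raise ValueError(f"need at least {p + 2} studies for {p} coefficients")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("design matrix is rank deficient (constant covariate?)")
        self.X = X

    def fit(self) -> "MetaRegressionResults":
        y, se = _as_arrays(self.estimates)
        v = se**2
        X = self.X
        k, p = X.shape
        w = 1.0 / v
        W = np.diag(w)
        XtWX_inv = np.linalg.inv(X.T @ (w[:, None] * X))
        H = X @ XtWX_inv @ X.T @ W
        resid = y - H @ y
        Q_E = float(np.sum(w * resid**2))
        P = W - W @ X @ XtWX_inv @ X.T @ W
        tau2 = max(0.0, (Q_E - (k - p)) / float(np.trace(P)))
        w_star = 1.0 / (v + tau2)
        cov_beta = np.linalg.inv(X.T @ (w_star[:, None] * X))
        beta = cov_beta @ X.T @ (w_star * y)
        bse = np.sqrt(np.diag(cov_beta))
        zvals = beta / bse
        pvals = 2.0 * stats.norm.sf(np.abs(zvals))
        names = self.exog_names
        return MetaRegressionResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            zvalues=pd.Series(zvals, index=names),
            pvalues=pd.Series(pvals, index=names),
            tau2=tau2,
            Q_E=Q_E,
            df_resid=k - p,
            k=k,
        )


@dataclass
class MetaRegressionResults:
    """Coefficients, SEs, z/p per covariate, and residual tau2."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    tau2: float
    Q_E: float
    df_resid: int
    k: int

    def summary(self) -> str:
        lines = [
            f"Random-effects meta-regression ({self.k} studies, "
            f"residual tau2 = {self.tau2:.4f})",
            f"{'coef':<16}{'estimate':>10}{'se':>10}{'z':>8}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.zvalues[name]:>8.2f}{self.pvalues[name]:>10.3g}"
            )
        return "\n".join(lines)


def meta_regression(
    estimates: Sequence[EffectEstimate],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> MetaRegressionResults:
    """Fit a random-effects meta-regression (see :class:`MetaRegression`)."""
    return MetaRegression(estimates, covariates).fit()
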