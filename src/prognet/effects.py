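"""Log-scale effect estimates from published hazard ratios and CIs.

Pooling happens on the natural-log scale: a published HR with a 95% CI is
converted to ``y = ln(HR)`` with standard error
``se = (ln(upper) - ln(lower)) / (2 z)``, where ``z`` is the exact standard
normal quantile at ``(1 + level) / 2`` (1.959964 at 95%, not the rounded
1.96 — hand calculations dividing by 3.92 will differ by about 0.1%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["EffectEstimate", "effect_from_hr_ci", "effects_from_records"]


@dataclass(frozen=True)
class EffectEstimate:
    """A log-hazard-ratio ``y`` with its standard error and derived weights."""

    study_id: str
    y: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"study {self.study_id!r}: se must be > 0")

    @property
    def var(self) -> float:
        return self.se**2

    @property
    def w_fixed(self) -> float:
        """Inverse-variance (fixed-effect) weight."""
        return 1.0 / self.var

    @property
    def hr(self) -> float:
        return math.exp(self.y)


def effect_from_hr_ci(
    hr: float,
    lo: float,
    hi: float,
    level: float = 0.95,
    study_id: str = "",
) -> EffectEstimate:
    """Back-transform a published ``HR (lo–hi)`` pair to a log-scale estimate.

    The point estimate is ``ln(hr)`` (the published HR is authoritative); the
    CI is used only for the standard error.  A CI that is visibly asymmetric
    on the log scale (midpoint off by more than 0.1 se, typically due to
    aggressive rounding in the source) triggers a logged warning but is
    accepted.
    """
    if min(hr, lo, hi) <= 0:
        raise ValueError("hr and CI bounds must be positive")
    if lo >= hi:
        raise ValueError(f"CI bounds out of order: ({lo}, {hi})")
    if not (lo <= hr <= hi):
        raise ValueError(f"hr {hr} outside its CI ({lo}, {hi})")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    y = math.log(hr)
    se = (math.log(hi) - math.log(lo)) / (2.0 * z)
    midpoint = 0.5 * (math.log(lo) + math.log(hi))
    if abs(y - midpoint) > 0.1 * se:
        logger.warning(
            "study %r: CI not log-symmetric around HR (|ln HR - midpoint| "
            "= %.4f > 0.1 se)", study_id, abs(y - midpoint),
        )
    return EffectEstimate(study_id=study_id, y=y, se=se)


def effects_from_records(records: Iterable) -> list[EffectEstimate]:
    """Convert :class:`~prognet.io.StudyRecord` rows to effect estimates."""
    return [
        effect_from_hr_ci(
            r.hr, r.ci_lower, r.ci_upper, level=r.ci_level, study_id=r.study_id
        )
        for r in records
    ]
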