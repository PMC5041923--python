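"""Per-study odds ratios with Woolf standard errors and Wald confidence intervals.

For a 2×2 table (a, b, c, d) = (exposed cases, unexposed cases, exposed
controls, unexposed controls) the cross-product odds ratio is OR = ad/bc and
the Woolf standard error of log OR is sqrt(1/a + 1/b + 1/c + 1/d). All
inference happens on the log-odds scale; confidence bounds are
exp(log OR ∓ z·SE) with the exact normal quantile for the requested level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import DomainError, ValidationError
from .genetic_models import ContingencyTable, GeneticModel


@dataclass(frozen=True)
class EffectEstimate:
    study_id: str
    model: GeneticModel
    log_or: float
    se_log_or: float
    or_: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def odds_ratio(table: ContingencyTable, level: float = 0.95) -> EffectEstimate:
    """Cross-product odds ratio with a Woolf-SE Wald interval.

    The table must have no zero cell — apply
    :func:`genemeta.genetic_models.apply_continuity_correction` first.
    """
    a, b, c, d = table.cells()
    if any(cell < 0 for cell in (a, b, c, d)):
        raise ValidationError(f"study {table.study_id!r}: negative cell in 2x2 table")
    if any(cell == 0 for cell in (a, b, c, d)):
        raise DomainError(
            f"study {table.study_id!r}: zero cell; apply a continuity correction "
            "before computing the odds ratio"
        )
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0,1), got {level}")
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(0.5 + level / 2))
    return EffectEstimate(
        study_id=table.study_id,
        model=table.model,
        log_or=log_or,
        se_log_or=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        level=level,
    )
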