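"""Funnel-plot coordinates and Egger's regression test for publication bias.

A funnel plot scatters each study's log OR (x) against its standard error
(y, inverted axis): with no publication bias, small studies scatter
symmetrically and increasingly widely around the pooled value, giving an
inverted funnel. Pseudo-confidence guide lines pooled ± z·SE trace the
expected envelope.

Egger's test quantifies asymmetry by regressing the standardized effect
θ_i/SE_i on precision 1/SE_i; under symmetry the intercept is zero, and a
t-test with k−2 df on the intercept flags small-study effects. The source
analysis this package reproduces assessed bias visually only; Egger's test
is an extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate
from .exceptions import DomainError
from .pooling import PooledResult


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    x: float  # log OR
    y: float  # SE(log OR), plotted on an inverted axis
    pooled_ref: float  # pooled log OR for the centreline


@dataclass(frozen=True)
class FunnelGuides:
    """Pseudo-CI envelope: at each SE in ``se_grid``, bounds pooled ± z·SE."""

    se_grid: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    centre: float


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    p: float
    df: int
    degenerate: bool = False


def funnel_data(
    estimates: Sequence[EffectEstimate], pooled: PooledResult, n_grid: int = 50
) -> tuple[list[FunnelPoint], FunnelGuides]:
    """Per-study funnel coordinates plus the pseudo-CI guide lines.

    Guide lines span SE from 0 (where they converge to the pooled value) to
    the largest study SE, at the pooled result's confidence level.
    """
    if len(estimates) < 2:
        raise DomainError("funnel plot requires at least 2 studies")
    centre = pooled.pooled_log_or
    points = [
        FunnelPoint(study_id=e.study_id, x=e.log_or, y=e.se_log_or, pooled_ref=centre)
        for e in estimates
    ]
    z = float(stats.norm.ppf(0.5 + pooled.level / 2))
    se_grid = np.linspace(0.0, max(e.se_log_or for e in estimates), n_grid)
    guides = FunnelGuides(
        se_grid=tuple(se_grid),
        lower=tuple(centre - z * se_grid),
        upper=tuple(centre + z * se_grid),
        centre=centre,
    )
    return points, guides


def egger_test(estimates: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's regression asymmetry test.

    OLS of θ_i/SE_i on 1/SE_i over k ≥ 3 studies; returns the intercept, its
    standard error and the two-sided t-test p-value with k−2 df. If all SEs
    are equal the precision predictor is constant and the regression is
    degenerate: the result is flagged and its statistics are NaN.
    """
    k = len(estimates)
    if k < 3:
        raise DomainError("Egger's test requires at least 3 studies")
    se = np.array([e.se_log_or for e in estimates])
    y = np.array([e.log_or for e in estimates]) / se
    x = 1.0 / se
    if np.ptp(x) == 0:
        warnings.warn(
            "all standard errors equal: Egger regression degenerate", stacklevel=2
        )
        nan = float("nan")
        return EggerResult(nan, nan, nan, k - 2, degenerate=True)
    fit = stats.linregress(x, y)
    df = k - 2
    t = fit.intercept / fit.intercept_stderr
    p = float(2 * stats.t.sf(abs(t), df))
    return EggerResult(
        intercept=float(fit.intercept),
        se_intercept=float(fit.intercept_stderr),
        p=p,
        df=df,
    )
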