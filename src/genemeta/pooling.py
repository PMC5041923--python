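"""Inverse-variance and DerSimonian–Laird pooling of per-study log odds ratios.

Fixed-effect pooling weights each study log OR θ_i by w_i = 1/SE_i² and
reports the weighted mean with SE = 1/sqrt(Σw_i). Heterogeneity is summarised
by Cochran's Q = Σ w_i (θ_i − θ̂)², referred to χ² with k−1 df, and by
I² = max(0, (Q − df)/Q)·100.

The DerSimonian–Laird random-effects model adds a between-study variance

    τ² = max(0, (Q − df) / (Σw_i − Σw_i²/Σw_i))

estimated by the method of moments from the *fixed-effect* weights, then
re-weights with w*_i = 1/(SE_i² + τ²). Q and I² are always reported from the
fixed-effect weights (the convention of mainstream meta-analysis software),
so both schemes agree on heterogeneity and differ only in the pooled value
and its uncertainty. The overall-effect test is a plain Wald z on the pooled
log OR; no small-sample (Hartung–Knapp) adjustment is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from scipy import stats

from .effects import EffectEstimate, odds_ratio
from .exceptions import DomainError, ValidationError
from .genetic_models import GeneticModel, apply_continuity_correction, build_contrast
from .io_tables import StudyRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PooledResult:
    """Pooled effect plus heterogeneity statistics for one model and scheme."""

    model: GeneticModel
    scheme: str  # "fixed" | "random"
    k: int
    pooled_log_or: float
    se_pooled: float
    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    q: float
    df: int
    p_q: float
    i2: float
    tau2: float
    level: float = 0.95
    label: str = "overall"


@dataclass(frozen=True)
class SubgroupResult:
    overall: PooledResult
    per_subgroup: Mapping[str, PooledResult]


def z_test(pooled_log_or: float, se: float) -> tuple[float, float]:
    """Wald z statistic and two-sided normal p-value for a pooled log OR."""
    if se <= 0:
        raise DomainError(f"standard error must be positive, got {se}")
    z = pooled_log_or / se
    return z, float(2 * stats.norm.sf(abs(z)))


def _check_estimates(estimates: Sequence[EffectEstimate]) -> GeneticModel:
    if not estimates:
        raise DomainError("cannot pool an empty list of estimates")
    model = estimates[0].model
    if any(e.model != model for e in estimates):
        raise ValidationError("cannot pool estimates from different genetic models")
    return model


def _heterogeneity(y: Sequence[float], w: Sequence[float]) -> tuple[float, int, float, float]:
    """Cochran's Q on fixed weights, its df and p, and I² (truncated at 0)."""
    k = len(y)
    mu = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - mu) ** 2 for wi, yi in zip(w, y))
    df = k - 1
    if df == 0:
        logger.info("single study: Q and I-squared not applicable, reported as 0")
        return 0.0, 0, 1.0, 0.0
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p_q, i2


def _assemble(
    model: GeneticModel,
    scheme: str,
    estimates: Sequence[EffectEstimate],
    weights: Sequence[float],
    het: tuple[float, int, float, float],
    tau2: float,
    level: float,
    label: str,
) -> PooledResult:
    y = [e.log_or for e in estimates]
    sw = sum(weights)
    mu = sum(wi * yi for wi, yi in zip(weights, y)) / sw
    se = 1.0 / math.sqrt(sw)
    z, p = z_test(mu, se)
    zq = float(stats.norm.ppf(0.5 + level / 2))
    q, df, p_q, i2 = het
    return PooledResult(
        model=model,
        scheme=scheme,
        k=len(estimates),
        pooled_log_or=mu,
        se_pooled=se,
        pooled_or=math.exp(mu),
        ci_low=math.exp(mu - zq * se),
        ci_high=math.exp(mu + zq * se),
        z=z,
        p_value=p,
        q=q,
        df=df,
        p_q=p_q,
        i2=i2,
        tau2=tau2,
        level=level,
        label=label,
    )


def pool_fixed(
    estimates: Sequence[EffectEstimate], level: float = 0.95, label: str = "overall"
) -> PooledResult:
    """Inverse-variance fixed-effect pooling (τ² reported as 0)."""
    model = _check_estimates(estimates)
    w = [1.0 / e.se_log_or**2 for e in estimates]
    het = _heterogeneity([e.log_or for e in estimates], w)
    return _assemble(model, "fixed", estimates, w, het, 0.0, level, label)


def pool_random(
    estimates: Sequence[EffectEstimate], level: float = 0.95, label: str = "overall"
) -> PooledResult:
    """DerSimonian–Laird random-effects pooling.

    When Q ≤ df the moment estimate of τ² truncates to 0 and the result
    coincides exactly with :func:`pool_fixed`.
    """
    model = _check_estimates(estimates)
    w = [1.0 / e.se_log_or**2 for e in estimates]
    y = [e.log_or for e in estimates]
    het = _heterogeneity(y, w)
    q, df, _, _ = het
    if df == 0:
        tau2 = 0.0
    else:
        c = sum(w) - sum(wi**2 for wi in w) / sum(w)
        tau2 = max(0.0, (q - df) / c)
        if q <= df:
            logger.info("Q <= df: tau-squared truncated to 0; random == fixed")
    w_star = [1.0 / (e.se_log_or**2 + tau2) for e in estimates]
    return _assemble(model, "random", estimates, w_star, het, tau2, level, label)


def pool(
    estimates: Sequence[EffectEstimate],
    scheme: str = "random",
    level: float = 0.95,
    label: str = "overall",
) -> PooledResult:
    if scheme == "fixed":
        return pool_fixed(estimates, level, label)
    if scheme == "random":
        return pool_random(estimates, level, label)
    raise ValidationError(f"unknown pooling scheme {scheme!r}")


def estimates_for(
    studies: Sequence[StudyRecord], model: GeneticModel, level: float = 0.95
) -> list[EffectEstimate]:
    """Per-study Woolf effect estimates under one model, with automatic
    continuity correction of zero-cell tables."""
    out = []
    for study in studies:
        table = build_contrast(study, model)
        if any(cell == 0 for cell in table.cells()):
            table = apply_continuity_correction(table)
        out.append(odds_ratio(table, level))
    return out


def subgroup_analysis(
    studies: Sequence[StudyRecord],
    model: GeneticModel,
    scheme: str = "random",
    grouping: Callable[[StudyRecord], str] | None = None,
    level: float = 0.95,
) -> SubgroupResult:
    """Overall plus per-subgroup pooled results under one model.

    Each subgroup is pooled independently (its own τ²); the overall result
    pools all studies jointly. ``grouping`` defaults to the study's
    ``subgroup`` label; it must return a non-empty label for every study.
    """
    if grouping is None:
        grouping = lambda s: s.subgroup  # noqa: E731
    labels = []
    for study in studies:
        label = grouping(study)
        if not label or (isinstance(label, float) and math.isnan(label)):
            raise ValidationError(f"study {study.study_id!r} has no subgroup label")
        labels.append(label)

    overall = pool(estimates_for(studies, model, level), scheme, level, "overall")
    per_subgroup: dict[str, PooledResult] = {}
    for label in dict.fromkeys(labels):  # first-appearance order
        members = [s for s, lab in zip(studies, labels) if lab == label]
        per_subgroup[label] = pool(estimates_for(members, model, level), scheme, level, label)
    return SubgroupResult(overall=overall, per_subgroup=per_subgroup)
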