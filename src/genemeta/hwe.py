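"""Hardy–Weinberg equilibrium testing and the control-arm screening filter.

Under HWE with G-allele frequency *p*, the expected genotype proportions are
p², 2p(1−p), (1−p)². The test here is the standard 1-df goodness-of-fit χ² of
observed genotype counts against those expectations, without continuity
correction. Departure from HWE in *controls* flags genotyping error or
population stratification, so only the control arm is screened; case-arm HWE
can be computed informationally but never excludes a study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .exceptions import DegenerateInputError, DomainError, GenemetaError
from .io_tables import GenotypeCounts, StudyRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HWEResult:
    """χ² goodness-of-fit result for one genotype-count triple."""

    chi2: float
    df: int
    p_value: float
    allele_freq_g: float


def hwe_chisq(counts: GenotypeCounts) -> HWEResult:
    """1-df χ² test of genotype counts against Hardy–Weinberg proportions.

    Parameters
    ----------
    counts
        GG/TG/TT counts for one study arm; must be non-empty and polymorphic.

    Raises
    ------
    DomainError
        If the arm is empty.
    DegenerateInputError
        If the sample is monomorphic (allele frequency 0 or 1), where the
        expected heterozygote/homozygote counts vanish and the statistic is
        undefined.
    """
    n = counts.total()
    if n == 0:
        raise DomainError("HWE test undefined for an empty arm")
    p = counts.allele_freq_g()
    if p == 0.0 or p == 1.0:
        raise DegenerateInputError("HWE test undefined for a monomorphic sample")
    expected = (n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p))
    observed = (counts.gg, counts.tg, counts.tt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    # one free parameter (p) estimated from 3 classes -> df = 3 - 1 - 1 = 1
    p_value = float(stats.chi2.sf(chi2, 1))
    return HWEResult(chi2=float(chi2), df=1, p_value=p_value, allele_freq_g=p)


def hwe_filter(
    studies: Sequence[StudyRecord], alpha: float = 0.05
) -> tuple[list[StudyRecord], list[tuple[StudyRecord, HWEResult]]]:
    """Partition studies by whether their control arm is consistent with HWE.

    A study is kept iff the control-arm χ² p-value is strictly greater than
    ``alpha``; order is preserved in both partitions. Excluded studies carry
    the failing :class:`HWEResult`.
    """
    kept: list[StudyRecord] = []
    excluded: list[tuple[StudyRecord, HWEResult]] = []
    for study in studies:
        try:
            result = hwe_chisq(study.controls)
        except GenemetaError as exc:
            raise type(exc)(f"study {study.study_id!r}: {exc}") from exc
        if result.p_value > alpha:
            kept.append(study)
        else:
            logger.info(
                "HWE filter excluded study %s (chi2=%.4f, p=%.4g <= alpha=%g)",
                study.study_id,
                result.chi2,
                result.p_value,
                alpha,
            )
            excluded.append((study, result))
    return kept, excluded
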