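"""Genetic-model contrasts: collapsing three genotype classes into a 2×2 table.

For a biallelic SNP with risk allele G, a *genetic model* partitions the
genotypes {GG, TG, TT} into an exposed and an unexposed set:

* dominant:  GG+TG vs TT (carriage of at least one G allele)
* recessive: GG vs TG+TT (two G alleles)
* additive:  GG+TT vs TG — as used in the source literature this pipeline
  reproduces, this is a homozygote-vs-heterozygote contrast, *not* the
  conventional allele-dose model. The conventional per-allele 2×2 is
  available separately as :func:`build_allele_contrast`.

The resulting 2×2 table (case/control × exposed/unexposed) feeds the odds
ratio machinery in :mod:`genemeta.effects`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import FrozenSet

from .exceptions import DomainError, ValidationError
from .io_tables import GenotypeCounts, StudyRecord

logger = logging.getLogger(__name__)

GENOTYPES = frozenset({"GG", "TG", "TT"})


@dataclass(frozen=True)
class GeneticModel:
    """A named genotype partition defining exposure in the 2×2 contrast."""

    name: str
    exposed_genotypes: FrozenSet[str]

    def __post_init__(self) -> None:
        exposed = frozenset(self.exposed_genotypes)
        object.__setattr__(self, "exposed_genotypes", exposed)
        if not exposed or exposed == GENOTYPES:
            raise ValidationError("exposed genotype set must be a proper non-empty subset")
        if not exposed <= GENOTYPES:
            raise ValidationError(f"unknown genotype labels: {exposed - GENOTYPES}")

    @property
    def unexposed_genotypes(self) -> FrozenSet[str]:
        return GENOTYPES - self.exposed_genotypes


DOMINANT = GeneticModel("dominant", frozenset({"GG", "TG"}))
RECESSIVE = GeneticModel("recessive", frozenset({"GG"}))
ADDITIVE = GeneticModel("additive", frozenset({"GG", "TT"}))

MODELS: dict[str, GeneticModel] = {m.name: m for m in (DOMINANT, RECESSIVE, ADDITIVE)}


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 exposed/unexposed × case/control table for one study and model.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls. Cells are integers until a continuity correction adds 0.5 to
    each (``corrected=True``).
    """

    a: float
    b: float
    c: float
    d: float
    model: GeneticModel
    study_id: str
    corrected: bool = False

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def _collapse(counts: GenotypeCounts, exposed: FrozenSet[str]) -> tuple[int, int]:
    by_genotype = {"GG": counts.gg, "TG": counts.tg, "TT": counts.tt}
    e = sum(v for g, v in by_genotype.items() if g in exposed)
    return e, counts.total() - e


def build_contrast(study: StudyRecord, model: GeneticModel) -> ContingencyTable:
    """Collapse a study's genotype counts into the model's 2×2 table.

    Row sums equal the arm totals; cells are exact integer sums.
    """
    if study.cases.total() == 0 or study.controls.total() == 0:
        raise DomainError(f"study {study.study_id!r}: empty arm")
    a, b = _collapse(study.cases, model.exposed_genotypes)
    c, d = _collapse(study.controls, model.exposed_genotypes)
    return ContingencyTable(a=a, b=b, c=c, d=d, model=model, study_id=study.study_id)


# Allele counting is not a genotype partition, so the allelic "model" exists
# only as a label on tables built by build_allele_contrast; its exposed set
# (G-homozygotes) is never used for collapsing.
ALLELIC = GeneticModel("allelic", frozenset({"GG"}))


def build_allele_contrast(study: StudyRecord) -> ContingencyTable:
    """Conventional allelic 2×2: G vs T allele counts in cases and controls.

    Each individual contributes two alleles. Provided as an extension; the
    reproduction pipeline uses only the three genotype models in ``MODELS``.
    """
    if study.cases.total() == 0 or study.controls.total() == 0:
        raise DomainError(f"study {study.study_id!r}: empty arm")
    return ContingencyTable(
        a=2 * study.cases.gg + study.cases.tg,
        b=2 * study.cases.tt + study.cases.tg,
        c=2 * study.controls.gg + study.controls.tg,
        d=2 * study.controls.tt + study.controls.tg,
        model=ALLELIC,
        study_id=study.study_id,
    )


def apply_continuity_correction(table: ContingencyTable) -> ContingencyTable:
    """Add 0.5 to all four cells if any cell is zero (Haldane–Anscombe).

    Called on a table with no zero cell, this is a no-op with a logged
    warning.
    """
    if all(cell > 0 for cell in table.cells()):
        logger.warning(
            "continuity correction requested for study %s but no cell is zero; no-op",
            table.study_id,
        )
        return table
    return replace(
        table,
        a=table.a + 0.5,
        b=table.b + 0.5,
        c=table.c + 0.5,
        d=table.d + 0.5,
        corrected=True,
    )
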