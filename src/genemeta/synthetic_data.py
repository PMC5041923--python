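"""Synthetic case-control genotype datasets with known ground truth.

The generator mirrors the data-generating structure that the random-effects
meta-analysis assumes:

* Controls are drawn multinomially from exact Hardy–Weinberg proportions
  (p², 2p(1−p), (1−p)²) at a specified G-allele frequency p.
* Disease odds are genotype-specific with TT as baseline: OR_het for TG and
  OR_hom for GG. Case genotype probabilities are the control probabilities
  re-weighted by those odds and renormalized — distributionally equivalent to
  logistic sampling of individuals under a rare-disease-free odds model, but
  far cheaper.
* Between-study heterogeneity is a single normal shift δ_i ~ N(0, τ²) added
  to *both* genotype log ORs, so a collapsed contrast whose exposed set picks
  up the shift (e.g. the dominant contrast when OR_het = OR_hom) has
  study-level log OR exactly baseline + δ_i — the structure DerSimonian–Laird
  pooling assumes.

Randomness is reproducible: each study uses a substream derived
deterministically from (seed, study_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .exceptions import ValidationError
from .io_tables import GenotypeCounts, StudyRecord

SizeSpec = Union[int, tuple[int, int], Sequence[int]]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for a simulated meta-analysis dataset.

    Defaults describe a typical genome-wide-association follow-up
    meta-analysis of a common variant: nine studies of a few hundred
    participants per arm, a common risk allele (p = 0.5, close to the
    fixture's control G frequency), weak genotype effects and no
    heterogeneity.
    """

    n_studies: int = 9
    cases_per_study: SizeSpec = 400
    controls_per_study: SizeSpec = 400
    control_allele_freq_g: float = 0.5
    or_het: float = 1.0  # TG vs TT disease odds ratio
    or_hom: float = 1.0  # GG vs TT disease odds ratio
    tau: float = 0.0  # SD of the shared between-study shift on log OR scale
    subgroup_labels: Union[Sequence[str], None] = None  # one per study, optional
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValidationError("n_studies must be >= 1")
        if not 0.0 < self.control_allele_freq_g < 1.0:
            raise ValidationError("control_allele_freq_g must be in (0,1)")
        if self.or_het <= 0 or self.or_hom <= 0:
            raise ValidationError("genotype odds ratios must be > 0")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if self.subgroup_labels is not None and len(self.subgroup_labels) != self.n_studies:
            raise ValidationError("subgroup_labels must have one label per study")


def _arm_size(spec: SizeSpec, index: int, rng: np.random.Generator) -> int:
    """Resolve a size spec: scalar, (low, high) range, or per-study sequence."""
    if isinstance(spec, int):
        n = spec
    elif isinstance(spec, tuple) and len(spec) == 2:
        n = int(rng.integers(spec[0], spec[1] + 1))
    else:
        n = int(spec[index])
    if n < 1:
        raise ValidationError(f"arm size must be >= 1, got {n}")
    return n


def genotype_probabilities(config: SimulationConfig, delta: float = 0.0):
    """Control and case genotype probability vectors (GG, TG, TT).

    ``delta`` is the study-specific shift applied to both genotype log ORs.
    """
    p = config.control_allele_freq_g
    control = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    odds = np.array([config.or_hom * np.exp(delta), config.or_het * np.exp(delta), 1.0])
    case = control * odds
    case /= case.sum()
    return control, case


def _study_rng(seed: int, study_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, study_index)))


def simulate_study(config: SimulationConfig, study_index: int) -> StudyRecord:
    """Draw one synthetic study; deterministic given (config.seed, study_index)."""
    rng = _study_rng(config.seed, study_index)
    delta = rng.normal(0.0, config.tau) if config.tau > 0 else 0.0
    control_p, case_p = genotype_probabilities(config, delta)
    n_cases = _arm_size(config.cases_per_study, study_index, rng)
    n_controls = _arm_size(config.controls_per_study, study_index, rng)
    case_counts = rng.multinomial(n_cases, case_p)
    control_counts = rng.multinomial(n_controls, control_p)
    label = (
        config.subgroup_labels[study_index]
        if config.subgroup_labels is not None
        else "simulated"
    )
    return StudyRecord(
        study_id=f"sim{study_index:03d}",
        author=f"Synthetic {study_index:03d}",
        year=2000 + study_index,
        country="synthetic",
        subgroup=label,
        cases=GenotypeCounts(*(int(x) for x in case_counts)),
        controls=GenotypeCounts(*(int(x) for x in control_counts)),
    )


def simulate_meta_dataset(config: SimulationConfig) -> list[StudyRecord]:
    """Draw the full dataset: n_studies independent studies."""
    return [simulate_study(config, i) for i in range(config.n_studies)]
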