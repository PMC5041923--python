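"""Reading and writing study genotype-count tables and analysis results.

A *studies table* is a CSV with one row per case-control study of a biallelic
SNP. The fixed schema is::

    study_id, author, year, country, subgroup,
    case_gg, case_tg, case_tt, control_gg, control_tg, control_tt,
    reported_association, reported_hwe_p

Counts are genotype counts (individuals, not alleles). ``reported_association``
("Y"/"N") and ``reported_hwe_p`` echo what the source publication reported and
are carried as metadata only; nothing downstream computes from them.

The nine-study prostate-cancer dataset used throughout the documentation ships
as a packaged fixture, available via :func:`load_table1`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .exceptions import SchemaError, ValidationError

REQUIRED_COLUMNS = (
    "study_id",
    "author",
    "year",
    "country",
    "subgroup",
    "case_gg",
    "case_tg",
    "case_tt",
    "control_gg",
    "control_tg",
    "control_tt",
)
OPTIONAL_COLUMNS = ("reported_association", "reported_hwe_p")

COUNT_COLUMNS = REQUIRED_COLUMNS[5:]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (GG/TG/TT) for one arm of one study.

    "G" is the risk allele; GG/TG/TT are the three genotype classes of the
    biallelic SNP. Counts are individuals.
    """

    gg: int
    tg: int
    tt: int

    def __post_init__(self) -> None:
        for name in ("gg", "tg", "tt"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValidationError(f"genotype count {name!r} must be an integer, got {value!r}")
            if value < 0:
                raise ValidationError(f"genotype count {name!r} must be >= 0, got {value}")

    def total(self) -> int:
        return self.gg + self.tg + self.tt

    def allele_freq_g(self) -> float:
        """Sample frequency of the G allele, (2·GG + TG) / (2·n)."""
        n = self.total()
        if n == 0:
            raise ValidationError("allele frequency undefined for an empty arm")
        return (2 * self.gg + self.tg) / (2 * n)


@dataclass(frozen=True)
class StudyRecord:
    """One study: metadata plus case and control genotype counts."""

    study_id: str
    author: str
    year: int
    country: str
    subgroup: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    reported_association: Union[str, None] = None
    reported_hwe_p: Union[float, None] = None


def _parse_count(raw, study_id: str, column: str) -> int:
    """Parse one count cell, rejecting negatives and non-integers."""
    if pd.isna(raw):
        raise ValidationError(f"study {study_id!r}: missing count in column {column!r}")
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"study {study_id!r}: count in column {column!r} must be a non-negative "
            f"integer, got {raw!r}"
        ) from None
    if not math.isfinite(value) or value != int(value):
        raise ValidationError(
            f"study {study_id!r}: count in column {column!r} must be a non-negative "
            f"integer, got {raw!r}"
        )
    if value < 0:
        raise ValidationError(
            f"study {study_id!r}: count in column {column!r} is negative ({raw!r})"
        )
    return int(value)


def read_studies(path: Union[str, Path]) -> list[StudyRecord]:
    """Read a studies CSV into a list of :class:`StudyRecord`, preserving row order.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        For negative/non-integer counts or duplicate ``study_id`` values.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    seen: set[str] = set()
    records: list[StudyRecord] = []
    for _, row in frame.iterrows():
        study_id = str(row["study_id"])
        if study_id in seen:
            raise ValidationError(f"duplicate study_id {study_id!r}")
        seen.add(study_id)
        counts = {c: _parse_count(row[c], study_id, c) for c in COUNT_COLUMNS}
        assoc = row.get("reported_association")
        hwe_p = row.get("reported_hwe_p")
        records.append(
            StudyRecord(
                study_id=study_id,
                author=str(row["author"]),
                year=int(row["year"]),
                country=str(row["country"]),
                subgroup=str(row["subgroup"]),
                cases=GenotypeCounts(counts["case_gg"], counts["case_tg"], counts["case_tt"]),
                controls=GenotypeCounts(
                    counts["control_gg"], counts["control_tg"], counts["control_tt"]
                ),
                reported_association=None if pd.isna(assoc) else str(assoc),
                reported_hwe_p=None if pd.isna(hwe_p) else float(hwe_p),
            )
        )
    return records


def write_studies(studies: Sequence[StudyRecord], path: Union[str, Path]) -> None:
    """Write studies back out in the same CSV schema (inverse of read_studies)."""
    rows = []
    for s in studies:
        rows.append(
            {
                "study_id": s.study_id,
                "author": s.author,
                "year": s.year,
                "country": s.country,
                "subgroup": s.subgroup,
                "case_gg": s.cases.gg,
                "case_tg": s.cases.tg,
                "case_tt": s.cases.tt,
                "control_gg": s.controls.gg,
                "control_tg": s.controls.tg,
                "control_tt": s.controls.tt,
                "reported_association": s.reported_association,
                "reported_hwe_p": s.reported_hwe_p,
            }
        )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)).to_csv(
        path, index=False
    )


def load_table1() -> list[StudyRecord]:
    """Load the packaged nine-study prostate-cancer rs6983267 dataset."""
    with resources.as_file(resources.files("genemeta.data") / "table1.csv") as p:
        return read_studies(p)


def _result_row(result) -> dict:
    """Flatten an EffectEstimate or PooledResult into one results-CSV row."""
    # imported here to keep io_tables importable before the stats modules
    from .effects import EffectEstimate
    from .pooling import PooledResult

    if isinstance(result, EffectEstimate):
        return {
            "kind": "study",
            "label": result.study_id,
            "model": result.model.name,
            "scheme": "",
            "k": 1,
            "or": result.or_,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "log_or": result.log_or,
            "se_log_or": result.se_log_or,
            "z": "",
            "p_value": "",
            "q": "",
            "df": "",
            "p_q": "",
            "i2": "",
            "tau2": "",
            "or_display": f"{result.or_:.2f}",
            "ci_low_display": f"{result.ci_low:.2f}",
            "ci_high_display": f"{result.ci_high:.2f}",
            "i2_display": "",
        }
    if isinstance(result, PooledResult):
        return {
            "kind": "pooled",
            "label": result.label,
            "model": result.model.name,
            "scheme": result.scheme,
            "k": result.k,
            "or": result.pooled_or,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "log_or": result.pooled_log_or,
            "se_log_or": result.se_pooled,
            "z": result.z,
            "p_value": result.p_value,
            "q": result.q,
            "df": result.df,
            "p_q": result.p_q,
            "i2": result.i2,
            "tau2": result.tau2,
            "or_display": f"{result.pooled_or:.2f}",
            "ci_low_display": f"{result.ci_low:.2f}",
            "ci_high_display": f"{result.ci_high:.2f}",
            "i2_display": f"{result.i2:.0f}",
        }
    raise ValidationError(f"unsupported result type {type(result).__name__}")


def write_results(results: Iterable, path: Union[str, Path]) -> None:
    """Write per-study effects and pooled results to one CSV.

    Floating values are written at full precision; ``*_display`` columns carry
    the 2-decimal OR/CI strings and whole-percent I² used in human-readable
    summaries.
    """
    rows = [_result_row(r) for r in results]
    if not rows:
        raise ValidationError("write_results requires at least one result")
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    """Read a results CSV back as a DataFrame (full-precision columns)."""
    return pd.read_csv(path)
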