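"""End-to-end meta-analysis pipeline: HWE screen → contrasts → pooling → outputs.

`run_metaanalysis` is the library entry point behind the ``genemeta run``
command; it reads a studies CSV, screens control arms for Hardy–Weinberg
equilibrium, builds the requested genetic-model contrasts, pools with the
requested scheme(s), and writes per-study effects, pooled results, funnel
data and a human-readable summary into an output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from . import bias, hwe, io_tables, pooling, synthetic_data
from .exceptions import DomainError, ValidationError
from .genetic_models import MODELS, GeneticModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: Union[str, Path, None] = None
    models: Sequence[str] = ("dominant", "recessive", "additive")
    scheme: str = "random"  # "fixed" | "random" | "both"
    hwe_alpha: float = 0.05
    confidence_level: float = 0.95
    subgroup_column: Union[str, None] = "subgroup"
    output_dir: Union[str, Path] = "genemeta_out"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not self.models:
            raise ValidationError("at least one genetic model is required")
        unknown = [m for m in self.models if m not in MODELS]
        if unknown:
            raise ValidationError(f"unknown model(s): {', '.join(unknown)}")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValidationError("hwe_alpha must be in (0,1)")
        if not 0.0 < self.confidence_level < 1.0:
            raise ValidationError("confidence_level must be in (0,1)")
        if self.scheme not in ("fixed", "random", "both"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")


@dataclass
class RunReport:
    """Everything `run_metaanalysis` computed, plus where it was written."""

    studies_total: int
    kept: list
    excluded: list  # (StudyRecord, HWEResult) pairs
    effects: dict  # model name -> list[EffectEstimate]
    results: dict  # (model name, scheme) -> SubgroupResult
    output_dir: Path
    summary_lines: list = field(default_factory=list)

    @property
    def summary(self) -> str:
        return "\n".join(self.summary_lines)


def _fmt_pooled(r: pooling.PooledResult) -> str:
    return (
        f"OR = {r.pooled_or:.2f} ({r.level:.0%} CI: {r.ci_low:.2f}, {r.ci_high:.2f}); "
        f"P = {r.p_value:.2f}; I2 = {r.i2:.0f}% (k={r.k}, tau2={r.tau2:.4f})"
    )


def _funnel_frame(points, guides) -> pd.DataFrame:
    rows = [
        {"record": "study", "study_id": p.study_id, "log_or": p.x, "se": p.y,
         "centre": p.pooled_ref, "guide_lower": "", "guide_upper": ""}
        for p in points
    ]
    for se, lo, hi in zip(guides.se_grid, guides.lower, guides.upper):
        rows.append(
            {"record": "guide", "study_id": "", "log_or": "", "se": se,
             "centre": guides.centre, "guide_lower": lo, "guide_upper": hi}
        )
    return pd.DataFrame(rows)


def _plot_funnel(points, guides, pooled, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(guides.lower, guides.se_grid, "--", color="grey", lw=0.8)
    ax.plot(guides.upper, guides.se_grid, "--", color="grey", lw=0.8)
    ax.axvline(guides.centre, color="grey", lw=0.8)
    ax.scatter([p.x for p in points], [p.y for p in points], s=18, color="k")
    ax.invert_yaxis()
    ax.set_xlabel("log OR")
    ax.set_ylabel("SE(log OR)")
    ax.set_title(f"Funnel plot — {pooled.model.name} model")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_metaanalysis(config: RunConfig, studies=None) -> RunReport:
    """Run the full pipeline; returns a report and writes the output bundle.

    ``studies`` may be given directly (list of StudyRecord) to bypass file
    reading; otherwise ``config.input_path`` is read.
    """
    if studies is None:
        if config.input_path is None:
            raise ValidationError("either studies or config.input_path is required")
        studies = io_tables.read_studies(config.input_path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    kept, excluded = hwe.hwe_filter(studies, alpha=config.hwe_alpha)
    if not kept:
        raise DomainError("no studies remain after HWE filter")

    n_cases = sum(s.cases.total() for s in kept)
    n_controls = sum(s.controls.total() for s in kept)
    lines = [
        f"Studies read: {len(studies)}; kept after HWE screen (alpha={config.hwe_alpha}): "
        f"{len(kept)}; excluded: {len(excluded)}",
    ]
    for study, res in excluded:
        lines.append(
            f"  excluded {study.study_id}: control HWE chi2={res.chi2:.3f}, p={res.p_value:.4g}"
        )
    lines.append(
        f"Participants: {n_cases} cases + {n_controls} controls = {n_cases + n_controls}"
    )

    schemes = ("fixed", "random") if config.scheme == "both" else (config.scheme,)
    grouping = None
    if config.subgroup_column is None:
        grouping = lambda s: "all"  # noqa: E731
    elif config.subgroup_column != "subgroup":
        raise ValidationError(
            f"unknown subgroup column {config.subgroup_column!r}; the studies schema "
            "has a single grouping column named 'subgroup'"
        )

    effects: dict = {}
    results: dict = {}
    all_rows: list = []
    for model_name in config.models:
        model: GeneticModel = MODELS[model_name]
        ests = pooling.estimates_for(kept, model, config.confidence_level)
        effects[model_name] = ests
        for scheme in schemes:
            sub = pooling.subgroup_analysis(
                kept, model, scheme, grouping, config.confidence_level
            )
            results[(model_name, scheme)] = sub
            lines.append(f"[{model_name} | {scheme}] overall: {_fmt_pooled(sub.overall)}")
            for label, res in sub.per_subgroup.items():
                if label != "all":
                    lines.append(f"[{model_name} | {scheme}]   {label}: {_fmt_pooled(res)}")
            all_rows.extend([sub.overall, *sub.per_subgroup.values()])

        io_tables.write_results(ests, out_dir / f"effects_{model_name}.csv")
        # funnel uses the last scheme's overall pooled value as centreline
        pooled_for_funnel = results[(model_name, schemes[-1])].overall
        if len(ests) >= 2:
            points, guides = bias.funnel_data(ests, pooled_for_funnel)
            _funnel_frame(points, guides).to_csv(
                out_dir / f"funnel_{model_name}.csv", index=False
            )
            if config.make_plots:
                _plot_funnel(points, guides, pooled_for_funnel,
                             out_dir / f"funnel_{model_name}.png")

    io_tables.write_results(all_rows, out_dir / "pooled_results.csv")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return RunReport(
        studies_total=len(studies),
        kept=kept,
        excluded=excluded,
        effects=effects,
        results=results,
        output_dir=out_dir,
        summary_lines=lines,
    )


def run_simulate(
    sim_config: synthetic_data.SimulationConfig,
    output_path: Union[str, Path],
    analyze: bool = False,
    run_config: Union[RunConfig, None] = None,
) -> Union[RunReport, None]:
    """Write a simulated dataset in the studies CSV schema; optionally analyse it."""
    studies = synthetic_data.simulate_meta_dataset(sim_config)
    io_tables.write_studies(studies, output_path)
    if analyze:
        cfg = run_config or RunConfig()
        cfg.input_path = output_path
        return run_metaanalysis(cfg)
    return None
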