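"""End-to-end analysis pipeline producing a structured JSON-able report.

Runs, on one event table (read from file or synthesized), every analysis
stage the package offers: prey spectrum, predator size distribution,
per-class spectra, per-taxon GMFR fits, ratio summaries, the binomial
field-expectation test for gastropod prey of large predators, and the
random-encounter cannibalism model. Stage-local failures (too few events
for a fit, no conspecific events, ...) are recorded as skips with reasons;
they never abort the rest of the report.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata

import numpy as np

from .cannibalism import RatioRules, run_cannibalism_analysis
from .errors import (
    ConfigError,
    DegenerateDataError,
    DegenerateModelError,
    InsufficientDataError,
)
from .events import EventTable, read_events, filter_events
from .gmfr import fit_gmfr
from .ratios import GASTROPOD_RATIO_THRESHOLD, field_expectation, ratio_summary
from .spectra import SizeClassGrid, class_distribution, prey_spectrum, spectrum_by_class
from .synth import GeneratorConfig, generate_events

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline configuration; exactly one input source must be set."""

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    grid: SizeClassGrid = field(default_factory=SizeClassGrid)
    ratio_threshold: float = GASTROPOD_RATIO_THRESHOLD
    rules: RatioRules = field(default_factory=RatioRules)
    field_cutoff_mm: float = 41.0
    crustacean_small_prey_max_mm: float = 20.0

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ConfigError("set exactly one of input_path and generator")


def _gmfr_section(x: np.ndarray, y: np.ndarray) -> dict:
    try:
        fit = fit_gmfr(x, y)
    except (InsufficientDataError, DegenerateDataError) as exc:
        return {"skipped": str(exc), "n": int(len(x))}
    return dataclasses.asdict(fit)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every analysis stage and return the report as a plain dict.

    Deterministic given the input table (or generator seed); the only
    non-reproducible field is ``provenance.timestamp``, isolated there so
    determinism checks can exclude it.
    """
    config.validate()
    t0 = time.perf_counter()

    if config.input_path is not None:
        table = read_events(config.input_path)
        source = {"input_path": str(config.input_path)}
    else:
        table, gen_report = generate_events(config.generator)
        source = {
            "generator": dataclasses.asdict(config.generator),
            "realized_counts": gen_report.group_counts,
        }
    logger.info("events stage: %d rows", len(table))

    report: dict = {"n_events": len(table)}

    spectrum = prey_spectrum(table)
    report["prey_spectrum"] = {
        "group_counts": spectrum.group_counts,
        "group_percentages": spectrum.percentages(),
        "taxon_counts": spectrum.taxon_counts,
        "total": spectrum.total,
    }

    dist = class_distribution(table, config.grid, which="predator")
    report["predator_size_distribution"] = {
        "labels": config.grid.labels(),
        "counts": list(dist.counts),
        "total": dist.total,
    }

    report["spectra_by_class"] = [
        {"label": lab, "group_counts": s.group_counts, "total": s.total}
        for lab, s in zip(config.grid.labels(), spectrum_by_class(table, config.grid))
    ]

    # per-taxon predator-vs-prey size relationships
    gmfr_sections: dict[str, dict] = {}
    for group in ("gastropod", "bivalve", "crustacean", "conspecific"):
        sub = filter_events(table, prey_group=group)
        gmfr_sections[group] = _gmfr_section(sub.predator_lengths, sub.prey_lengths)
    small_crust = filter_events(
        table,
        prey_group="crustacean",
        prey_range_mm=(0.0, config.crustacean_small_prey_max_mm),
    )
    gmfr_sections["crustacean_small_prey"] = _gmfr_section(
        small_crust.predator_lengths, small_crust.prey_lengths
    )
    report["gmfr"] = gmfr_sections

    # ratio summaries for the groups governed by the 1.45 threshold
    ratio_sections: dict[str, dict] = {}
    for group in ("gastropod", "conspecific"):
        sub = filter_events(table, prey_group=group)
        if len(sub) == 0:
            ratio_sections[group] = {"skipped": "no events", "n": 0}
            continue
        rs = ratio_summary(sub, config.ratio_threshold)
        ratio_sections[group] = {
            "threshold": rs.threshold,
            "n_above": rs.n_above,
            "n_not_above": rs.n_not_above,
            "min_ratio": rs.min_ratio,
        }
    report["ratio_summaries"] = ratio_sections

    # field test: gastropod prey taken by predators at/above the cutoff
    gast = filter_events(table, prey_group="gastropod")
    if len(gast) == 0:
        report["field_expectation"] = {"skipped": "no gastropod-prey events"}
    else:
        observed = int(np.sum(gast.predator_lengths >= config.field_cutoff_mm))
        try:
            fe = field_expectation(
                table.predator_lengths, gast, config.field_cutoff_mm, observed
            )
            report["field_expectation"] = dataclasses.asdict(fe)
        except (ValueError, DegenerateDataError) as exc:
            report["field_expectation"] = {"skipped": str(exc)}

    try:
        cm = run_cannibalism_analysis(table, config.grid, config.rules)
        report["cannibalism_model"] = {
            "expected": list(cm.expected),
            "observed": list(cm.observed),
            "scale": cm.scale,
            "chi_square": cm.chi_square,
            "df": cm.df,
            "n_pool": cm.n_pool,
        }
    except (DegenerateDataError, DegenerateModelError) as exc:
        report["cannibalism_model"] = {"skipped": str(exc)}

    try:
        version = metadata.version("preyspectra")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    report["provenance"] = {
        "source": source,
        "config": {
            "grid": dataclasses.asdict(config.grid),
            "ratio_threshold": config.ratio_threshold,
            "rules": dataclasses.asdict(config.rules),
            "field_cutoff_mm": config.field_cutoff_mm,
        },
        "package_version": version,
        "timestamp": dt.datetime.now().isoformat(),
        "elapsed_s": round(time.perf_counter() - t0, 4),
    }
    return report


def report_to_json(report: dict, path=None) -> str:
    """Serialize a report; writes to ``path`` when given."""
    text = json.dumps(report, indent=2, default=str)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
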