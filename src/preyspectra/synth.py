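"""Synthetic predation-event generator.

Emulates the statistical structure of the field dataset so every
downstream stage is testable without the original deposited table:

* a unimodal predator size distribution on [18.0, 57.4] mm with about 76%
  of individuals between 25 and 37 mm (truncated lognormal, mode 30 mm);
* a prey-taxon mix of roughly half gastropods, a quarter bivalves, and the
  rest crustaceans and conspecifics (165/88/43/31 of 327);
* bivalve prey filling a "predation window" [3.7, min(L, 40)] mm that
  widens with predator size L;
* gastropod prey below 19 mm taken only by predators up to ~41 mm, always
  respecting the 1.45 predator:prey ratio threshold (rare configurable
  outliers aside);
* crustacean prey bimodal: small 4–15 mm items for predators over 23 mm,
  plus rare >30 mm items taken by 26.5–35 mm predators;
* cannibalism dominated by predators over 41 mm, victims at least 1.45
  times smaller, with a knob for the occasional small cannibal.

One global seed governs everything; per-taxon substreams are spawned from
it so changing the draw volume of one taxon leaves the others untouched.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError
from .events import COLUMNS, EventTable, PREDATOR_SPECIES
import pandas as pd

#: Conditional taxon frequencies within each prey group, as recorded in the
#: field prey-spectrum table.
_TAXA_WITHIN_GROUP = {
    "gastropod": (("Olivella semistriata", 163), ("Mazatlania fulgurata", 2)),
    "bivalve": (
        ("Donax sp.", 69),
        ("Pitar sp.", 5),
        ("Tivela sp.", 1),
        ("Milbe sp.", 1),
        ("Bivalvia indet.", 12),
    ),
    "crustacean": (("Emerita sp.", 26), ("Crustacea indet.", 17)),
    "conspecific": ((PREDATOR_SPECIES, 1),),
}

_GROUP_ORDER = ("gastropod", "bivalve", "crustacean", "conspecific")


@dataclass(frozen=True)
class PredatorSizeModel:
    """Truncated lognormal shell-length distribution of successful predators.

    mode_mm is the peak of the untruncated density; log_sd controls spread.
    Defaults put ~76% of mass in [25, 37) mm after truncation to
    [min_mm, max_mm], matching the observed size histogram.
    """

    mode_mm: float = 30.0
    log_sd: float = 0.165
    min_mm: float = 18.0
    max_mm: float = 57.4

    def _dist(self):
        mu = math.log(self.mode_mm) + self.log_sd**2
        return stats.lognorm(s=self.log_sd, scale=math.exp(mu))

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        lo: float | None = None,
        hi: float | None = None,
    ) -> np.ndarray:
        """Inverse-CDF sampling on the (possibly further restricted) support."""
        lo = self.min_mm if lo is None else max(lo, self.min_mm)
        hi = self.max_mm if hi is None else min(hi, self.max_mm)
        if not lo < hi:
            raise ConfigError(f"empty predator size window [{lo}, {hi}]")
        d = self._dist()
        a, b = d.cdf(lo), d.cdf(hi)
        return d.ppf(rng.uniform(a, b, n))


@dataclass(frozen=True)
class GastropodRule:
    ratio_threshold: float = 1.45
    prey_floor_mm: float = 5.0
    prey_cap_mm: float = 19.0
    predator_cap_mm: float = 41.0
    outlier_probability: float = 1.0 / 163.0


@dataclass(frozen=True)
class BivalveRule:
    prey_floor_mm: float = 3.7
    prey_cap_mm: float = 40.0
    window_widening: bool = True
    #: Beta(a, a) shape of the window fill; larger = tighter mid-window
    #: clustering, hence stronger predator-prey size correlation.
    fill_concentration: float = 8.0


@dataclass(frozen=True)
class CrustaceanRule:
    small_prey_mm: tuple[float, float] = (4.0, 15.0)
    predator_floor_mm: float = 23.0
    large_prey_probability: float = 2.0 / 43.0
    large_prey_mm: tuple[float, float] = (30.0, 40.0)
    large_prey_predator_mm: tuple[float, float] = (26.5, 35.0)


@dataclass(frozen=True)
class CannibalRule:
    predator_floor_mm: float = 41.0
    small_cannibal_probability: float = 3.0 / 31.0
    small_cannibal_predator_mm: tuple[float, float] = (25.0, 41.0)
    ratio_threshold: float = 1.45
    victim_floor_mm: float = 13.0
    victim_cap_small_mm: float = 19.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of one synthetic event table."""

    n_events: int = 327
    seed: int = 0
    predator_dist: PredatorSizeModel = field(default_factory=PredatorSizeModel)
    taxon_mix: tuple[float, float, float, float] = (
        165 / 327,
        88 / 327,
        43 / 327,
        31 / 327,
    )
    gastropod_rule: GastropodRule = field(default_factory=GastropodRule)
    bivalve_rule: BivalveRule = field(default_factory=BivalveRule)
    crustacean_rule: CrustaceanRule = field(default_factory=CrustaceanRule)
    cannibal_rule: CannibalRule = field(default_factory=CannibalRule)
    location: str = "Playa Grande"

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        """Build a config from a plain (e.g. YAML-loaded) mapping.

        Nested mappings populate the corresponding rule dataclasses;
        unknown keys raise rather than being ignored.
        """
        nested = {
            "predator_dist": PredatorSizeModel,
            "gastropod_rule": GastropodRule,
            "bivalve_rule": BivalveRule,
            "crustacean_rule": CrustaceanRule,
            "cannibal_rule": CannibalRule,
        }
        kwargs: dict = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in valid:
                raise ConfigError(f"unknown generator config key {key!r}")
            if key in nested and isinstance(value, dict):
                sub_valid = {f.name for f in dataclasses.fields(nested[key])}
                bad = set(value) - sub_valid
                if bad:
                    raise ConfigError(f"unknown keys in {key}: {sorted(bad)}")
                value = nested[key](
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in value.items()
                    }
                )
            elif key == "taxon_mix" and isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    def validate(self) -> None:
        if self.n_events < 1:
            raise ConfigError("n_events must be positive")
        if abs(sum(self.taxon_mix) - 1.0) > 1e-9:
            raise ConfigError(f"taxon_mix must sum to 1, got {sum(self.taxon_mix)}")
        if any(p < 0 for p in self.taxon_mix):
            raise ConfigError("taxon_mix probabilities must be nonnegative")
        d = self.predator_dist
        if not 0 < d.min_mm < d.max_mm:
            raise ConfigError("predator size bounds must satisfy 0 < min < max")
        g = self.gastropod_rule
        if not 0 < g.prey_floor_mm < g.prey_cap_mm:
            raise ConfigError("gastropod prey bounds must satisfy 0 < floor < cap")
        # smallest admissible predator must clear the ratio floor over prey_floor
        if g.prey_floor_mm * g.ratio_threshold >= min(g.predator_cap_mm, d.max_mm):
            raise ConfigError(
                "infeasible gastropod rule: no predator below the cap can take "
                "prey at the floor while respecting the ratio threshold"
            )
        b = self.bivalve_rule
        if not 0 < b.prey_floor_mm < b.prey_cap_mm:
            raise ConfigError("bivalve prey bounds must satisfy 0 < floor < cap")
        if b.prey_floor_mm >= d.min_mm:
            raise ConfigError("bivalve prey floor must be below the smallest predator")
        c = self.cannibal_rule
        if c.victim_floor_mm * c.ratio_threshold >= d.max_mm:
            raise ConfigError(
                "infeasible cannibal rule: victim floor times ratio threshold "
                "exceeds the largest predator"
            )
        lo, _ = c.small_cannibal_predator_mm
        if c.victim_floor_mm * c.ratio_threshold >= lo:
            raise ConfigError(
                "infeasible cannibal rule: small cannibals cannot clear the "
                "ratio threshold over the victim floor"
            )


@dataclass(frozen=True)
class GeneratorReport:
    """Realized composition of one generated table."""

    seed: int
    group_counts: dict[str, int]
    size_ranges: dict[str, tuple[float, float, float, float]]  # pred lo/hi, prey lo/hi

    @property
    def total(self) -> int:
        return sum(self.group_counts.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "group_counts": self.group_counts,
                "size_ranges": self.size_ranges,
            },
            indent=2,
        )


def _round01(x: np.ndarray) -> np.ndarray:
    """Round sizes to the 0.1 mm field measurement resolution."""
    return np.round(np.asarray(x, dtype=float), 1)


def _ratio_safe_cap(pred: np.ndarray, threshold: float) -> np.ndarray:
    """Largest 0.1 mm grid prey size satisfying pred/prey >= threshold.

    The candidate floor(pred/threshold) on the 0.1 grid is nudged down one
    step wherever floating-point rounding would leave the realized ratio a
    hair below the threshold, so generated events satisfy the constraint
    under the same arithmetic the analysis uses.
    """
    cap = np.floor(np.asarray(pred, dtype=float) * 10.0 / threshold) / 10.0
    bad = pred / cap < threshold
    cap[bad] -= 0.1
    return cap


def generate_population_sizes(
    n: int,
    predator_dist: PredatorSizeModel | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw shell lengths from the successful-predator size distribution.

    Used directly as the encounter pool in synthetic cannibalism-model
    tests. Values are rounded to 0.1 mm and lie within the truncation
    bounds.
    """
    if n < 1:
        raise ConfigError("n must be positive")
    dist = predator_dist or PredatorSizeModel()
    rng = rng if rng is not None else np.random.default_rng(seed)
    return _round01(dist.sample(n, rng))


def _gen_gastropod(n: int, cfg: GeneratorConfig, rng: np.random.Generator):
    rule = cfg.gastropod_rule
    # predator must clear ratio over the prey floor even after the cap
    pred_lo = max(cfg.predator_dist.min_mm, rule.prey_floor_mm * rule.ratio_threshold)
    pred = _round01(cfg.predator_dist.sample(n, rng, lo=pred_lo, hi=rule.predator_cap_mm))
    cap = np.minimum(rule.prey_cap_mm, _ratio_safe_cap(pred, rule.ratio_threshold))
    prey = _round01(rng.uniform(rule.prey_floor_mm, cap))
    outlier = rng.random(n) < rule.outlier_probability
    if outlier.any():
        # ratio violators: prey pushed just above L/threshold (may exceed the
        # usual prey cap for large predators, like the single field outlier)
        p = pred[outlier]
        lo = p / rule.ratio_threshold
        prey[outlier] = _round01(rng.uniform(lo * 1.01, np.maximum(lo * 1.05, 0.95 * p)))
    return pred, prey


def _gen_bivalve(n: int, cfg: GeneratorConfig, rng: np.random.Generator):
    rule = cfg.bivalve_rule
    pred = _round01(cfg.predator_dist.sample(n, rng))
    hi = np.minimum(pred, rule.prey_cap_mm)
    if rule.window_widening:
        a = rule.fill_concentration
        fill = rng.beta(a, a, n)
    else:
        fill = rng.uniform(0.0, 1.0, n)
    prey = rule.prey_floor_mm + (hi - rule.prey_floor_mm) * fill
    return pred, np.clip(_round01(prey), rule.prey_floor_mm, hi)


def _gen_crustacean(n: int, cfg: GeneratorConfig, rng: np.random.Generator):
    rule = cfg.crustacean_rule
    pred = _round01(cfg.predator_dist.sample(n, rng, lo=rule.predator_floor_mm))
    prey = _round01(rng.uniform(*rule.small_prey_mm, n))
    large = rng.random(n) < rule.large_prey_probability
    if large.any():
        m = int(large.sum())
        pred[large] = _round01(rng.uniform(*rule.large_prey_predator_mm, m))
        prey[large] = _round01(rng.uniform(*rule.large_prey_mm, m))
    return pred, prey


def _gen_cannibal(n: int, cfg: GeneratorConfig, rng: np.random.Generator):
    rule = cfg.cannibal_rule
    pred = _round01(cfg.predator_dist.sample(n, rng, lo=rule.predator_floor_mm))
    small = rng.random(n) < rule.small_cannibal_probability
    if small.any():
        m = int(small.sum())
        lo, hi = rule.small_cannibal_predator_mm
        pred[small] = _round01(cfg.predator_dist.sample(m, rng, lo=lo, hi=hi))
    cap = _ratio_safe_cap(pred, rule.ratio_threshold)
    cap[small] = np.minimum(cap[small], rule.victim_cap_small_mm)
    prey = _round01(rng.uniform(rule.victim_floor_mm, cap))
    return pred, prey


def _pick_taxa(group: str, n: int, rng: np.random.Generator) -> np.ndarray:
    names, weights = zip(*_TAXA_WITHIN_GROUP[group])
    p = np.asarray(weights, dtype=float)
    return rng.choice(np.asarray(names, dtype=object), size=n, p=p / p.sum())


def generate_events(config: GeneratorConfig | None = None) -> tuple[EventTable, GeneratorReport]:
    """Generate one synthetic event table plus its realization report.

    Deterministic given the config: the same seed yields a byte-identical
    CSV via :func:`preyspectra.events.write_events`.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()

    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(6)
    rng_assign = np.random.default_rng(streams[0])
    rng_by_group = {
        g: np.random.default_rng(s)
        for g, s in zip(_GROUP_ORDER, streams[1:5])
    }
    rng_dates = np.random.default_rng(streams[5])

    counts = rng_assign.multinomial(cfg.n_events, cfg.taxon_mix)
    generators = {
        "gastropod": _gen_gastropod,
        "bivalve": _gen_bivalve,
        "crustacean": _gen_crustacean,
        "conspecific": _gen_cannibal,
    }

    group_col: list[str] = []
    taxon_col: list[str] = []
    pred_col: list[np.ndarray] = []
    prey_col: list[np.ndarray] = []
    size_ranges: dict[str, tuple[float, float, float, float]] = {}
    for g, n in zip(_GROUP_ORDER, counts):
        if n == 0:
            continue
        rng = rng_by_group[g]
        pred, prey = generators[g](int(n), cfg, rng)
        group_col.extend([g] * int(n))
        taxon_col.extend(_pick_taxa(g, int(n), rng).tolist())
        pred_col.append(pred)
        prey_col.append(prey)
        size_ranges[g] = (
            float(pred.min()),
            float(pred.max()),
            float(prey.min()),
            float(prey.max()),
        )

    pred_all = np.concatenate(pred_col)
    prey_all = np.concatenate(prey_col)
    # interleave the groups so the file order is not block-structured
    order = rng_assign.permutation(cfg.n_events)

    start = dt.date(2011, 11, 1)
    span = (dt.date(2017, 4, 30) - start).days
    day_offsets = np.sort(rng_dates.integers(0, span + 1, cfg.n_events))
    dates = [start + dt.timedelta(days=int(d)) for d in day_offsets]

    frame = pd.DataFrame(
        {
            "date": dates,
            "location": [cfg.location] * cfg.n_events,
            "prey_group": np.asarray(group_col, dtype=object)[order],
            "prey_taxon": np.asarray(taxon_col, dtype=object)[order],
            "predator_length_mm": pred_all[order],
            "prey_length_mm": prey_all[order],
        },
        columns=list(COLUMNS),
    )
    table = EventTable(frame, provenance=f"synthetic(seed={cfg.seed}, n={cfg.n_events})")
    report = GeneratorReport(
        seed=cfg.seed,
        group_counts={g: int(c) for g, c in zip(_GROUP_ORDER, counts)},
        size_ranges=size_ranges,
    )
    return table, report
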