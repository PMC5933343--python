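"""Random-encounter cannibalism model and goodness-of-fit comparison.

The null model: every individual in the pool of successful predators meets
every other with equal probability, and a cannibalistic attack by the
larger on the smaller succeeds according to a step function of the shell
length ratio determined in field experiments — certain success at ratio
>= 1.46, certain failure below 1.18, and a coin flip in between. The
expected size-class distribution of successful cannibals then follows
analytically from the empirical size distribution alone, and is compared
with the observed cannibal distribution by a χ² goodness-of-fit statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, DegenerateModelError
from .events import EventTable
from .spectra import ClassDistribution, SizeClassGrid, class_distribution


@dataclass(frozen=True)
class RatioRules:
    """Step-function success probabilities for a cannibalistic attack.

    Both thresholds are inclusive lower bounds ("at least"): success
    probability is 1 for ratio >= success_threshold, 0 for ratio <
    failure_threshold, and intermediate_probability in between.
    """

    success_threshold: float = 1.46
    failure_threshold: float = 1.18
    intermediate_probability: float = 0.5

    def __post_init__(self) -> None:
        if not self.failure_threshold < self.success_threshold:
            raise ValueError("failure_threshold must be below success_threshold")
        if not 0.0 <= self.intermediate_probability <= 1.0:
            raise ValueError("intermediate_probability must lie in [0, 1]")


def success_probability(
    predator_length_mm: float, victim_length_mm: float, rules: RatioRules | None = None
) -> float:
    """Probability that an attack by predator on victim succeeds."""
    rules = rules or RatioRules()
    if predator_length_mm <= 0 or victim_length_mm <= 0:
        raise ValueError("lengths must be positive")
    ratio = predator_length_mm / victim_length_mm
    if ratio >= rules.success_threshold:
        return 1.0
    if ratio < rules.failure_threshold:
        return 0.0
    return rules.intermediate_probability


def _success_matrix(sizes: np.ndarray, rules: RatioRules) -> np.ndarray:
    """w[i, j] = success probability of i attacking j; zero diagonal."""
    ratio = sizes[:, None] / sizes[None, :]
    w = np.where(
        ratio >= rules.success_threshold,
        1.0,
        np.where(ratio < rules.failure_threshold, 0.0, rules.intermediate_probability),
    )
    np.fill_diagonal(w, 0.0)
    return w


def cannibal_propensities(sizes, rules: RatioRules | None = None) -> np.ndarray:
    """Raw per-individual cannibal weight W_i = sum_j w_ij over all j != i.

    W_i is nondecreasing in the individual's own size: growing can only
    move pairings across the thresholds in the favorable direction.
    """
    rules = rules or RatioRules()
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < 2:
        raise DegenerateDataError("need at least 2 individuals")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    return _success_matrix(sizes, rules).sum(axis=1)


def expected_cannibal_distribution(
    sizes,
    grid: SizeClassGrid | None = None,
    rules: RatioRules | None = None,
    scale_to: float = 1.0,
) -> np.ndarray:
    """Expected per-class counts of successful cannibals, scaled.

    All ordered pairs (i, j), i != j, are equally likely encounters; the
    per-class raw expectation sums the propensities W_i of the class
    members and is then normalized so the classes sum to ``scale_to``
    (normally the observed number of cannibalization events), making the
    subsequent χ² a comparison of distribution shapes.
    """
    grid = grid or SizeClassGrid()
    rules = rules or RatioRules()
    sizes = np.asarray(sizes, dtype=float)
    if scale_to <= 0:
        raise ValueError("scale_to must be positive")
    w_tot = cannibal_propensities(sizes, rules)
    raw = np.zeros(grid.n_classes, dtype=float)
    np.add.at(raw, grid.indices(sizes), w_tot)
    total = raw.sum()
    if total == 0:
        raise DegenerateModelError(
            "all pairwise success probabilities are zero; expected distribution undefined"
        )
    return raw * (scale_to / total)


def simulate_cannibal_distribution(
    sizes,
    grid: SizeClassGrid | None = None,
    rules: RatioRules | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Monte-Carlo check of the analytic expectation.

    Draws ``n_draws`` uniformly random ordered pairs (i, j), i != j,
    resolves each attack as a Bernoulli trial with probability w_ij, and
    histograms the attacker sizes of the successful attacks. Returns
    (per-class success counts, total successes). Used to validate
    :func:`expected_cannibal_distribution`, never to replace it.
    """
    grid = grid or SizeClassGrid()
    rules = rules or RatioRules()
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < 2:
        raise DegenerateDataError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    n = sizes.size
    i = rng.integers(0, n, n_draws)
    j = rng.integers(0, n - 1, n_draws)
    j = np.where(j >= i, j + 1, j)  # uniform over j != i
    w = _success_matrix(sizes, rules)[i, j]
    success = rng.random(n_draws) < w
    counts = np.zeros(grid.n_classes, dtype=int)
    np.add.at(counts, grid.indices(sizes[i[success]]), 1)
    return counts, int(success.sum())


def chi_square_gof(observed, expected, sum_rtol: float = 1e-6) -> tuple[float, int]:
    """χ² goodness of fit of observed counts against expected counts.

    Classes with expected = observed = 0 are skipped; expected = 0 with
    observed > 0 makes the statistic undefined and raises. df is the number
    of classes entering the sum minus one (the scaling constraint).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same shape")
    if not np.isclose(obs.sum(), exp.sum(), rtol=sum_rtol, atol=1e-9):
        raise ValueError(
            f"observed sum {obs.sum()} and expected sum {exp.sum()} disagree"
        )
    if np.any((exp == 0) & (obs > 0)):
        raise DegenerateModelError(
            "expected count 0 with observed > 0: χ² is undefined for this class"
        )
    use = exp > 0
    chi2 = float(np.sum((obs[use] - exp[use]) ** 2 / exp[use]))
    return chi2, int(use.sum()) - 1


@dataclass(frozen=True)
class CannibalismModelResult:
    """Expected vs observed cannibal size distributions plus χ² and df."""

    expected: tuple[float, ...]
    observed: tuple[int, ...]
    scale: float
    chi_square: float
    df: int
    grid: SizeClassGrid
    n_pool: int


def run_cannibalism_analysis(
    table: EventTable,
    grid: SizeClassGrid | None = None,
    rules: RatioRules | None = None,
) -> CannibalismModelResult:
    """Full cannibalism analysis on an event table.

    The encounter pool is the predator sizes of ALL successful predators in
    the table, whatever their prey; the observed distribution is the
    predator sizes of the conspecific-prey events only. The expectation is
    scaled to the observed number of cannibalization events before χ².
    """
    grid = grid or SizeClassGrid()
    rules = rules or RatioRules()
    groups = table.prey_groups
    cannibal_mask = groups == "conspecific"
    n_cannibal = int(cannibal_mask.sum())
    if n_cannibal == 0:
        raise DegenerateDataError("table contains no conspecific-prey events")
    pool = table.predator_lengths
    expected = expected_cannibal_distribution(pool, grid, rules, scale_to=n_cannibal)
    observed = class_distribution(table.subset(cannibal_mask), grid).counts
    chi2, df = chi_square_gof(np.asarray(observed), expected)
    return CannibalismModelResult(
        expected=tuple(float(e) for e in expected),
        observed=observed,
        scale=float(n_cannibal),
        chi_square=chi2,
        df=df,
        grid=grid,
        n_pool=int(pool.size),
    )
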