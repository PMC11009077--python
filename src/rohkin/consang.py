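"""Two-level Monte-Carlo test for the rate of first-cousin unions.

Level 1 (individual): the observed statistic of the most-ROH-rich
individual — summed ROH > 20 cM, or the single longest segment — is placed
within the simulated null distribution for offspring of a given union type,
as a one-sided lower-tail percentile q = P(statistic <= observed).

Level 2 (cohort): under the null hypothesis that each of n sampled
individuals is the offspring of a first-cousin union with probability r
(and otherwise carries no long ROH), the cohort maximum statistic is
compared with the observed maximum.  The one-sided p-value has the closed
form

    p = (1 - r * (1 - q)) ** n

because the cohort maximum is <= observed iff every first-cousin offspring
in the cohort falls in the lower q-tail.  A Monte-Carlo version simulates
cohorts directly (members drawn from the individual null) and must agree
with the closed form within sampling error.

Inverting the closed form at a significance level alpha gives the largest
union rate compatible with the data:

    r* = (1 - alpha ** (1/n)) / (1 - q).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeMap
from .pedigree import (
    DEFAULT_INTERFERENCE_SHAPE,
    PedigreeSpec,
    UnionType,
    simulate_offspring_roh,
)
from .profiles import DEFAULT_BINNING, ROHBinning, bin_profile

__all__ = [
    "SimDistribution",
    "CohortTestConfig",
    "CohortTestResult",
    "RateSearchResult",
    "build_null",
    "individual_percentile",
    "cohort_pvalue",
    "max_compatible_rate",
]

_STATISTICS = ("sum_gt20", "longest")


@dataclass(frozen=True)
class SimDistribution:
    """Empirical null distribution of (sum ROH>20 cM, longest segment)."""

    union_type: UnionType
    sum_gt20: np.ndarray
    longest: np.ndarray
    total: np.ndarray  # summed ROH over all lengths, for conservation checks
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for arr in (self.sum_gt20, self.longest, self.total):
            if len(arr) != self.n_reps or np.any(arr < 0):
                raise ValueError("replicate values must be n_reps non-negatives")

    def values(self, statistic: str) -> np.ndarray:
        if statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {statistic!r}; use one of {_STATISTICS}")
        return self.sum_gt20 if statistic == "sum_gt20" else self.longest


@dataclass(frozen=True)
class CohortTestConfig:
    """Cohort size n, first-cousin union rate r, level alpha, statistic."""

    n: int = 14
    rate_fc: float = 0.40
    alpha: float = 0.05
    n_reps: int = 10_000
    statistic: str = "sum_gt20"

    def __post_init__(self) -> None:
        if not 0 <= self.rate_fc <= 1:
            raise ValueError("rate_fc must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if self.statistic not in _STATISTICS:
            raise ValueError(f"statistic must be one of {_STATISTICS}")


@dataclass(frozen=True)
class CohortTestResult:
    p_monte_carlo: float
    p_closed_form: float
    q: float
    n_reps: int
    config: CohortTestConfig


@dataclass(frozen=True)
class RateSearchResult:
    rate: float
    q: float
    p_closed_form_at_rate: float
    p_monte_carlo_at_rate: float
    unbounded: bool = False


def build_null(
    union_type: UnionType | str,
    genome: GenomeMap,
    n_reps: int = 10_000,
    seed: int = 0,
    binning: ROHBinning = DEFAULT_BINNING,
    interference_shape: float = DEFAULT_INTERFERENCE_SHAPE,
) -> SimDistribution:
    """Simulate ``n_reps`` independent offspring of the union type and reduce
    each to (sum ROH>20, longest segment).

    Replicate i uses its own random stream derived from ``seed``, so any
    replicate is reproducible in isolation.
    """
    union_type = UnionType(union_type)
    if union_type is UnionType.UNRELATED:
        raise ValueError("the null is defined for consanguineous union types")
    spec = PedigreeSpec(union_type)
    sums = np.empty(n_reps)
    longs = np.empty(n_reps)
    totals = np.empty(n_reps)
    for i, child_seed in enumerate(np.random.SeedSequence(seed).spawn(n_reps)):
        rng = np.random.default_rng(child_seed)
        segs = simulate_offspring_roh(spec, genome, rng, interference_shape)
        prof = bin_profile(f"sim_{i}", segs, binning)
        sums[i] = prof.sum_gt20_cM
        longs[i] = prof.longest_cM
        totals[i] = sum(s.length_cM for s in segs)
    return SimDistribution(
        union_type=union_type,
        sum_gt20=sums,
        longest=longs,
        total=totals,
        n_reps=n_reps,
        seed=seed,
    )


def individual_percentile(
    observed: float, dist: SimDistribution, statistic: str = "sum_gt20"
) -> float:
    """One-sided lower-tail percentile: fraction of replicates with
    statistic <= observed (ties count as <=)."""
    values = dist.values(statistic)
    return float(np.mean(values <= observed))


def cohort_pvalue(
    config: CohortTestConfig,
    observed_max: float,
    genome: GenomeMap,
    seed: int = 0,
    null: SimDistribution | None = None,
) -> CohortTestResult:
    """One-sided p-value for the observed cohort maximum statistic.

    Monte Carlo: ``config.n_reps`` cohorts of size n; each member is a
    first-cousin offspring with probability ``rate_fc`` (its statistic drawn
    from the individual first-cousin null) and otherwise contributes 0.
    p is the fraction of cohorts whose maximum is <= observed_max.  The
    closed form ``(1 - r (1 - q)) ** n`` is returned alongside.
    """
    if observed_max < 0:
        raise ValueError("observed_max must be non-negative")
    if null is None:
        null = build_null(UnionType.FIRST_COUSIN, genome, config.n_reps, seed)
    q = individual_percentile(observed_max, null, config.statistic)
    r, n = config.rate_fc, config.n
    p_closed = float((1.0 - r * (1.0 - q)) ** n)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    values = null.values(config.statistic)
    ks = rng.binomial(n, r, size=config.n_reps)
    total = int(ks.sum())
    draws_ok = values[rng.integers(0, len(values), size=total)] <= observed_max
    # cohort maximum <= observed iff every consanguineous member's draw is;
    # cohorts with k=0 have maximum 0 <= observed_max
    offsets = np.concatenate([[0], np.cumsum(ks)[:-1]])
    ok = np.ones(config.n_reps, dtype=bool)
    nonzero = ks > 0
    if total:
        ok[nonzero] = np.minimum.reduceat(draws_ok, offsets[nonzero])
    p_mc = float(ok.mean())
    return CohortTestResult(
        p_monte_carlo=p_mc,
        p_closed_form=p_closed,
        q=q,
        n_reps=config.n_reps,
        config=config,
    )


def max_compatible_rate(
    config: CohortTestConfig,
    observed_max: float,
    genome: GenomeMap,
    seed: int = 0,
    null: SimDistribution | None = None,
) -> RateSearchResult:
    """Largest first-cousin union rate r with cohort p-value >= alpha.

    Closed form ``r* = (1 - alpha**(1/n)) / (1 - q)`` clipped to [0, 1],
    with a Monte-Carlo confirmation of the p-value at the returned rate.
    A degenerate null with q = 1 leaves the rate unbounded.
    """
    if null is None:
        null = build_null(UnionType.FIRST_COUSIN, genome, config.n_reps, seed)
    q = individual_percentile(observed_max, null, config.statistic)
    if q >= 1.0:
        return RateSearchResult(
            rate=1.0, q=q, p_closed_form_at_rate=1.0,
            p_monte_carlo_at_rate=1.0, unbounded=True,
        )
    r_star = (1.0 - config.alpha ** (1.0 / config.n)) / (1.0 - q)
    r_star = float(min(max(r_star, 0.0), 1.0))
    check = cohort_pvalue(
        CohortTestConfig(
            n=config.n, rate_fc=r_star, alpha=config.alpha,
            n_reps=config.n_reps, statistic=config.statistic,
        ),
        observed_max, genome, seed=seed, null=null,
    )
    return RateSearchResult(
        rate=r_star,
        q=q,
        p_closed_form_at_rate=check.p_closed_form,
        p_monte_carlo_at_rate=check.p_monte_carlo,
    )
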