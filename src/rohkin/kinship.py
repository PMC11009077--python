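"""Pairwise-mismatch relatedness and coverage-based genetic sexing.

Relatedness between two low-coverage individuals is estimated from their
pseudo-haploid pairwise mismatch rate (pmr): the fraction of overlapping
autosomal sites at which the two sampled alleles differ.  Against the
cohort baseline B (the unrelated-pair mismatch rate), the expected ratios
pmr/B are 0.50 for identical individuals (or the same person sampled
twice), 0.75 for first-degree pairs, 0.875 for second degree and 1.0 for
unrelated pairs; degree calls use midpoint decision boundaries.

Genetic sex is called from sequencing coverage on the sex chromosomes
normalized by autosomal coverage: females carry two X and no Y, males one
of each; calls outside the two decision regions are left indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import MISSING, GenotypeMatrix

__all__ = [
    "PairwiseMismatch",
    "SexCall",
    "DEGREE_BOUNDARIES",
    "MIN_OVERLAP_DEFAULT",
    "pairwise_mismatch",
    "estimate_baseline",
    "classify_degree",
    "call_sex",
    "tafone_sex_summary",
    "simulate_pair_genotypes",
]

#: ratio pmr/B decision boundaries (midpoints of 0.50/0.75/0.875/1.0)
DEGREE_BOUNDARIES = (0.625, 0.8125, 0.9375)
#: minimum overlapping sites for a degree call
MIN_OVERLAP_DEFAULT = 15_000

_DEGREES = ("identical", "first", "second", "unrelated-or-more-distant")


@dataclass(frozen=True)
class PairwiseMismatch:
    pair: tuple[str, str]
    n_overlap: int
    pmr: float
    min_overlap: int = MIN_OVERLAP_DEFAULT

    def __post_init__(self) -> None:
        if self.n_overlap < 0:
            raise ValueError("overlap count must be >= 0")
        if self.n_overlap >= self.min_overlap and not 0 <= self.pmr <= 1:
            raise ValueError("pmr must be in [0, 1]")

    @property
    def sufficient(self) -> bool:
        return self.n_overlap >= self.min_overlap


@dataclass(frozen=True)
class SexCall:
    individual: str
    x_normalized: float
    y_normalized: float
    call: str  # XX / XY / indeterminate


def pairwise_mismatch(
    genotypes: GenotypeMatrix,
    pair: tuple[str, str],
    min_overlap: int = MIN_OVERLAP_DEFAULT,
) -> PairwiseMismatch:
    """Mismatch rate of a pair over the autosomal sites both cover.

    Requires pseudo-haploid calls (one sampled allele per site); the degree
    call is deferred to :func:`classify_degree`.
    """
    if genotypes.ploidy_mode != "pseudo_haploid":
        raise ValueError("pairwise mismatch is defined on pseudo-haploid calls")
    a = genotypes.column(pair[0])
    b = genotypes.column(pair[1])
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    pmr = float(np.mean(a[both] != b[both])) if n else float("nan")
    return PairwiseMismatch(pair=tuple(pair), n_overlap=n, pmr=pmr, min_overlap=min_overlap)


def estimate_baseline(pms: Sequence[PairwiseMismatch]) -> float:
    """Cohort unrelated-pair baseline B.

    Median pmr over pairs with sufficient overlap, with one iteration of
    excluding pairs already below the second-degree boundary (so related
    pairs do not drag the baseline down).  Needs >= 10 usable pairs.
    """
    vals = np.array([p.pmr for p in pms if p.sufficient])
    if len(vals) < 10:
        raise ValueError("need >= 10 pairs with sufficient overlap to estimate B")
    b0 = float(np.median(vals))
    unrelated = vals[vals / b0 >= DEGREE_BOUNDARIES[-1]]
    return float(np.median(unrelated)) if len(unrelated) else b0


def classify_degree(pm: PairwiseMismatch, baseline: float) -> str:
    """Degree call from pmr/B with midpoint boundaries.

    The boundaries partition [0, inf): identical < 0.625 <= first <
    0.8125 <= second < 0.9375 <= unrelated-or-more-distant.
    """
    if baseline <= 0:
        raise ValueError("baseline B must be > 0")
    if not pm.sufficient:
        return "insufficient-data"
    ratio = pm.pmr / baseline
    for cut, name in zip(DEGREE_BOUNDARIES, _DEGREES):
        if ratio < cut:
            return name
    return _DEGREES[-1]


def call_sex(
    individual: str, x_rate: float, y_rate: float, autosomal_rate: float
) -> SexCall:
    """Genetic sex from X/Y coverage normalized by autosomal coverage.

    XX: normalized X in [0.8, 1.2] and Y < 0.05.  XY: X in [0.4, 0.6] and
    Y in [0.3, 0.7].  Anything else is indeterminate, never forced.
    """
    if autosomal_rate <= 0:
        raise ValueError("autosomal coverage rate must be > 0")
    if x_rate < 0 or y_rate < 0:
        raise ValueError("coverage rates must be >= 0")
    x = x_rate / autosomal_rate
    y = y_rate / autosomal_rate
    if 0.8 <= x <= 1.2 and y < 0.05:
        call = "XX"
    elif 0.4 <= x <= 0.6 and 0.3 <= y <= 0.7:
        call = "XY"
    else:
        call = "indeterminate"
    return SexCall(individual=individual, x_normalized=x, y_normalized=y, call=call)


def tafone_sex_summary(
    sex_calls: Iterable[SexCall] | Mapping[str, str],
    grouping: Mapping[str, str],
) -> tuple[pd.DataFrame, int, int]:
    """Sex composition per burial unit (tafone).

    Returns (per-unit table, number of multi-individual units, number of
    multi-individual units containing both XX and XY individuals).
    """
    if not grouping:
        raise ValueError("empty burial grouping")
    if isinstance(sex_calls, Mapping):
        calls = dict(sex_calls)
    else:
        calls = {c.individual: c.call for c in sex_calls}
    rows = []
    units: dict[str, list[str]] = {}
    for ind, unit in grouping.items():
        units.setdefault(unit, []).append(ind)
    for unit, inds in sorted(units.items()):
        cs = [calls.get(i, "indeterminate") for i in inds]
        n_xx = cs.count("XX")
        n_xy = cs.count("XY")
        rows.append(
            {
                "burial_unit": unit,
                "n_individuals": len(inds),
                "n_XX": n_xx,
                "n_XY": n_xy,
                "n_indeterminate": len(cs) - n_xx - n_xy,
                "both_sexes": n_xx > 0 and n_xy > 0,
            }
        )
    table = pd.DataFrame(rows)
    multi = table[table["n_individuals"] >= 2]
    return table, int(len(multi)), int(multi["both_sexes"].sum())


def simulate_pair_genotypes(
    relationship: str,
    n_sites: int,
    rng: np.random.Generator,
    freq: float | np.ndarray = 0.5,
) -> GenotypeMatrix:
    """Pseudo-haploid calls for a synthetic pair at unlinked sites.

    ``relationship``: "duplicate" (two pseudo-haploid samplings of one
    diploid individual), "parent_offspring" (the child inherits one allele
    from the parent), or "unrelated".  Used as the simulation oracle for
    the degree classifier.
    """
    f = np.broadcast_to(np.asarray(freq, dtype=float), (n_sites,))
    a1 = rng.random(n_sites) < f  # individual A's two alleles (alt indicators)
    a2 = rng.random(n_sites) < f
    if relationship == "duplicate":
        b1, b2 = a1, a2
    elif relationship == "parent_offspring":
        # child: one allele transmitted by A, one from the population
        b1 = np.where(rng.random(n_sites) < 0.5, a1, a2)
        b2 = rng.random(n_sites) < f
    elif relationship == "unrelated":
        b1 = rng.random(n_sites) < f
        b2 = rng.random(n_sites) < f
    else:
        raise ValueError(f"unknown relationship {relationship!r}")
    pick_a = rng.integers(2, size=n_sites).astype(bool)
    pick_b = rng.integers(2, size=n_sites).astype(bool)
    samp_a = np.where(pick_a, a1, a2)
    samp_b = np.where(pick_b, b1, b2)
    calls = np.stack(
        [2 - 2 * samp_a.astype(np.int8), 2 - 2 * samp_b.astype(np.int8)], axis=1
    )
    sites = pd.DataFrame(
        {
            "chromosome": "1",
            "bp": np.arange(1, n_sites + 1),
            "cM": np.linspace(0.0, 1.0, n_sites),
            "ref": "A",
            "alt": "G",
            "freq": f,
        }
    )
    return GenotypeMatrix(sites, ["A", "B"], calls, "pseudo_haploid")
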