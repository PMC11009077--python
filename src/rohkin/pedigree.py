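"""Pedigree gene-dropping simulation of runs of homozygosity.

The consanguinity test needs the null distribution of ROH carried by the
offspring of a first-cousin (or second-cousin) union.  We obtain it by gene
dropping: every founder haplotype in the pedigree receives a unique label,
meioses propagate label mosaics down the pedigree under a renewal crossover
model, and the offspring's ROH are the maximal intervals where its two
haplotypes carry the same founder label (autozygosity).

Full first cousins share two grandparents (offspring inbreeding coefficient
F = 1/16); second cousins share two great-grandparents (F = 1/64).
Individuals from "unrelated" unions carry zero ROH under the simplifying
assumption that any deeper genealogical relationship is too old to produce
long segments.

Crossovers follow the chi-square interference model: chiasmata on the
four-strand bundle form a stationary gamma renewal process with shape
``nu`` and rate 2 per Morgan, and each chiasma involves the transmitted
chromatid with probability 1/2.  The gamete therefore sees on average one
crossover per Morgan regardless of ``nu``; ``nu = 1`` recovers the
no-interference Poisson model, while the default ``nu = 5`` corresponds to
the classic human interference estimate (chi-square m = 4).  Interference
leaves mean ROH (F x G) untouched but thins the right tail of segment
lengths, which matters for longest-segment statistics.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .genome import ChromosomeMap, GenomeMap

__all__ = [
    "DEFAULT_INTERFERENCE_SHAPE",
    "crossover_positions",
    "UnionType",
    "PedigreeSpec",
    "ROHSegment",
    "LabeledHaplotype",
    "meiosis",
    "shared_segments",
    "simulate_offspring_roh",
]


class UnionType(str, Enum):
    FIRST_COUSIN = "first_cousin"
    SECOND_COUSIN = "second_cousin"
    UNRELATED = "unrelated"


#: inbreeding coefficient of the offspring, by union type
_F_BY_UNION = {
    UnionType.FIRST_COUSIN: 1.0 / 16.0,
    UnionType.SECOND_COUSIN: 1.0 / 64.0,
    UnionType.UNRELATED: 0.0,
}


@dataclass(frozen=True)
class PedigreeSpec:
    """Union type plus its implied offspring inbreeding coefficient F."""

    union_type: UnionType

    def __post_init__(self) -> None:
        object.__setattr__(self, "union_type", UnionType(self.union_type))

    @property
    def inbreeding_coefficient(self) -> float:
        return _F_BY_UNION[self.union_type]


@dataclass(frozen=True)
class ROHSegment:
    """A run of homozygosity as a half-open interval [start_cM, end_cM)."""

    chromosome: str
    start_cM: float
    end_cM: float

    def __post_init__(self) -> None:
        if not self.end_cM > self.start_cM:
            raise ValueError("ROHSegment requires end_cM > start_cM")

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


class LabeledHaplotype:
    """Piecewise-constant founder-label mosaic along one chromosome.

    ``bounds`` has ``n_intervals + 1`` strictly increasing entries spanning
    ``[0, length_cM]``; interval ``i`` is ``[bounds[i], bounds[i+1])`` and
    carries founder label ``labels[i]``.  Adjacent intervals never share a
    label (merged on construction by :func:`meiosis`).
    """

    __slots__ = ("chromosome", "bounds", "labels")

    def __init__(self, chromosome: str, bounds: list[float], labels: list[int]):
        if len(bounds) != len(labels) + 1:
            raise ValueError("bounds must have one more entry than labels")
        if any(b >= a for a, b in zip(bounds[1:], bounds)):
            raise ValueError("bounds must be strictly increasing")
        if bounds[0] != 0.0:
            raise ValueError("haplotype must start at 0 cM")
        self.chromosome = chromosome
        self.bounds = bounds
        self.labels = labels

    @property
    def length_cM(self) -> float:
        return self.bounds[-1]

    @classmethod
    def founder(cls, chrom: ChromosomeMap, label: int) -> "LabeledHaplotype":
        return cls(chrom.name, [0.0, chrom.length_cM], [label])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LabeledHaplotype)
            and self.chromosome == other.chromosome
            and self.bounds == other.bounds
            and self.labels == other.labels
        )

    def __repr__(self) -> str:
        return f"LabeledHaplotype({self.chromosome}, {len(self.labels)} intervals)"


def _append_slice(
    hap: LabeledHaplotype,
    start: float,
    end: float,
    out_bounds: list[float],
    out_labels: list[int],
) -> None:
    """Append the piece [start, end) of ``hap`` to the output mosaic, merging
    adjacent intervals that carry the same label."""
    b = hap.bounds
    lab = hap.labels
    i = bisect_right(b, start) - 1
    if i >= len(lab):  # start == chromosome end; nothing to copy
        return
    while i < len(lab) and b[i] < end:
        hi = min(b[i + 1], end)
        if out_labels and out_labels[-1] == lab[i]:
            out_bounds[-1] = hi
        else:
            out_labels.append(lab[i])
            out_bounds.append(hi)
        i += 1


#: default interference shape (chi-square model, human m = 4)
DEFAULT_INTERFERENCE_SHAPE = 5.0


def crossover_positions(
    length_cM: float,
    rng: np.random.Generator,
    interference_shape: float = DEFAULT_INTERFERENCE_SHAPE,
) -> list[float]:
    """Sorted crossover positions on one gamete along a chromosome.

    Chiasmata on the tetrad are a stationary gamma renewal process with shape
    ``interference_shape`` and rate 2 per Morgan; each involves the gamete's
    chromatid with probability 1/2, giving a mean of ``length_cM / 100``
    crossovers per meiosis.  Shape 1 is the exact Poisson special case.
    """
    if interference_shape <= 0:
        raise ValueError("interference_shape must be positive")
    nu = interference_shape
    scale = 100.0 / (2.0 * nu)  # gamma scale in cM for tetrad rate 2/Morgan
    # stationary start: distance to the first chiasma is U * (length-biased
    # spacing), the length-biased gamma(nu) being gamma(nu + 1)
    x = rng.uniform() * rng.gamma(nu + 1.0, scale)
    pts: list[float] = []
    while x < length_cM:
        if rng.integers(2) == 0:  # chromatid thinning
            pts.append(x)
        x += rng.gamma(nu, scale)
    return pts


def meiosis(
    hap_a: LabeledHaplotype,
    hap_b: LabeledHaplotype,
    chrom: ChromosomeMap,
    rng: np.random.Generator,
    interference_shape: float = DEFAULT_INTERFERENCE_SHAPE,
) -> LabeledHaplotype:
    """One meiosis: recombine two parental haplotypes into a gamete.

    Crossover positions come from :func:`crossover_positions` (mean count
    ``length_cM / 100``); the starting haplotype is chosen with probability
    1/2 and sources alternate at each crossover.  The output intervals
    exactly partition the chromosome.
    """
    for h in (hap_a, hap_b):
        if h.chromosome != chrom.name or abs(h.length_cM - chrom.length_cM) > 1e-9:
            raise ValueError("haplotype does not span the given chromosome")
    L = chrom.length_cM
    first = hap_a if rng.integers(2) == 0 else hap_b
    cuts = crossover_positions(L, rng, interference_shape)
    if not cuts:
        return LabeledHaplotype(chrom.name, list(first.bounds), list(first.labels))
    other = hap_b if first is hap_a else hap_a
    out_bounds: list[float] = [0.0]
    out_labels: list[int] = []
    pos = 0.0
    cur, nxt = first, other
    for c in cuts:
        if c > pos:
            _append_slice(cur, pos, c, out_bounds, out_labels)
            pos = c
        cur, nxt = nxt, cur
    if pos < L:
        _append_slice(cur, pos, L, out_bounds, out_labels)
    return LabeledHaplotype(chrom.name, out_bounds, out_labels)


def shared_segments(
    hap1: LabeledHaplotype, hap2: LabeledHaplotype, min_length_cM: float = 0.0
) -> list[ROHSegment]:
    """Maximal intervals where the two haplotypes carry the same founder label."""
    if hap1.chromosome != hap2.chromosome:
        raise ValueError("haplotypes are on different chromosomes")
    L = hap1.bounds[-1]
    segs: list[ROHSegment] = []
    i = j = 0
    pos = 0.0
    run_start: float | None = None
    while pos < L:
        e1 = hap1.bounds[i + 1]
        e2 = hap2.bounds[j + 1]
        end = e1 if e1 < e2 else e2
        if hap1.labels[i] == hap2.labels[j]:
            if run_start is None:
                run_start = pos
        else:
            if run_start is not None:
                if pos - run_start > min_length_cM:
                    segs.append(ROHSegment(hap1.chromosome, run_start, pos))
                run_start = None
        pos = end
        if e1 <= end:
            i += 1
        if e2 <= end:
            j += 1
    if run_start is not None and L - run_start > min_length_cM:
        segs.append(ROHSegment(hap1.chromosome, run_start, L))
    return segs


def _drop_first_cousin(
    chrom: ChromosomeMap, rng: np.random.Generator, nu: float
) -> list[ROHSegment]:
    def gamete(parent):
        return meiosis(*parent, chrom, rng, interference_shape=nu)

    F = LabeledHaplotype.founder
    # shared grandparents
    g1 = (F(chrom, 0), F(chrom, 1))
    g2 = (F(chrom, 2), F(chrom, 3))
    # spouses marrying into the two sibling lines
    sa = (F(chrom, 4), F(chrom, 5))
    sb = (F(chrom, 6), F(chrom, 7))
    sib_a = (gamete(g1), gamete(g2))
    sib_b = (gamete(g1), gamete(g2))
    p1 = (gamete(sib_a), gamete(sa))
    p2 = (gamete(sib_b), gamete(sb))
    return shared_segments(gamete(p1), gamete(p2))


def _drop_second_cousin(
    chrom: ChromosomeMap, rng: np.random.Generator, nu: float
) -> list[ROHSegment]:
    def gamete(parent):
        return meiosis(*parent, chrom, rng, interference_shape=nu)

    F = LabeledHaplotype.founder
    # shared great-grandparents
    gg1 = (F(chrom, 0), F(chrom, 1))
    gg2 = (F(chrom, 2), F(chrom, 3))
    spouses = [(F(chrom, 4 + 2 * k), F(chrom, 5 + 2 * k)) for k in range(4)]
    sib_a = (gamete(gg1), gamete(gg2))
    sib_b = (gamete(gg1), gamete(gg2))
    d1 = (gamete(sib_a), gamete(spouses[0]))
    d2 = (gamete(sib_b), gamete(spouses[1]))
    p1 = (gamete(d1), gamete(spouses[2]))
    p2 = (gamete(d2), gamete(spouses[3]))
    return shared_segments(gamete(p1), gamete(p2))


def simulate_offspring_roh(
    spec: PedigreeSpec,
    genome: GenomeMap,
    rng: np.random.Generator,
    interference_shape: float = DEFAULT_INTERFERENCE_SHAPE,
) -> list[ROHSegment]:
    """Gene-drop one offspring of the specified union and return its ROH.

    Per-chromosome random streams are spawned from ``rng`` in genome order,
    so the result is invariant to chromosome processing order given the
    derived streams.  Segments are returned sorted in genome order, merged
    (adjacent same-label intervals coalesced inside :func:`shared_segments`).
    """
    spec = PedigreeSpec(spec.union_type)
    if spec.union_type is UnionType.UNRELATED:
        return []
    drop = (
        _drop_first_cousin
        if spec.union_type is UnionType.FIRST_COUSIN
        else _drop_second_cousin
    )
    segs: list[ROHSegment] = []
    for chrom, crng in zip(genome.chromosomes, rng.spawn(len(genome.chromosomes))):
        segs.extend(drop(chrom, crng, interference_shape))
    return segs
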