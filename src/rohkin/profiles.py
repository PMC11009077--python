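"""Binned ROH profiles and coverage-based inclusion filtering.

An individual's ROH calls are summarized into the length bins used
throughout the analysis — [4, 8), [8, 12), [12, 20] and > 20 cM — together
with the summed length > 20 cM and the single longest segment.  Segments
shorter than 4 cM are below the reliable calling floor for ancient
pseudo-haploid data and are excluded from the profile.

The exactly-20 boundary goes to the [12, 20] bin so that the four bins
partition [4, inf): the "> 20 cM" statistic is strict, matching the
convention that long-ROH sums count only segments strictly longer than
20 cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pedigree import ROHSegment

__all__ = [
    "ROHBinning",
    "ROHProfile",
    "DEFAULT_BINNING",
    "bin_profile",
    "filter_individuals",
    "MIN_SNPS_KINSHIP",
    "MIN_SNPS_ROH",
]

#: coverage floor for kinship / population analyses (covered SNPs)
MIN_SNPS_KINSHIP = 20_000
#: coverage floor for ROH calling and Ne estimation (covered SNPs)
MIN_SNPS_ROH = 300_000


@dataclass(frozen=True)
class ROHBinning:
    """Length-bin edges in cM; the final edge opens the strict > edge bin."""

    edges: tuple[float, ...] = (4.0, 8.0, 12.0, 20.0)

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("need at least two bin edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def labels(self) -> tuple[str, ...]:
        finite = [
            f"{_fmt(a)}_{_fmt(b)}" for a, b in zip(self.edges, self.edges[1:])
        ]
        return tuple(finite + [f"gt{_fmt(self.edges[-1])}"])

    def bin_index(self, length_cM: float) -> int | None:
        """Index of the bin containing a segment length, or None if below
        the calling floor.  Half-open [lo, hi) bins; the last finite bin is
        closed at its upper edge; the final bin is strict >."""
        if length_cM < self.edges[0]:
            return None
        if length_cM > self.edges[-1]:
            return self.n_bins - 1
        for i, (a, b) in enumerate(zip(self.edges, self.edges[1:])):
            if a <= length_cM < b or (b == self.edges[-1] and length_cM == b):
                return i
        return None  # pragma: no cover


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


DEFAULT_BINNING = ROHBinning()


@dataclass(frozen=True)
class ROHProfile:
    """Per-individual binned ROH record: the unit of the whole pipeline."""

    individual_id: str
    segments: tuple[ROHSegment, ...]
    bin_sums: tuple[float, ...]
    bin_counts: tuple[int, ...]
    sum_gt20_cM: float
    longest_cM: float
    n_snps_covered: int | None = None
    binning: ROHBinning = field(default=DEFAULT_BINNING)

    @property
    def total_cM(self) -> float:
        """Total ROH length above the calling floor."""
        return float(sum(self.bin_sums))

    @property
    def n_segments(self) -> int:
        return int(sum(self.bin_counts))


def bin_profile(
    individual_id: str,
    segments: Iterable[ROHSegment],
    binning: ROHBinning = DEFAULT_BINNING,
    n_snps_covered: int | None = None,
) -> ROHProfile:
    """Reduce a segment list to a binned :class:`ROHProfile`.

    Segments below the lowest edge (default 4 cM) are dropped; the summed
    ROH > 20 cM and the longest segment are computed over the retained set.
    Idempotent and invariant to segment order.
    """
    kept: list[ROHSegment] = []
    sums = [0.0] * binning.n_bins
    counts = [0] * binning.n_bins
    longest = 0.0
    sum_gt = 0.0
    for seg in segments:
        if seg.length_cM <= 0:
            raise ValueError(f"non-positive segment length for {individual_id}")
        idx = binning.bin_index(seg.length_cM)
        if idx is None:
            continue
        kept.append(seg)
        sums[idx] += seg.length_cM
        counts[idx] += 1
        if seg.length_cM > binning.edges[-1]:
            sum_gt += seg.length_cM
        if seg.length_cM > longest:
            longest = seg.length_cM
    kept.sort(key=lambda s: (s.chromosome, s.start_cM))
    return ROHProfile(
        individual_id=individual_id,
        segments=tuple(kept),
        bin_sums=tuple(sums),
        bin_counts=tuple(counts),
        sum_gt20_cM=sum_gt,
        longest_cM=longest,
        n_snps_covered=n_snps_covered,
        binning=binning,
    )


def filter_individuals(
    records: Sequence[ROHProfile] | Mapping[str, int],
    min_snps: int,
) -> tuple[list, list[tuple[str, str]]]:
    """Apply the inclusive coverage floor: keep records with
    ``n_snps_covered >= min_snps``.

    Accepts either a sequence of :class:`ROHProfile` (or any objects with
    ``individual_id`` and ``n_snps_covered``) or a mapping id -> coverage.
    Returns ``(retained, exclusion_log)`` where the log holds
    ``(individual_id, reason)`` pairs.
    """
    if isinstance(records, Mapping):
        items = [(k, k, v) for k, v in records.items()]
    else:
        items = [(r, r.individual_id, r.n_snps_covered) for r in records]
    retained, excluded = [], []
    for rec, ind, cov in items:
        if cov is None:
            raise ValueError(f"{ind}: missing n_snps_covered")
        if cov >= min_snps:
            retained.append(rec)
        else:
            excluded.append((ind, f"{cov} covered SNPs < {min_snps}"))
    return retained, excluded
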