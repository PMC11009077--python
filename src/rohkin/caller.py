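"""Diploid ROH calling with a two-state HMM, plus a synthetic-genotype
generator with planted ROH tracts.

The caller is intentionally diploid-only: low-coverage ancient data are
pseudo-haploid and need a haplotype-copying model with an external reference
panel, which is out of scope here.  This module exists so the segment ->
profile -> test pipeline is exercisable end to end on synthetic data with a
known truth table.

HMM: hidden states non-ROH (0) and ROH (1).  Emissions per site use the
population allele frequency f: under non-ROH, genotypes follow Hardy-
Weinberg [(1-f)^2, 2f(1-f), f^2]; under ROH the site is autozygous,
[(1-f), ~0, f], with a small heterozygote emission floor absorbing
genotyping error.  Transition probabilities between adjacent sites scale
with the genetic distance d via the two-state continuous-process solution
with rates 1/t_in (into ROH) and 1/t_out (out of ROH) per cM.  Posterior
decoding at a threshold yields segments; those shorter than the calling
floor (4 cM) are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .pedigree import ROHSegment

__all__ = [
    "GenotypeMatrix",
    "GenotypeSimConfig",
    "ROHCallerParams",
    "synthesize_genotypes",
    "call_roh",
]

MISSING = 9


@dataclass
class GenotypeMatrix:
    """Sites x individuals genotype calls, EIGENSTRAT-dialect backed.

    ``calls[i, j]`` is the reference-allele count of individual j at site i:
    0/1/2 for diploid calls, 0/2 for pseudo-haploid, 9 for missing.  Sites
    is a DataFrame with columns chromosome, bp, cM, ref, alt, freq (alt
    allele frequency), sorted by (chromosome, cM).
    """

    sites: pd.DataFrame
    individuals: list[str]
    calls: np.ndarray
    ploidy_mode: str = "diploid"

    def __post_init__(self) -> None:
        if self.ploidy_mode not in ("diploid", "pseudo_haploid"):
            raise ValueError("ploidy_mode must be 'diploid' or 'pseudo_haploid'")
        if self.calls.shape != (len(self.sites), len(self.individuals)):
            raise ValueError("calls shape must be (n_sites, n_individuals)")
        allowed = {0, 1, 2, MISSING} if self.ploidy_mode == "diploid" else {0, 2, MISSING}
        present = set(np.unique(self.calls).tolist())
        if not present <= allowed:
            raise ValueError(f"calls contain values {present - allowed} invalid for {self.ploidy_mode}")
        if "freq" in self.sites.columns:
            f = self.sites["freq"].to_numpy()
            if np.any((f <= 0) | (f >= 1)):
                raise ValueError("allele frequencies must lie in (0, 1)")
        for chrom, grp in self.sites.groupby("chromosome", sort=False):
            if np.any(np.diff(grp["cM"].to_numpy()) < 0):
                raise ValueError(f"sites not sorted by cM on chromosome {chrom}")

    def column(self, individual: str) -> np.ndarray:
        return self.calls[:, self.individuals.index(individual)]


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Synthetic-genotype contract: marker density, allele frequencies,
    per-allele genotyping error rate epsilon, missingness, planted ROH."""

    density_per_cM: float = 20.0
    freq_range: tuple[float, float] = (0.05, 0.95)
    error_rate: float = 0.0
    missing_rate: float = 0.0
    planted_roh: dict[str, list[ROHSegment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.density_per_cM > 0:
            raise ValueError("density_per_cM must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for ind, segs in self.planted_roh.items():
            by_chrom: dict[str, list[ROHSegment]] = {}
            for s in segs:
                by_chrom.setdefault(s.chromosome, []).append(s)
            for chrom, ss in by_chrom.items():
                ss = sorted(ss, key=lambda s: s.start_cM)
                for a, b in zip(ss, ss[1:]):
                    if b.start_cM < a.end_cM:
                        raise ValueError(
                            f"{ind}: overlapping planted segments on chromosome {chrom}"
                        )


def synthesize_genotypes(
    config: GenotypeSimConfig,
    genome: GenomeMap,
    rng: np.random.Generator,
    individuals: list[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate a diploid genotype matrix with planted autozygous tracts.

    Outside planted ROH the two haplotypes are drawn independently from the
    site allele frequency; inside, a single draw is shared by both.  Each
    allele then flips with probability ``error_rate``; calls go missing
    independently with ``missing_rate``.  Returns the matrix and the truth
    segment table (individual_id, chromosome, start_cM, end_cM, length_cM).
    """
    if individuals is None:
        individuals = sorted(config.planted_roh) or ["ind_0"]
    site_rows = []
    for chrom in genome.chromosomes:
        n = max(2, int(round(config.density_per_cM * chrom.length_cM)))
        cms = np.sort(rng.uniform(0.0, chrom.length_cM, size=n))
        freqs = rng.uniform(*config.freq_range, size=n)
        for cm, f in zip(cms, freqs):
            site_rows.append((chrom.name, int(cm * 1e4) + 1, cm, "A", "G", f))
    sites = pd.DataFrame(
        site_rows, columns=["chromosome", "bp", "cM", "ref", "alt", "freq"]
    )
    n_sites = len(sites)
    freqs = sites["freq"].to_numpy()
    calls = np.empty((n_sites, len(individuals)), dtype=np.int8)

    chrom_codes = sites["chromosome"].to_numpy()
    cms = sites["cM"].to_numpy()
    for j, ind in enumerate(individuals):
        in_roh = np.zeros(n_sites, dtype=bool)
        for seg in config.planted_roh.get(ind, []):
            in_roh |= (
                (chrom_codes == seg.chromosome)
                & (cms >= seg.start_cM)
                & (cms < seg.end_cM)
            )
        h1 = rng.random(n_sites) < freqs  # alt-allele indicators
        h2 = np.where(in_roh, h1, rng.random(n_sites) < freqs)
        if config.error_rate > 0:
            h1 ^= rng.random(n_sites) < config.error_rate
            h2 ^= rng.random(n_sites) < config.error_rate
        geno = 2 - (h1.astype(np.int8) + h2.astype(np.int8))  # ref-allele count
        if config.missing_rate > 0:
            geno[rng.random(n_sites) < config.missing_rate] = MISSING
        calls[:, j] = geno

    truth = pd.DataFrame(
        [
            (ind, s.chromosome, s.start_cM, s.end_cM, s.length_cM)
            for ind in individuals
            for s in config.planted_roh.get(ind, [])
        ],
        columns=["individual_id", "chromosome", "start_cM", "end_cM", "length_cM"],
    )
    return GenotypeMatrix(sites, list(individuals), calls, "diploid"), truth


@dataclass(frozen=True)
class ROHCallerParams:
    roh_het_emission: float = 0.01
    t_in_cM: float = 100.0  # mean non-ROH tract length (1/rate into ROH)
    t_out_cM: float = 10.0  # mean ROH tract length (1/rate out of ROH)
    posterior_threshold: float = 0.5
    min_length_cM: float = 4.0


def _forward_backward(
    log_e: np.ndarray, dists: np.ndarray, params: ROHCallerParams
) -> np.ndarray:
    """Posterior P(ROH) for one chromosome; log_e is (n_sites, 2) emission
    log-likelihoods, dists the cM gaps between consecutive sites."""
    a = 1.0 / params.t_in_cM
    b = 1.0 / params.t_out_cM
    pi1 = a / (a + b)  # stationary P(ROH)
    n = len(log_e)
    decay = np.exp(-(a + b) * dists)
    # 2-state transition matrices per gap
    p01 = pi1 * (1.0 - decay)
    p11 = pi1 + (1.0 - pi1) * decay
    log_fwd = np.empty((n, 2))
    log_bwd = np.empty((n, 2))
    log_fwd[0, 0] = math.log(1.0 - pi1) + log_e[0, 0]
    log_fwd[0, 1] = math.log(pi1) + log_e[0, 1]
    for i in range(1, n):
        t00, t01 = math.log1p(-p01[i - 1]), math.log(p01[i - 1])
        t11, t10 = math.log(p11[i - 1]), math.log1p(-p11[i - 1])
        f0, f1 = log_fwd[i - 1]
        log_fwd[i, 0] = np.logaddexp(f0 + t00, f1 + t10) + log_e[i, 0]
        log_fwd[i, 1] = np.logaddexp(f0 + t01, f1 + t11) + log_e[i, 1]
    log_bwd[-1] = 0.0
    for i in range(n - 2, -1, -1):
        t00, t01 = math.log1p(-p01[i]), math.log(p01[i])
        t11, t10 = math.log(p11[i]), math.log1p(-p11[i])
        b0, b1 = log_bwd[i + 1]
        log_bwd[i, 0] = np.logaddexp(t00 + log_e[i + 1, 0] + b0, t01 + log_e[i + 1, 1] + b1)
        log_bwd[i, 1] = np.logaddexp(t10 + log_e[i + 1, 0] + b0, t11 + log_e[i + 1, 1] + b1)
    log_post = log_fwd + log_bwd
    log_post -= np.logaddexp(log_post[:, 0], log_post[:, 1])[:, None]
    return np.exp(log_post[:, 1])


def call_roh(
    genotypes: GenotypeMatrix,
    individual: str,
    params: ROHCallerParams = ROHCallerParams(),
) -> list[ROHSegment]:
    """Call ROH segments for one individual from diploid genotypes.

    Raises on pseudo-haploid input: single sampled alleles carry no
    within-individual heterozygosity signal, and calling ROH from them
    needs the reference-panel copying model that is out of scope.
    """
    if genotypes.ploidy_mode != "diploid":
        raise ValueError(
            "call_roh supports diploid genotypes only; pseudo-haploid ROH "
            "calling requires a haplotype-copying model (see module docs)"
        )
    geno = genotypes.column(individual)
    segs: list[ROHSegment] = []
    for chrom, grp in genotypes.sites.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        cm = grp["cM"].to_numpy()
        f = grp["freq"].to_numpy()
        g = geno[idx]
        het = g == 1
        hom_ref = g == 0
        hom_alt = g == 2
        missing = g == MISSING
        e = params.roh_het_emission
        # emission P(observed genotype | state); alt freq f
        p_bg = np.select(
            [het, hom_ref, hom_alt],
            [2 * f * (1 - f), (1 - f) ** 2, f**2],
            default=1.0,
        )
        p_roh = np.select(
            [het, hom_ref, hom_alt],
            [np.full_like(f, e), (1 - e) * (1 - f), (1 - e) * f],
            default=1.0,
        )
        p_bg = np.where(missing, 1.0, np.maximum(p_bg, 1e-12))
        p_roh = np.where(missing, 1.0, np.maximum(p_roh, 1e-12))
        log_e = np.stack([np.log(p_bg), np.log(p_roh)], axis=1)
        post = _forward_backward(log_e, np.diff(cm), params)
        in_roh = post >= params.posterior_threshold
        # runs of ROH-state sites -> segments
        boundaries = np.flatnonzero(np.diff(in_roh.astype(np.int8)))
        starts = [0] if in_roh[0] else []
        starts += [i + 1 for i in boundaries if not in_roh[i]]
        ends = [i + 1 for i in boundaries if in_roh[i]]
        if in_roh[-1]:
            ends.append(len(in_roh))
        for s, t in zip(starts, ends):
            length = cm[t - 1] - cm[s]
            if length >= params.min_length_cM:
                segs.append(ROHSegment(str(chrom), float(cm[s]), float(cm[t - 1])))
    segs.sort(key=lambda s: (s.chromosome, s.start_cM))
    return segs
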