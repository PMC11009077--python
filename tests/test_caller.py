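"""Synthetic genotypes and the two-state ROH HMM."""

import numpy as np
import pytest

from rohkin.caller import (
    MISSING,
    GenotypeMatrix,
    GenotypeSimConfig,
    ROHCallerParams,
    call_roh,
    synthesize_genotypes,
)
from rohkin.pedigree import ROHSegment
from rohkin.profiles import bin_profile


def _overlap(a, b):
    return max(0.0, min(a.end_cM, b.end_cM) - max(a.start_cM, b.start_cM))


class TestSynthesize:
    def test_heterozygosity_rate_at_half_frequency(self, one_chrom_genome, rng):
        cfg = GenotypeSimConfig(density_per_cM=60, freq_range=(0.4999, 0.5001))
        gm, _ = synthesize_genotypes(cfg, one_chrom_genome, rng, ["a"])
        het = np.mean(gm.calls[:, 0] == 1)
        n = len(gm.sites)
        assert n >= 10_000
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_planted_segment_has_no_heterozygotes(self, one_chrom_genome, rng):
        seg = ROHSegment("1", 50.0, 90.0)
        cfg = GenotypeSimConfig(error_rate=0.0, planted_roh={"a": [seg]})
        gm, truth = synthesize_genotypes(cfg, one_chrom_genome, rng, ["a"])
        cm = gm.sites["cM"].to_numpy()
        inside = (cm >= 50.0) & (cm < 90.0)
        assert np.all(gm.calls[inside, 0] != 1)
        assert truth.iloc[0]["length_cM"] == pytest.approx(40.0)

    def test_same_seed_identical_matrix(self, one_chrom_genome):
        cfg = GenotypeSimConfig(error_rate=0.01, missing_rate=0.05)
        a, _ = synthesize_genotypes(cfg, one_chrom_genome, np.random.default_rng(3), ["x"])
        b, _ = synthesize_genotypes(cfg, one_chrom_genome, np.random.default_rng(3), ["x"])
        assert np.array_equal(a.calls, b.calls)
        assert a.sites.equals(b.sites)

    def test_overlapping_planted_segments_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            GenotypeSimConfig(
                planted_roh={"a": [ROHSegment("1", 0.0, 10.0), ROHSegment("1", 5.0, 15.0)]}
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GenotypeSimConfig(error_rate=0.5)
        with pytest.raises(ValueError):
            GenotypeSimConfig(density_per_cM=0)


class TestCallROH:
    def test_clean_planted_segment_recovered(self, one_chrom_genome):
        """One 30 cM tract, no error, informative dense markers: exactly one
        call with boundaries within 0.5 cM."""
        seg = ROHSegment("1", 100.0, 130.0)
        cfg = GenotypeSimConfig(
            density_per_cM=50, error_rate=0.0, freq_range=(0.45, 0.55),
            planted_roh={"x": [seg]},
        )
        gm, _ = synthesize_genotypes(cfg, one_chrom_genome, np.random.default_rng(2), ["x"])
        calls = call_roh(gm, "x")
        assert len(calls) == 1
        assert abs(calls[0].start_cM - 100.0) < 0.5
        assert abs(calls[0].end_cM - 130.0) < 0.5

    def test_convergence_to_truth_with_density(self, one_chrom_genome):
        """Boundary error shrinks as marker spacing drops (two densities)."""
        seg = ROHSegment("1", 100.0, 130.0)
        errs = {}
        for dens in (10, 80):
            cfg = GenotypeSimConfig(
                density_per_cM=dens, error_rate=0.0, freq_range=(0.45, 0.55),
                planted_roh={"x": [seg]},
            )
            es = []
            for s in range(6):
                gm, _ = synthesize_genotypes(
                    cfg, one_chrom_genome, np.random.default_rng(s), ["x"]
                )
                c = max(call_roh(gm, "x"), key=lambda u: u.length_cM)
                es.append(abs(c.start_cM - 100.0) + abs(c.end_cM - 130.0))
            errs[dens] = np.mean(es)
        assert errs[80] < errs[10]

    def test_all_heterozygous_input_yields_nothing(self):
        import pandas as pd

        n = 2000
        sites = pd.DataFrame(
            {"chromosome": "1", "bp": np.arange(1, n + 1),
             "cM": np.linspace(0, 100, n), "ref": "A", "alt": "G", "freq": 0.5}
        )
        gm = GenotypeMatrix(sites, ["x"], np.ones((n, 1), dtype=np.int8), "diploid")
        assert call_roh(gm, "x") == []

    def test_pseudo_haploid_input_rejected(self):
        import pandas as pd

        sites = pd.DataFrame(
            {"chromosome": "1", "bp": [1, 2], "cM": [0.0, 1.0],
             "ref": "A", "alt": "G", "freq": 0.5}
        )
        gm = GenotypeMatrix(sites, ["x"], np.zeros((2, 1), dtype=np.int8), "pseudo_haploid")
        with pytest.raises(ValueError, match="diploid"):
            call_roh(gm, "x")

    def test_calls_sorted_non_overlapping_and_feed_bin_profile(self, genome, rng):
        planted = {
            "a": [ROHSegment("1", 20.0, 45.0), ROHSegment("5", 10.0, 28.0)],
        }
        cfg = GenotypeSimConfig(density_per_cM=20, error_rate=0.01, planted_roh=planted)
        gm, _ = synthesize_genotypes(cfg, genome, rng, ["a"])
        calls = call_roh(gm, "a")
        by_chrom: dict[str, list] = {}
        for s in calls:
            by_chrom.setdefault(s.chromosome, []).append(s)
        for ss in by_chrom.values():
            for u, v in zip(ss, ss[1:]):
                assert u.end_cM <= v.start_cM
        prof = bin_profile("a", calls)  # schema compatibility
        assert prof.individual_id == "a"

    def test_unsorted_sites_rejected(self):
        import pandas as pd

        sites = pd.DataFrame(
            {"chromosome": "1", "bp": [1, 2], "cM": [1.0, 0.0],
             "ref": "A", "alt": "G", "freq": 0.5}
        )
        with pytest.raises(ValueError, match="sorted"):
            GenotypeMatrix(sites, ["x"], np.zeros((2, 1), dtype=np.int8))


def make_benchmark(genome, rng, n_individuals=20, n_segments=50):
    """Plant 8-30 cM segments across a cohort; returns (config, individuals)."""
    inds = [f"ind_{k}" for k in range(n_individuals)]
    planted = {i: [] for i in inds}
    chroms = genome.chromosomes
    placed = 0
    while placed < n_segments:
        ind = inds[placed % n_individuals]
        ln = rng.uniform(8, 30)
        c = chroms[int(rng.integers(len(chroms)))]
        start = rng.uniform(0, c.length_cM - ln)
        seg = ROHSegment(c.name, start, start + ln)
        if all(
            not (seg.start_cM < o.end_cM and o.start_cM < seg.end_cM)
            for o in planted[ind]
            if o.chromosome == c.name
        ):
            planted[ind].append(seg)
            placed += 1
    return GenotypeSimConfig(density_per_cM=20, error_rate=0.01, planted_roh=planted), inds


def benchmark_precision_recall(genome, seed=11):
    rng = np.random.default_rng(seed)
    cfg, inds = make_benchmark(genome, rng)
    gm, truth = synthesize_genotypes(cfg, genome, rng, inds)
    called = {i: call_roh(gm, i) for i in inds}
    n_truth = tp = 0
    for row in truth.itertuples(index=False):
        seg = ROHSegment(row.chromosome, row.start_cM, row.end_cM)
        if seg.length_cM < 8:
            continue
        n_truth += 1
        if any(
            _overlap(seg, c) >= 0.5 * seg.length_cM
            for c in called[row.individual_id]
            if c.chromosome == seg.chromosome
        ):
            tp += 1
    n_called = pp = 0
    for ind in inds:
        truth_segs = [
            ROHSegment(r.chromosome, r.start_cM, r.end_cM)
            for r in truth[truth.individual_id == ind].itertuples(index=False)
        ]
        for c in called[ind]:
            if c.length_cM < 8:
                continue
            n_called += 1
            cov = sum(_overlap(c, t) for t in truth_segs if t.chromosome == c.chromosome)
            if cov >= 0.5 * c.length_cM:
                pp += 1
    return tp / n_truth, pp / n_called
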