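"""Gene-dropping simulator: meiosis contracts, conservation oracles, and
the F = per-locus autozygosity probability identity."""

import numpy as np
import pytest

from rohkin.genome import ChromosomeMap
from rohkin.pedigree import (
    LabeledHaplotype,
    PedigreeSpec,
    ROHSegment,
    UnionType,
    crossover_positions,
    meiosis,
    shared_segments,
    simulate_offspring_roh,
)


@pytest.fixture()
def chrom100():
    return ChromosomeMap("1", 100.0)


def _founders(chrom, a=0, b=1):
    return (
        LabeledHaplotype.founder(chrom, a),
        LabeledHaplotype.founder(chrom, b),
    )


class TestMeiosis:
    def test_mean_crossover_count_is_one_per_morgan(self, chrom100, rng):
        n = np.mean(
            [len(crossover_positions(chrom100.length_cM, rng)) for _ in range(10_000)]
        )
        # Poisson(1) 3-SE band; interference only shrinks the variance
        assert 0.94 <= n <= 1.06

    def test_gamete_partitions_chromosome(self, chrom100, rng):
        h1, h2 = _founders(chrom100)
        for _ in range(50):
            g = meiosis(h1, h2, chrom100, rng)
            assert g.bounds[0] == 0.0
            assert g.bounds[-1] == pytest.approx(100.0)
            assert all(b > a for a, b in zip(g.bounds, g.bounds[1:]))
            assert set(g.labels) <= {0, 1}
            # adjacent intervals merged
            assert all(x != y for x, y in zip(g.labels, g.labels[1:]))

    def test_tiny_chromosome_returns_a_parental_copy(self, rng):
        tiny = ChromosomeMap("1", 1e-9)
        h1, h2 = _founders(tiny)
        g = meiosis(h1, h2, tiny, rng)
        assert g.labels in ([0], [1])

    def test_same_seed_gives_identical_gamete(self, chrom100):
        h1, h2 = _founders(chrom100)
        g1 = meiosis(h1, h2, chrom100, np.random.default_rng(99))
        g2 = meiosis(h1, h2, chrom100, np.random.default_rng(99))
        assert g1 == g2

    def test_mismatched_haplotype_rejected(self, chrom100, rng):
        other = ChromosomeMap("2", 50.0)
        h1, h2 = _founders(other)
        with pytest.raises(ValueError, match="span"):
            meiosis(h1, h2, chrom100, rng)


class TestSharedSegments:
    def test_identical_haplotypes_share_everything(self, chrom100):
        h = LabeledHaplotype.founder(chrom100, 7)
        segs = shared_segments(h, h)
        assert len(segs) == 1
        assert segs[0].length_cM == pytest.approx(100.0)

    def test_disjoint_labels_share_nothing(self, chrom100):
        h1, h2 = _founders(chrom100, 0, 1)
        assert shared_segments(h1, h2) == []

    def test_partial_overlap(self):
        h1 = LabeledHaplotype("1", [0.0, 40.0, 100.0], [0, 1])
        h2 = LabeledHaplotype("1", [0.0, 60.0, 100.0], [0, 2])
        segs = shared_segments(h1, h2)
        assert len(segs) == 1
        assert (segs[0].start_cM, segs[0].end_cM) == (0.0, 40.0)


class TestOffspringROH:
    def test_unrelated_union_has_no_roh(self, genome, rng):
        assert simulate_offspring_roh(PedigreeSpec(UnionType.UNRELATED), genome, rng) == []

    @pytest.mark.parametrize(
        "union,f", [(UnionType.FIRST_COUSIN, 1 / 16), (UnionType.SECOND_COUSIN, 1 / 64)]
    )
    def test_inbreeding_coefficient_matches_union(self, union, f):
        assert PedigreeSpec(union).inbreeding_coefficient == f

    def test_segments_within_bounds_and_sorted_per_chromosome(self, genome, rng):
        segs = simulate_offspring_roh(PedigreeSpec(UnionType.FIRST_COUSIN), genome, rng)
        for s in segs:
            assert 0 <= s.start_cM < s.end_cM <= genome[s.chromosome].length_cM + 1e-9

    def test_per_locus_autozygosity_converges_to_F(self, genome):
        """Binomial CI check of P(locus autozygous) = F at three positions."""
        spec = PedigreeSpec(UnionType.FIRST_COUSIN)
        points = [("1", 50.0), ("10", 90.0), ("22", 30.0)]
        n = 3000
        hits = {p: 0 for p in points}
        for child in np.random.SeedSequence(5).spawn(n):
            segs = simulate_offspring_roh(spec, genome, np.random.default_rng(child))
            for chrom, pos in points:
                if any(
                    s.chromosome == chrom and s.start_cM <= pos < s.end_cM for s in segs
                ):
                    hits[(chrom, pos)] += 1
        f = 1 / 16
        se = np.sqrt(f * (1 - f) / n)
        for p, h in hits.items():
            assert abs(h / n - f) < 3 * se, f"autozygosity off at {p}: {h / n}"

    def test_mean_segment_length_near_expected(self, fc_null_small, genome):
        """First-cousin autozygous tracts break at ~6 meioses/Morgan, so the
        mean segment length is near 100/6 cM (finite chromosomes shorten it)."""
        spec = PedigreeSpec(UnionType.FIRST_COUSIN)
        lengths = []
        for child in np.random.SeedSequence(17).spawn(800):
            segs = simulate_offspring_roh(spec, genome, np.random.default_rng(child))
            lengths += [s.length_cM for s in segs]
        assert abs(np.mean(lengths) - 100 / 6) / (100 / 6) < 0.15

    def test_replicate_reproducible_in_isolation(self, genome):
        spec = PedigreeSpec(UnionType.SECOND_COUSIN)

        def replicate_stream():
            # a fresh SeedSequence each time: spawning mutates the parent
            return np.random.default_rng(np.random.SeedSequence(3).spawn(5)[4])

        a = simulate_offspring_roh(spec, genome, replicate_stream())
        b = simulate_offspring_roh(spec, genome, replicate_stream())
        assert [(s.chromosome, s.start_cM, s.end_cM) for s in a] == [
            (s.chromosome, s.start_cM, s.end_cM) for s in b
        ]


def test_roh_segment_validation():
    with pytest.raises(ValueError):
        ROHSegment("1", 5.0, 5.0)
    seg = ROHSegment("1", 1.0, 3.5)
    assert seg.length_cM == pytest.approx(2.5)


def test_labeled_haplotype_validation():
    with pytest.raises(ValueError):
        LabeledHaplotype("1", [0.0, 1.0], [1, 2])
    with pytest.raises(ValueError):
        LabeledHaplotype("1", [0.0, 2.0, 1.0], [1, 2])
    with pytest.raises(ValueError):
        LabeledHaplotype("1", [1.0, 2.0], [1])
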