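"""Pairwise mismatch rates, degree classification and genetic sexing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohkin.kinship import (
    DEGREE_BOUNDARIES,
    PairwiseMismatch,
    call_sex,
    classify_degree,
    estimate_baseline,
    pairwise_mismatch,
    simulate_pair_genotypes,
    tafone_sex_summary,
)


class TestPairwiseMismatch:
    def test_identical_vectors_have_zero_pmr(self, rng):
        gm = simulate_pair_genotypes("unrelated", 30_000, rng)
        gm.calls[:, 1] = gm.calls[:, 0]
        pm = pairwise_mismatch(gm, ("A", "B"))
        assert pm.pmr == 0.0

    def test_unrelated_pair_at_half_frequency(self, rng):
        gm = simulate_pair_genotypes("unrelated", 100_000, rng)
        pm = pairwise_mismatch(gm, ("A", "B"))
        assert pm.pmr == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 100_000))

    def test_duplicate_sampling_gives_half_baseline(self, rng):
        gm = simulate_pair_genotypes("duplicate", 100_000, rng)
        pm = pairwise_mismatch(gm, ("A", "B"))
        assert pm.pmr == pytest.approx(0.25, abs=3 * np.sqrt(0.25 / 100_000))

    def test_symmetric_in_pair(self, rng):
        gm = simulate_pair_genotypes("parent_offspring", 20_000, rng)
        a = pairwise_mismatch(gm, ("A", "B"))
        b = pairwise_mismatch(gm, ("B", "A"))
        assert a.pmr == b.pmr
        assert a.n_overlap == b.n_overlap

    def test_low_overlap_flagged_insufficient(self, rng):
        gm = simulate_pair_genotypes("unrelated", 1000, rng)
        pm = pairwise_mismatch(gm, ("A", "B"))
        assert not pm.sufficient
        assert classify_degree(pm, 0.5) == "insufficient-data"

    def test_diploid_input_rejected(self, one_chrom_genome, rng):
        from rohkin.caller import GenotypeSimConfig, synthesize_genotypes

        gm, _ = synthesize_genotypes(GenotypeSimConfig(), one_chrom_genome, rng, ["a", "b"])
        with pytest.raises(ValueError, match="pseudo-haploid"):
            pairwise_mismatch(gm, ("a", "b"))


class TestClassifyDegree:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.50, "identical"),
            (0.624, "identical"),
            (0.75, "first"),
            (0.875, "second"),
            (1.0, "unrelated-or-more-distant"),
            (1.4, "unrelated-or-more-distant"),
        ],
    )
    def test_expected_ratio_calls(self, ratio, expected):
        pm = PairwiseMismatch(("a", "b"), 50_000, 0.5 * ratio)
        assert classify_degree(pm, 0.5) == expected

    @given(st.floats(min_value=0.0, max_value=3.0, allow_nan=False))
    @settings(max_examples=80, deadline=None)
    def test_boundaries_partition_without_gaps(self, ratio):
        pm = PairwiseMismatch(("a", "b"), 50_000, min(ratio * 0.3, 1.0))
        call = classify_degree(pm, 0.3)
        assert call in (
            "identical", "first", "second", "unrelated-or-more-distant",
        )

    def test_bad_baseline_rejected(self):
        pm = PairwiseMismatch(("a", "b"), 50_000, 0.2)
        with pytest.raises(ValueError):
            classify_degree(pm, 0.0)

    def test_identical_vs_first_confusion_low(self, rng):
        """At 50k overlapping sites the duplicate/first-degree calls are
        separated: confusion < 5% each way."""
        wrong = 0
        n = 40
        for _ in range(n):
            gm = simulate_pair_genotypes("duplicate", 50_000, rng)
            if classify_degree(pairwise_mismatch(gm, ("A", "B")), 0.5) != "identical":
                wrong += 1
            gm = simulate_pair_genotypes("parent_offspring", 50_000, rng)
            if classify_degree(pairwise_mismatch(gm, ("A", "B")), 0.5) != "first":
                wrong += 1
        assert wrong / (2 * n) < 0.05


class TestBaseline:
    def test_median_of_unrelated_pairs(self, rng):
        pms = []
        for _ in range(12):
            gm = simulate_pair_genotypes("unrelated", 20_000, rng)
            pms.append(pairwise_mismatch(gm, ("A", "B")))
        b = estimate_baseline(pms)
        assert b == pytest.approx(0.5, abs=0.01)

    def test_related_pairs_do_not_drag_baseline(self, rng):
        pms = []
        for _ in range(15):
            gm = simulate_pair_genotypes("unrelated", 20_000, rng)
            pms.append(pairwise_mismatch(gm, ("A", "B")))
        for _ in range(6):
            gm = simulate_pair_genotypes("duplicate", 20_000, rng)
            pms.append(pairwise_mismatch(gm, ("A", "B")))
        assert estimate_baseline(pms) == pytest.approx(0.5, abs=0.01)

    def test_too_few_pairs_rejected(self, rng):
        gm = simulate_pair_genotypes("unrelated", 20_000, rng)
        with pytest.raises(ValueError, match=">= 10"):
            estimate_baseline([pairwise_mismatch(gm, ("A", "B"))])


class TestSexing:
    @pytest.mark.parametrize(
        "x,y,expected",
        [(1.0, 0.0, "XX"), (0.5, 0.5, "XY"), (0.7, 0.2, "indeterminate")],
    )
    def test_decision_regions(self, x, y, expected):
        assert call_sex("i", x, y, 1.0).call == expected

    def test_normalization_by_autosomal_rate(self):
        assert call_sex("i", 2.0, 0.0, 2.0).call == "XX"

    def test_zero_autosomal_rate_rejected(self):
        with pytest.raises(ValueError):
            call_sex("i", 1.0, 0.0, 0.0)


class TestTafoneSummary:
    def test_single_mixed_unit(self):
        table, n_multi, n_mixed = tafone_sex_summary(
            {"a": "XX", "b": "XY"}, {"a": "T1", "b": "T1"}
        )
        assert (n_multi, n_mixed) == (1, 1)

    def test_singletons_are_not_multi(self):
        _, n_multi, n_mixed = tafone_sex_summary(
            {"a": "XX", "b": "XY"}, {"a": "T1", "b": "T2"}
        )
        assert (n_multi, n_mixed) == (0, 0)

    def test_synthetic_15_unit_composition(self):
        grouping, calls = {}, {}
        k = 0
        # 5 mixed pairs, 4 same-sex pairs, 6 singletons -> 9 multi, 5 mixed
        for u in range(5):
            for s in ("XX", "XY"):
                calls[f"i{k}"] = s; grouping[f"i{k}"] = f"M{u}"; k += 1
        for u in range(4):
            for _ in range(2):
                calls[f"i{k}"] = "XX"; grouping[f"i{k}"] = f"S{u}"; k += 1
        for u in range(6):
            calls[f"i{k}"] = "XY"; grouping[f"i{k}"] = f"L{u}"; k += 1
        table, n_multi, n_mixed = tafone_sex_summary(calls, grouping)
        assert len(table) == 15
        assert (n_multi, n_mixed) == (9, 5)

    def test_empty_grouping_rejected(self):
        with pytest.raises(ValueError):
            tafone_sex_summary({}, {})
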