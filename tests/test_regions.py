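import numpy as np
import pytest
from scipy.stats import fisher_exact

from cnvburden.intervals import GenomicInterval, overlap_bp
from cnvburden.regions import (
    RegionCandidate,
    TypedFootprint,
    carrier_fisher,
    classify_candidates,
    ds_density_fisher,
    fisher_exact_2x2,
    patient_only_regions,
    shared_regions,
)
from conftest import coverage_mask, make_call


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestPatientOnlyRegions:
    def test_case_call_without_controls_is_kept_whole(self):
        fps = patient_only_regions([make_call(chrom="chr2", start=0, end=300_000)], [])
        assert [f.interval for f in fps] == [iv("chr2", 0, 300_000)]

    def test_control_coverage_is_subtracted(self):
        case = [make_call(chrom="chr2", start=0, end=300_000, cn=3)]
        ctrl = [make_call(sample="c", chrom="chr2", start=100_000, end=200_000, cn=3)]
        fps = patient_only_regions(case, ctrl)
        assert [f.interval for f in fps] == [
            iv("chr2", 0, 100_000),
            iv("chr2", 200_000, 300_000),
        ]

    def test_different_type_control_does_not_subtract(self):
        case = [make_call(chrom="chr2", start=0, end=300_000, cn=3)]
        ctrl = [make_call(sample="c", chrom="chr2", start=100_000, end=200_000, cn=1)]
        fps = patient_only_regions(case, ctrl)
        assert [f.interval for f in fps] == [iv("chr2", 0, 300_000)]

    def test_per_base_parity_with_boolean_oracle(self, rng):
        chroms = ("chr1", "chr2")
        case, ctrl = [], []
        for i in range(40):
            start = int(rng.integers(0, 80_000))
            end = start + int(rng.integers(5_000, 20_000))
            c = make_call(
                sample=f"s{i}",
                chrom=chroms[int(rng.integers(2))],
                start=start,
                end=end,
                cn=int(rng.choice([1, 3])),
            )
            (case if rng.random() < 0.5 else ctrl).append(c)
        fps = patient_only_regions(case, ctrl, min_fragment_bp=1)
        for cnv_type in ("deletion", "duplication"):
            mcase = coverage_mask(
                [c.interval for c in case if c.cnv_type == cnv_type], chroms, 100_000
            )
            mctrl = coverage_mask(
                [c.interval for c in ctrl if c.cnv_type == cnv_type], chroms, 100_000
            )
            mfp = coverage_mask(
                [f.interval for f in fps if f.cnv_type == cnv_type], chroms, 100_000
            )
            for c in chroms:
                assert np.array_equal(mfp[c], mcase[c] & ~mctrl[c])


class TestSharedRegions:
    def test_two_disease_overlap(self):
        fps = {
            "A": [TypedFootprint(iv("chr7", 0, 200_000), "duplication")],
            "B": [TypedFootprint(iv("chr7", 100_000, 300_000), "duplication")],
        }
        (cand,) = shared_regions(fps)
        assert cand.region == iv("chr7", 100_000, 200_000)
        assert cand.span == iv("chr7", 0, 300_000)
        assert cand.diseases == {"A", "B"}
        assert cand.cnv_type == "duplication"

    def test_disjoint_footprints_give_nothing(self):
        fps = {
            "A": [TypedFootprint(iv("chr7", 0, 100_000), "deletion")],
            "B": [TypedFootprint(iv("chr7", 200_000, 300_000), "deletion")],
        }
        assert shared_regions(fps) == []

    def test_mixed_types_flagged(self):
        fps = {
            "A": [TypedFootprint(iv("chr7", 0, 200_000), "deletion")],
            "B": [TypedFootprint(iv("chr7", 100_000, 300_000), "duplication")],
        }
        (cand,) = shared_regions(fps)
        assert cand.cnv_type == "mixed"

    def test_three_disease_fixture_matches_hand_enumeration(self):
        # A: [0,300), B: [100,400), C: [200,500) (kb): >= 2 diseases over
        # [100,400); all three over [200,300)
        fps = {
            "A": [TypedFootprint(iv("chr3", 0, 300_000), "duplication")],
            "B": [TypedFootprint(iv("chr3", 100_000, 400_000), "duplication")],
            "C": [TypedFootprint(iv("chr3", 200_000, 500_000), "duplication")],
        }
        (cand,) = shared_regions(fps)
        assert cand.region == iv("chr3", 100_000, 400_000)
        assert cand.diseases == {"A", "B", "C"}
        (core3,) = [c.region for c in shared_regions(fps, min_diseases=3)]
        assert core3 == iv("chr3", 200_000, 300_000)

    def test_requires_two_diseases(self):
        with pytest.raises(ValueError):
            shared_regions({"A": []})


class TestExactTests:
    def test_empty_region_p_one(self):
        assert ds_density_fisher(0, 0) == 1.0

    def test_identical_odds_p_one(self):
        assert ds_density_fisher(5, 10, 50, 100) == 1.0

    def test_extreme_region_matches_enumeration(self):
        # region 10 DS of 10 vs genome 50:50 overall
        from math import comb

        p = ds_density_fisher(10, 10, 50, 100)
        # hypergeometric: margins r1=10 (region), c1=50 (DS), N=100
        denom = comb(100, 50)
        nums = [comb(10, k) * comb(90, 50 - k) for k in range(0, 11)]
        na = nums[10]
        expect = sum(n for n in nums if n <= na) / denom
        assert p == pytest.approx(expect, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ds_density_fisher(10, 12, 5, 100)

    def test_carrier_worked_example(self):
        # 4 of 380 case carriers vs 0 of 1280 controls
        assert carrier_fisher(4, 380, 0, 1280) == pytest.approx(0.0027, abs=5e-5)

    def test_carrier_trivial_cases(self):
        assert carrier_fisher(0, 100, 0, 100) == 1.0
        assert carrier_fisher(1, 1, 0, 1) == pytest.approx(0.5, abs=1e-12)

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            carrier_fisher(0, 0, 0, 10)

    def test_agrees_with_scipy_on_random_tables(self, rng):
        # independent cross-check of the direct hypergeometric summation
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, 4))
            assert fisher_exact_2x2(a, b, c, d, "two-sided") == pytest.approx(
                fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue,
                abs=1e-10,
            )
            assert fisher_exact_2x2(a, b, c, d, "greater") == pytest.approx(
                fisher_exact([[a, b], [c, d]], alternative="greater").pvalue,
                abs=1e-10,
            )


class TestClassifyCandidates:
    def cand(self, diseases=("A", "B"), n_ds=0, total=None):
        c = RegionCandidate(
            region=iv("chr1", 100_000, 200_000),
            span=iv("chr1", 50_000, 250_000),
            diseases=set(diseases),
            cnv_type="duplication",
        )
        c.ds_genes = [f"g{i}" for i in range(n_ds)]
        c.total_genes = total if total is not None else n_ds
        return c

    def test_reported_and_shared_is_shared(self):
        c = self.cand(n_ds=0, total=2)
        shared, specific = classify_candidates([c], [iv("chr1", 0, 60_000)])
        assert shared == [c] and specific == []

    def test_ds_rich_unreported_single_disease_is_specific(self):
        c = self.cand(diseases=("A",), n_ds=7)
        shared, specific = classify_candidates([c], [])
        assert shared == [] and specific == [c]
        assert c.ds_rich  # "more than six" is strict: 7 qualifies

    def test_six_ds_genes_is_not_ds_rich(self):
        c = self.cand(diseases=("A",), n_ds=6)
        _, specific = classify_candidates([c], [])
        assert not c.ds_rich and specific == []

    def test_unremarkable_candidate_is_in_neither_list(self):
        c = self.cand(diseases=("A",), n_ds=0, total=3)
        shared, specific = classify_candidates(
            [c], [], carrier_counts={id(c): (1, 100, 1, 100)}
        )
        assert shared == [] and specific == []
        assert c.fisher_carrier_p is not None and c.fisher_carrier_p >= 0.05

    def test_carrier_significance_rescues_candidate(self):
        c = self.cand(diseases=("A",), n_ds=0, total=3)
        _, specific = classify_candidates(
            [c], [], carrier_counts={id(c): (8, 100, 0, 400)}
        )
        assert specific == [c]


def test_shared_region_scenario_end_to_end():
    from cnvburden.enrichment import GeneIndex
    from cnvburden.regions import count_carriers, count_region_genes
    from cnvburden.simulate import shared_region_scenario

    sc = shared_region_scenario(3)
    fps = {
        d: patient_only_regions(calls, sc["control_calls"])
        for d, calls in sc["case_calls"].items()
    }
    cands = shared_regions(fps)
    hits = [c for c in cands if overlap_bp(c.region, sc["locus"]) > 0]
    assert len(hits) == 1
    cand = hits[0]
    assert cand.diseases == set(sc["case_calls"])
    index = GeneIndex(sc["genes"])
    count_region_genes(cand, index)
    assert cand.total_genes >= len(cand.ds_genes)
    count_carriers(
        cand,
        {"cases": [c for calls in sc["case_calls"].values() for c in calls],
         "controls": sc["control_calls"]},
    )
    assert cand.carriers["cases"] >= 6  # three planted carriers per disease
    assert cand.carriers["controls"] == 0
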