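"""Consensus haplotype, carrier extents, minimal core, background frequency."""

import numpy as np
import pytest

from conftest import tiny_matrix
from foundertrace.haplotype_io import CarrierSet, focal_carriers
from foundertrace.shared_core import (
    SharedCoreError,
    background_frequency,
    carrier_extent,
    consensus_haplotype,
    match_matrix,
    minimal_core,
    shared_core_analysis,
)
from foundertrace.variants import VariantRecord

FOCAL = VariantRecord("1", 300, "A", "C")  # site index 2 in 5-site fixtures
POSITIONS = [100, 200, 300, 400, 500]


def carrier_set(matrix, haps):
    """CarrierSet over the given (sample, hap) pairs of a tiny matrix."""
    return CarrierSet(haps, FOCAL)


class TestConsensus:
    def test_single_carrier_equals_own_haplotype(self):
        m = tiny_matrix([[1, 0, 1, 1, 0], [0, 0, 0, 0, 0]], POSITIONS)
        cons = consensus_haplotype(m, carrier_set(m, [("s1", 0)]))
        assert cons.alleles.tolist() == [1, 0, 1, 1, 0]
        assert cons.support.tolist() == [1] * 5

    def test_majority_vote(self):
        m = tiny_matrix(
            [
                [1, 1, 1, 1, 1], [0] * 5,
                [1, 1, 1, 1, 1], [0] * 5,
                [0, 1, 1, 1, 1], [0] * 5,
            ],
            POSITIONS,
        )
        cs = carrier_set(m, [("s1", 0), ("s2", 0), ("s3", 0)])
        cons = consensus_haplotype(m, cs)
        assert cons.alleles[0] == 1  # (1,1,0) -> majority 1
        assert cons.support[0] == 2

    def test_tie_broken_toward_first_sorted_carrier(self):
        m = tiny_matrix(
            [[0, 1, 1, 1, 1], [0] * 5, [1, 1, 1, 1, 1], [0] * 5],
            POSITIONS,
            samples=["b", "a"],
        )
        # Tie at site 0; first carrier in sample-ID sort order is "a" (allele 1).
        cons = consensus_haplotype(m, carrier_set(m, [("b", 0), ("a", 0)]))
        assert cons.alleles[0] == 1

    def test_empty_carriers_error(self):
        m = tiny_matrix([[1, 0, 1, 1, 0], [0] * 5], POSITIONS)
        with pytest.raises(SharedCoreError):
            consensus_haplotype(m, carrier_set(m, []))

    def test_consensus_equals_founder_inside_truth_intersection(
        self, small_cohort
    ):
        config, matrix, truth = small_cohort
        cs = focal_carriers(matrix, config.focal)
        cons = consensus_haplotype(matrix, cs)
        lo, hi = truth.segment_intersection()
        inside = (matrix.positions >= lo) & (matrix.positions <= hi)
        np.testing.assert_array_equal(
            cons.alleles[inside], truth.founder_alleles[inside]
        )


class TestCarrierExtent:
    def fixture_matrix(self, carrier_alleles):
        rows = [carrier_alleles, [0] * 5, [1, 1, 1, 1, 1], [0] * 5]
        return tiny_matrix(rows, POSITIONS)

    def test_identical_to_consensus_spans_region(self):
        m = self.fixture_matrix([1, 1, 1, 1, 1])
        cs = carrier_set(m, [("s1", 0), ("s2", 0)])
        cons = consensus_haplotype(m, cs)
        ext = carrier_extent(m, ("s1", 0), cons, focal_index=2)
        assert (ext.left_pos, ext.right_pos, ext.n_sites) == (100, 500, 5)

    def test_tolerance_zero_stops_at_first_mismatch(self):
        m = self.fixture_matrix([1, 0, 1, 1, 1])
        cs = carrier_set(m, [("s2", 0)])  # consensus = all ones
        cons = consensus_haplotype(m, cs)
        ext = carrier_extent(m, ("s1", 0), cons, 2, mismatch_tolerance=0)
        assert (ext.left_pos, ext.right_pos) == (300, 500)
        assert ext.n_sites == 3

    def test_tolerance_one_bridges_the_mismatch(self):
        m = self.fixture_matrix([1, 0, 1, 1, 1])
        cons = consensus_haplotype(m, carrier_set(m, [("s2", 0)]))
        ext = carrier_extent(m, ("s1", 0), cons, 2, mismatch_tolerance=1)
        assert (ext.left_pos, ext.right_pos) == (100, 500)
        assert ext.n_sites == 4  # the tolerated mismatch is not a match

    def test_boundary_is_outermost_matched_site(self):
        # Leftmost site mismatches: tolerated but trimmed from the extent.
        m = self.fixture_matrix([0, 1, 1, 1, 1])
        cons = consensus_haplotype(m, carrier_set(m, [("s2", 0)]))
        ext = carrier_extent(m, ("s1", 0), cons, 2, mismatch_tolerance=1)
        assert ext.left_pos == 200

    def test_extent_contains_truth_intersection_on_simulation(self, small_cohort):
        # Inside the intersection of all true ancestral segments every
        # carrier carries founder alleles, so the consensus equals the
        # founder there and no extent can stop before its edge.  (A single
        # carrier's own segment is NOT guaranteed to be contained: outside
        # the intersection the majority consensus can disagree with the
        # founder once most other segments have ended.)
        config, matrix, truth = small_cohort
        cs = focal_carriers(matrix, config.focal)
        analysis = shared_core_analysis(matrix, cs, mismatch_tolerance=0)
        positions = matrix.positions
        lo, hi = truth.segment_intersection()
        inside = positions[(positions >= lo) & (positions <= hi)]
        for ext in analysis.extents:
            assert ext.left_pos <= inside.min()
            assert ext.right_pos >= inside.max()


class TestMinimalCore:
    def test_interval_intersection(self):
        m = tiny_matrix([[1] * 5, [0] * 5], POSITIONS)
        cons = consensus_haplotype(m, carrier_set(m, [("s1", 0)]))
        # Extents [100,500],[200,400],[100,400] intersect to [200,400].
        from foundertrace.shared_core import ExtentInterval

        exts = [
            ExtentInterval("a", 100, 500, 5, 0, 4),
            ExtentInterval("b", 200, 400, 3, 1, 3),
            ExtentInterval("c", 100, 400, 4, 0, 3),
        ]
        core = minimal_core(exts, cons)
        assert core.core_interval == (200, 400)
        assert core.core_alleles.tolist() == [1, 1, 1]

    def test_single_carrier_core_is_extent(self):
        m = tiny_matrix([[1] * 5, [0] * 5], POSITIONS)
        cons = consensus_haplotype(m, carrier_set(m, [("s1", 0)]))
        ext = carrier_extent(m, ("s1", 0), cons, 2)
        core = minimal_core([ext], cons)
        assert core.core_interval == (ext.left_pos, ext.right_pos)

    def test_adding_carrier_never_enlarges_core(self, small_cohort):
        config, matrix, truth = small_cohort
        cs = focal_carriers(matrix, config.focal)
        for k in range(2, len(cs) + 1):
            sub = CarrierSet(cs.carriers[:k], cs.focal)
            prev = CarrierSet(cs.carriers[: k - 1], cs.focal)
            core_k = shared_core_analysis(matrix, sub).core
            core_p = shared_core_analysis(matrix, prev).core
            assert core_p.core_left <= core_k.core_left
            assert core_p.core_right >= core_k.core_right


class TestBackgroundFrequency:
    def test_exact_copy_in_background(self):
        # 1 carrier + 3 background samples; one background haplotype copies
        # the carrier's core alleles.
        rows = [
            [1, 1, 1, 1, 1], [0] * 5,  # carrier
            [1, 1, 1, 1, 1], [0] * 5,  # bg s2 hap0 matches
            [0, 1, 0, 1, 0], [0] * 5,
            [1, 0, 1, 0, 1], [0] * 5,
        ]
        m = tiny_matrix(rows, POSITIONS)
        cs = carrier_set(m, [("s1", 0)])
        cons = consensus_haplotype(m, cs)
        ext = carrier_extent(m, ("s1", 0), cons, 2)
        core = background_frequency(m, minimal_core([ext], cons), cs)
        assert core.background_total == 6
        assert core.background_matches == 1
        assert core.frequency_text == "1 in 6"

    def test_single_site_core_matches_allele_frequency(self):
        rng = np.random.default_rng(0)
        n_bg = 400
        rows = [[1], [0]] + [[int(rng.random() < 0.5)] for _ in range(2 * n_bg)]
        m = tiny_matrix(rows, [300])
        cs = carrier_set(m, [("s1", 0)])
        cons = consensus_haplotype(m, cs)
        core = background_frequency(
            m, minimal_core([carrier_extent(m, ("s1", 0), cons, 0)], cons), cs
        )
        assert core.background_matches / core.background_total == pytest.approx(
            0.5, abs=0.08
        )

    def test_matches_monotone_in_core_extension(self, small_cohort):
        config, matrix, truth = small_cohort
        cs = focal_carriers(matrix, config.focal)
        analysis = shared_core_analysis(matrix, cs)
        cons, core = analysis.consensus, analysis.core
        carrier_samples = set(cs.sample_ids)
        rows = np.array(
            [
                2 * i + k
                for i, s in enumerate(matrix.samples)
                if s not in carrier_samples
                for k in (0, 1)
            ]
        )
        focal_j = analysis.focal_index
        prev = None
        for width in range(0, 15):
            idx = np.arange(
                max(0, focal_j - width), min(matrix.n_sites, focal_j + width + 1)
            )
            sub = matrix.alleles[np.ix_(rows, idx)]
            n = int(np.all(sub == cons.alleles[idx], axis=1).sum())
            if prev is not None:
                assert n <= prev
            prev = n

    def test_counting_oracle_on_simulation(self, small_cohort):
        config, matrix, truth = small_cohort
        cs = focal_carriers(matrix, config.focal)
        analysis = shared_core_analysis(matrix, cs)
        core = analysis.core
        # Brute-force recount over explicit haplotype loops.
        carriers = set(cs.sample_ids)
        count = 0
        total = 0
        for i, s in enumerate(matrix.samples):
            if s in carriers:
                continue
            for k in (0, 1):
                total += 1
                hap = matrix.haplotype(i, k)
                if all(
                    hap[j] == core.core_alleles[jj]
                    for jj, j in enumerate(core.core_site_indices)
                ):
                    count += 1
        assert (count, total) == (core.background_matches, core.background_total)


def test_match_matrix_rows_align_with_extents(small_cohort):
    config, matrix, truth = small_cohort
    cs = focal_carriers(matrix, config.focal)
    analysis = shared_core_analysis(matrix, cs)
    mm = match_matrix(matrix, cs, analysis.consensus)
    assert mm.shape == (len(cs), matrix.n_sites)
    for row, ext in zip(mm, analysis.extents):
        assert row[ext.left_index] == 1 and row[ext.right_index] == 1
        assert row[ext.left_index : ext.right_index + 1].sum() == ext.n_sites
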