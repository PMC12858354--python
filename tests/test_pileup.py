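"""CIGAR simplification, pileup construction, masking, and segmentation."""

import numpy as np
import pytest

from lorespl import pileup, simulate
from lorespl.pileup import (Pileup, aligned_fraction, build_pileup, coverage_mask,
                            filter_regions, region_counts, segment_regions,
                            simplify_cigar)

from conftest import make_alignment, make_header


def ref_span(segs):
    return sum(l for _, l in segs)


class TestSimplifyCigar:
    def test_clean_spliced_cigar_unchanged(self):
        assert simplify_cigar([("M", 50), ("N", 100), ("M", 50)]) == \
            [("M", 50), ("N", 100), ("M", 50)]

    def test_insertions_are_ignored(self):
        assert simplify_cigar([("M", 20), ("I", 5), ("M", 30)]) == [("M", 50)]

    def test_short_deletion_merges_into_preceding_match(self):
        assert simplify_cigar([("M", 20), ("D", 5), ("M", 30)]) == [("M", 55)]

    def test_long_deletion_survives(self):
        assert simplify_cigar([("M", 20), ("D", 12), ("M", 30)]) == \
            [("M", 20), ("D", 12), ("M", 30)]

    def test_leading_short_segment_merges_forward(self):
        assert simplify_cigar([("D", 4), ("M", 30)]) == [("M", 34)]

    def test_empty_cigar_rejected(self):
        with pytest.raises(ValueError):
            simplify_cigar([])

    def test_reference_span_preserved_on_random_cigars(self):
        """Simplification must never change the reference span (merges eat
        short segments but keep their reference length)."""
        rng = np.random.default_rng(4)
        ops = ["M", "D", "N", "I"]
        for _ in range(200):
            cigar = []
            for _ in range(rng.integers(1, 12)):
                op = ops[rng.integers(0, 4)]
                cigar.append((op, int(rng.integers(1, 60))))
            if all(op == "I" for op, _ in cigar):
                cigar.append(("M", 25))
            before = sum(l for op, l in cigar if op in "MDN")
            segs = simplify_cigar(cigar)
            assert ref_span(segs) == before
            assert all(l >= 1 for _, l in segs)
            # adjacent segments never share a type
            assert all(a[0] != b[0] for a, b in zip(segs, segs[1:]))


class TestAlignedFraction:
    @pytest.mark.parametrize("cigar,expected", [
        ("90M10S", 0.9),
        ("50M50S", 0.5),
        ("100M", 1.0),
        ("40M20I40M20S", 100 / 120),
    ])
    def test_fraction_values(self, cigar, expected):
        assert aligned_fraction(make_alignment(cigar)) == pytest.approx(expected)

    def test_exact_eighty_percent_is_excluded(self):
        """The filter keeps reads with fraction strictly above 0.8."""
        a = make_alignment("80M20S", pos=0)
        pile = build_pileup([a], "chrS", 1000)
        assert pile.spanning.sum() == 0  # read dropped entirely


class TestBuildPileup:
    def test_single_spliced_read_contributions(self):
        a = make_alignment("50M100N50M", pos=0)
        pile = build_pileup([a], "chrS", 1000)
        # terminal M segments are ignored; the N interval spans only
        assert (pile.included == 0).all()
        assert (pile.spanning[50:150] == 1).all()
        assert pile.spanning[:50].sum() == 0 and pile.spanning[150:].sum() == 0

    def test_interior_match_counts_included_and_spanning(self):
        a = make_alignment("30M100N40M100N30M", pos=0)
        pile = build_pileup([a], "chrS", 1000)
        assert (pile.included[130:170] == 1).all()
        assert (pile.spanning[30:270] == 1).all()
        assert pile.included.sum() == 40
        assert pile.spanning.sum() == 240

    def test_matches_per_base_brute_force_recount(self):
        """Pileup equals an independent per-base walk that re-applies the
        short-merge, insertion-drop, aligned-fraction and terminal-segment
        rules position by position."""
        rng = np.random.default_rng(14)
        header = make_header()
        length = 3000
        alignments = []
        for i in range(100):
            parts = []
            for j in range(rng.integers(1, 8)):
                op = "MIDNS"[rng.integers(0, 5)]
                parts.append(f"{rng.integers(1, 80)}{op}")
            cigar = f"{rng.integers(10, 50)}M" + "".join(parts) + f"{rng.integers(10, 50)}M"
            alignments.append(make_alignment(cigar, pos=int(rng.integers(0, 1500)),
                                             read_id=f"r{i}", header=header))
        got = build_pileup(alignments, "chrS", length)

        included = np.zeros(length, int)
        spanning = np.zeros(length, int)
        for a in alignments:
            ops = pileup.cigartuples_to_ops(a.cigartuples)
            aligned = sum(l for o, l in ops if o in "MI")
            total = sum(l for o, l in ops if o in "MIS")
            if not aligned / total > 0.8:
                continue
            segs = simplify_cigar(ops)
            pos = a.reference_start
            coords = []
            for op, l in segs:
                coords.append((op, pos, pos + l))
                pos += l
            for op, s, e in coords[1:-1]:
                for p in range(max(s, 0), min(e, length)):
                    spanning[p] += 1
                    if op == "M":
                        included[p] += 1
        assert (got.included == included).all()
        assert (got.spanning == spanning).all()


class TestCoverageMask:
    def make(self, spans):
        piles = []
        for s in spans:
            p = Pileup.zeros("chrS", 1, "x")
            p.spanning[0] = s
            piles.append(p)
        return coverage_mask(piles)

    def test_low_single_sample_excludes(self):
        assert self.make([4, 30, 30])[0]

    def test_low_mean_excludes(self):
        assert self.make([10, 10, 10])[0]

    def test_sufficient_coverage_retained(self):
        assert not self.make([20, 20, 20])[0]


def track_pileup(psi_values, coverage=100):
    """Pileup with deterministic included counts from a PSI track."""
    n = len(psi_values)
    p = Pileup.zeros("chrS", n, "pooled")
    p.spanning[:] = coverage
    p.included[:] = np.round(np.asarray(psi_values) * coverage).astype(int)
    return p


class TestSegmentRegions:
    def test_step_track_splits_at_boundary(self):
        p = track_pileup([1.0] * 100 + [0.0] * 100)
        regions = segment_regions(p)
        assert [(r.start, r.end) for r in regions] == [(0, 100), (100, 200)]

    def test_constant_track_is_one_region(self):
        p = track_pileup([0.5] * 300)
        regions = segment_regions(p)
        assert [(r.start, r.end) for r in regions] == [(0, 300)]

    def test_small_noise_rarely_splits(self):
        """PSI 0.8 with +-0.05 uniform noise over 500 positions stays a
        single region in >= 95% of seeded trials."""
        single = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            psi = 0.8 + rng.uniform(-0.05, 0.05, 500)
            p = Pileup.zeros("chrS", 500, "pooled")
            p.spanning[:] = 1000
            p.included[:] = np.round(psi * 1000).astype(int)
            if len(segment_regions(p)) == 1:
                single += 1
        assert single >= 95

    def test_masked_positions_skipped_without_split(self):
        p = track_pileup([0.5] * 100)
        excluded = np.zeros(100, bool)
        excluded[40:60] = True
        regions = segment_regions(p, excluded)
        assert len(regions) == 1
        assert len(regions[0].positions) == 80

    def test_rerunning_on_output_reproduces_boundaries(self):
        rng = np.random.default_rng(3)
        psi = np.concatenate([np.full(80, 0.9), np.full(60, 0.2), np.full(90, 0.85)])
        psi = np.clip(psi + rng.normal(0, 0.02, psi.size), 0, 1)
        p = track_pileup(psi, coverage=500)
        first = segment_regions(p)
        again = segment_regions(p)
        assert [(r.start, r.end) for r in first] == [(r.start, r.end) for r in again]
        # segmentation partitions the usable positions
        all_pos = np.concatenate([r.positions for r in first])
        assert np.array_equal(np.sort(all_pos), np.arange(psi.size))


class TestRegionCountsAndFilter:
    def test_constant_region_counts(self):
        p = Pileup.zeros("chrS", 50, "s1")
        p.included[:] = 10
        p.spanning[:] = 20
        region = pileup.Region("chrS", 0, 50, np.arange(50))
        rc = region_counts(region, [p])
        assert rc.iloc[0]["retained_avg"] == 10
        assert rc.iloc[0]["total_avg"] == 20

    def test_rounding_half_away_from_zero(self):
        p = Pileup.zeros("chrS", 5, "s1")
        p.included[:] = [10, 11, 11, 10, 11]  # mean 10.6
        p.spanning[:] = [21, 21, 21, 21, 22]  # mean 21.2
        region = pileup.Region("chrS", 0, 5, np.arange(5))
        rc = region_counts(region, [p])
        assert rc.iloc[0]["retained_avg"] == 11
        assert rc.iloc[0]["total_avg"] == 21

    def test_region_filter_psi_thresholds(self):
        def pile_with_psi(psi):
            p = Pileup.zeros("chrS", 10, "s")
            p.spanning[:] = 100
            p.included[:] = int(psi * 100)
            return p

        region = pileup.Region("chrS", 0, 10, np.arange(10))
        low = [pile_with_psi(0.01), pile_with_psi(0.02), pile_with_psi(0.04)]
        assert filter_regions([region], low) == []
        rescued = [pile_with_psi(0.04), pile_with_psi(0.9)]
        assert filter_regions([region], rescued) == [region]
        boundary = [pile_with_psi(0.05)]
        assert filter_regions([region], boundary) == [region]  # strict "less than"
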