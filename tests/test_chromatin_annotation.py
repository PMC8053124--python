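import numpy as np
import pytest

from rearescan.chromatin_annotation import (
    associate_genes,
    containment_interval,
    distance_to_nearest,
    pairs_under_peaks,
    peak_set_algebra,
    percentage_with_pairs,
)
from rearescan.genome_io import Peak, TSSRecord
from rearescan.motif_engine import MotifHit
from rearescan.pair_finder import pair_nearest


def make_pair(re_iv, are_iv, chrom="chr1"):
    re_h = MotifHit(chrom, *re_iv, "+", "RE")
    are_h = MotifHit(chrom, *are_iv, "+", "ARE")
    (pair,) = pair_nearest([re_h], [are_h])
    return pair


class TestContainmentInterval:
    def test_reported_range(self):
        assert containment_interval(Peak("c", 1000, 1400)) == (1000, 1400)

    def test_center_window(self):
        assert containment_interval(
            Peak("c", 1000, 1400), mode="center_window", half_width=300
        ) == (900, 1500)

    def test_width_one_peak_center_window(self):
        lo, hi = containment_interval(
            Peak("c", 500, 501), mode="center_window", half_width=300
        )
        assert (lo, hi) == (200, 800) and hi - lo == 600


class TestPairsUnderPeaks:
    def test_full_containment_required(self):
        peak = Peak("chr1", 1000, 1400)
        inside = make_pair((1050, 1070), (1200, 1209))
        straddling = make_pair((990, 1010), (1200, 1209))
        annotated, counts = pairs_under_peaks([inside, straddling], [peak])
        assert counts["peaks_with_pairs"] == 1
        assert counts["pairs_under_any_peak"] == 1
        (ann,) = annotated
        assert ann.contained_pairs == [inside]

    def test_single_motif_peak_reported(self):
        peak = Peak("chr1", 1000, 1400)
        pair = make_pair((1050, 1070), (2000, 2009))  # ARE outside
        annotated, counts = pairs_under_peaks(
            [pair], [peak], hits=[pair.re_hit, pair.are_hit]
        )
        assert counts["peaks_with_pairs"] == 0
        assert counts["peaks_single_motif_only"] == 1
        (ann,) = annotated
        assert [h.start for h in ann.single_motif_hits] == [1050]

    def test_pair_under_two_overlapping_peaks_counted_per_peak_once_total(self):
        peaks = [Peak("chr1", 1000, 1400), Peak("chr1", 1040, 1500)]
        pair = make_pair((1050, 1070), (1200, 1209))
        annotated, counts = pairs_under_peaks([pair], peaks)
        assert counts["pair_assignments"] == 2
        assert counts["pairs_under_any_peak"] == 1

    def test_center_window_mode_extends_reach(self):
        peak = Peak("chr1", 1000, 1100)
        pair = make_pair((1150, 1170), (1200, 1209))  # outside reported range
        _, strict = pairs_under_peaks([pair], [peak], mode="reported_range")
        _, wide = pairs_under_peaks([pair], [peak], mode="center_window",
                                    half_width=300)
        assert strict["peaks_with_pairs"] == 0
        assert wide["peaks_with_pairs"] == 1

    def test_random_fixtures_match_generator_bookkeeping(self):
        """Constructed peak/pair worlds: containment counts equal truth."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 15))
            pairs, peaks, truly_covered = [], [], 0
            cursor = 0
            for i in range(n):
                cursor += int(rng.integers(100, 400))
                pair = make_pair((cursor, cursor + 20), (cursor + 50, cursor + 59))
                pairs.append(pair)
                covered = bool(rng.integers(0, 2))
                if covered:
                    peaks.append(Peak("chr1", cursor - 10, cursor + 70))
                    truly_covered += 1
                else:
                    # a peak too short to contain the whole pair
                    peaks.append(Peak("chr1", cursor - 10, cursor + 30))
                cursor += 100
            _, counts = pairs_under_peaks(pairs, peaks)
            assert counts["peaks_with_pairs"] == truly_covered
            assert counts["pairs_under_any_peak"] == truly_covered


class TestPercentages:
    def test_fraction_of_all_peaks(self):
        peaks = [Peak("chr1", i * 1000, i * 1000 + 300, "H3K27ac", "KP")
                 for i in range(12)]
        pairs = [make_pair((i * 1000 + 50, i * 1000 + 70),
                           (i * 1000 + 100, i * 1000 + 109)) for i in range(3)]
        annotated, _ = pairs_under_peaks(pairs, peaks)
        pct = percentage_with_pairs(annotated, peaks)
        assert pct[("H3K27ac", "KP")] == pytest.approx(25.0)

    def test_zero_and_full(self):
        peaks = [Peak("chr1", 0, 500, "H3K27ac", "DK")]
        assert percentage_with_pairs([], peaks)[("H3K27ac", "DK")] == 0.0
        pair = make_pair((10, 30), (100, 109))
        annotated, _ = pairs_under_peaks([pair], peaks)
        assert percentage_with_pairs(annotated, peaks)[("H3K27ac", "DK")] == 100.0

    def test_no_peaks_rejected(self):
        with pytest.raises(ValueError):
            percentage_with_pairs([], [])


class TestPeakSetAlgebra:
    def annotate(self, peaks, pairs):
        annotated, _ = pairs_under_peaks(pairs, peaks)
        return annotated

    def test_overlap_makes_common(self):
        pair_a = make_pair((110, 130), (150, 159))
        pair_b = make_pair((160, 180), (200, 209))
        a = self.annotate([Peak("chr1", 100, 200, state="KP")], [pair_a])
        b = self.annotate([Peak("chr1", 150, 250, state="DK")], [pair_b])
        part = peak_set_algebra(a, b)
        assert part.counts() == {"unique_a": 0, "unique_b": 0, "common_a": 1, "common_b": 1}

    def test_bookended_half_open_are_unique(self):
        pair_a = make_pair((110, 130), (150, 159))
        pair_b = make_pair((210, 230), (250, 259))
        a = self.annotate([Peak("chr1", 100, 200)], [pair_a])
        b = self.annotate([Peak("chr1", 200, 300)], [pair_b])
        part = peak_set_algebra(a, b)
        assert part.counts() == {"unique_a": 1, "unique_b": 1, "common_a": 0, "common_b": 0}

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(11)
        pairs_a, pairs_b, peaks_a, peaks_b = [], [], [], []
        cursor = 0
        for _ in range(30):
            cursor += int(rng.integers(50, 300))
            pair = make_pair((cursor + 10, cursor + 30), (cursor + 50, cursor + 59))
            peak = Peak("chr1", cursor, cursor + 80)
            if rng.integers(0, 2):
                pairs_a.append(pair); peaks_a.append(peak)
            else:
                pairs_b.append(pair); peaks_b.append(peak)
            cursor += 100
        a = self.annotate(peaks_a, pairs_a)
        b = self.annotate(peaks_b, pairs_b)
        part = peak_set_algebra(a, b)
        c = part.counts()
        assert c["unique_a"] + c["common_a"] == len([x for x in a if x.has_pair])
        assert c["unique_b"] + c["common_b"] == len([x for x in b if x.has_pair])


class TestDistanceToNearest:
    def tss(self, pos, chrom="chr1", fid="g"):
        return TSSRecord(fid, chrom, pos, "+", "gene")

    def test_point_to_span_gap(self):
        pair = make_pair((600, 620), (660, 669))  # span [600, 669)
        sample, unmatched = distance_to_nearest([self.tss(500)], [pair])
        assert sample.values.tolist() == [100] and unmatched == []

    def test_point_inside_span_is_zero(self):
        pair = make_pair((600, 620), (660, 669))
        sample, _ = distance_to_nearest([self.tss(650)], [pair])
        assert sample.values.tolist() == [0]

    def test_minimum_over_targets(self):
        near = make_pair((600, 620), (660, 669))
        far = make_pair((1100, 1120), (1160, 1169))
        sample, _ = distance_to_nearest([self.tss(1000)], [near, far])
        assert sample.values.tolist() == [100]  # 1100-1000 beats 1000-668

    def test_pair_to_nearest_tss_direction(self):
        pair = make_pair((600, 620), (660, 669))
        sample, _ = distance_to_nearest([pair], [self.tss(500), self.tss(800)])
        assert sample.values.tolist() == [100]

    def test_unmatched_chromosome_reported(self):
        pair = make_pair((600, 620), (660, 669))
        orphan = self.tss(100, chrom="chrX")
        sample, unmatched = distance_to_nearest([self.tss(500), orphan], [pair])
        assert sample.n == 1 and unmatched == [orphan]

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(9)
        pairs = []
        for s in rng.integers(0, 100_000, 150):
            pairs.append(make_pair((int(s), int(s) + 20), (int(s) + 40, int(s) + 49)))
        queries = [self.tss(int(p)) for p in rng.integers(0, 100_000, 150)]
        sample, _ = distance_to_nearest(queries, pairs)
        for q, got in zip(queries, sample.values):
            best = min(
                0 if p.span_start <= q.position < p.span_end
                else (p.span_start - q.position if q.position < p.span_start
                      else q.position - (p.span_end - 1))
                for p in pairs
            )
            assert got == best


class TestAssociateGenes:
    def annotated_peak(self, n_pairs=1, center=5000):
        half = 200
        peak = Peak("chr1", center - half, center + half)
        pairs = []
        for k in range(n_pairs):
            base = center - half + 10 + 60 * k
            pairs.append(make_pair((base, base + 20), (base + 30, base + 39)))
        annotated, _ = pairs_under_peaks(pairs, [peak])
        return annotated

    def test_boundary_inside_100kb(self):
        annotated = self.annotated_peak()
        tss = [TSSRecord("g1", "chr1", 104_999, "+", "gene")]
        table = associate_genes(annotated, tss, max_dist=100_000)
        assert table.feature_id.tolist() == ["g1"]
        assert table.distance.tolist() == [99_999]

    def test_boundary_outside_100kb(self):
        annotated = self.annotated_peak()
        tss = [TSSRecord("g1", "chr1", 105_001, "+", "gene")]
        table = associate_genes(annotated, tss, max_dist=100_000)
        assert table.feature_id.tolist() == ["unassigned"]

    def test_duplicate_assignment_per_contained_pair(self):
        annotated = self.annotated_peak(n_pairs=2)
        tss = [TSSRecord("g1", "chr1", 6000, "+", "gene")]
        table = associate_genes(annotated, tss)
        assert table.feature_id.tolist() == ["g1", "g1"]
        no_dup = associate_genes(annotated, tss, duplicate_per_pair=False)
        assert no_dup.feature_id.tolist() == ["g1"]

    def test_signed_distance_and_closest_selection(self):
        annotated = self.annotated_peak()
        tss = [
            TSSRecord("left", "chr1", 4000, "+", "gene"),
            TSSRecord("right", "chr1", 5600, "-", "gene"),
        ]
        table = associate_genes(annotated, tss)
        assert table.feature_id.tolist() == ["right"]
        assert table.distance.tolist() == [600]

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            associate_genes(self.annotated_peak(), [])
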