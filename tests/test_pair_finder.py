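import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rearescan.genome_io import ChromosomeRecord
from rearescan.motif_engine import MotifHit
from rearescan.pair_finder import (
    export_pair_sequences,
    flag_steric,
    pair_nearest,
    read_pairs_table,
    spacer,
)
from rearescan.genome_io import write_tables


def hit(start, end, chrom="chr1", strand="+", name="RE"):
    return MotifHit(chrom, start, end, strand, name)


class TestSpacer:
    @pytest.mark.parametrize(
        "re_iv,are_iv,expected,orientation",
        [
            ((100, 120), (150, 159), 30, "RE_upstream"),
            ((100, 120), (110, 119), -10, "overlapping"),
            ((200, 220), (100, 109), 91, "ARE_upstream"),
        ],
    )
    def test_inner_gap(self, re_iv, are_iv, expected, orientation):
        re_h, are_h = hit(*re_iv), hit(*are_iv, name="ARE")
        assert spacer(re_h, are_h) == expected
        pairs = pair_nearest([re_h], [are_h])
        assert pairs[0].orientation == orientation

    def test_symmetry(self):
        a, b = hit(10, 30), hit(100, 109, name="ARE")
        assert spacer(a, b) == spacer(b, a)

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError, match="different chromosomes"):
            spacer(hit(0, 10, chrom="chr1"), hit(0, 10, chrom="chr2"))

    @settings(max_examples=50, deadline=None)
    @given(
        s1=st.integers(0, 1000), w1=st.integers(1, 50),
        s2=st.integers(0, 1000), w2=st.integers(1, 50),
    )
    def test_symmetry_property(self, s1, w1, s2, w2):
        a, b = hit(s1, s1 + w1), hit(s2, s2 + w2, name="ARE")
        assert spacer(a, b) == spacer(b, a)


class TestPairNearest:
    def test_nearest_by_absolute_spacer(self):
        re_h = hit(100, 120)
        ares = [hit(10, 19, name="ARE"), hit(150, 159, name="ARE")]
        (pair,) = pair_nearest([re_h], ares)
        assert pair.are_hit.start == 150 and pair.spacer_n == 30

    def test_many_to_one_sharing(self):
        res = [hit(100, 120), hit(300, 320)]
        are = [hit(200, 209, name="ARE")]
        pairs = pair_nearest(res, are)
        assert len(pairs) == 2
        assert all(p.are_hit.start == 200 for p in pairs)

    def test_equidistant_tie_goes_to_lower_coordinate(self):
        re_h = hit(100, 120)
        ares = [hit(50, 60, name="ARE"), hit(160, 170, name="ARE")]  # both gap 40
        (pair,) = pair_nearest([re_h], ares)
        assert pair.are_hit.start == 50

    def test_empty_re_list(self):
        assert pair_nearest([], [hit(0, 9, name="ARE")]) == []

    def test_no_are_on_chromosome_skipped(self):
        pairs = pair_nearest([hit(0, 10)], [hit(0, 9, chrom="chr2", name="ARE")])
        assert pairs == []

    def test_max_window_restricts(self):
        re_h = hit(100, 120)
        ares = [hit(5000, 5009, name="ARE")]
        assert pair_nearest([re_h], ares, max_window=2000) == []
        assert len(pair_nearest([re_h], ares, max_window=6000)) == 1

    def test_one_to_one_mode_never_reuses_ares(self):
        res = [hit(100, 110), hit(130, 140), hit(400, 410)]
        ares = [hit(115, 124, name="ARE"), hit(200, 209, name="ARE")]
        pairs = pair_nearest(res, ares, one_to_one=True)
        used = [p.are_hit.start for p in pairs]
        assert len(used) == len(set(used)) == 2

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_agrees_with_all_pairs_brute_force(self, seed):
        """Nearest pairing equals an exhaustive |spacer| minimizer."""
        rng = np.random.default_rng(seed)
        n_re, n_are = rng.integers(1, 40, 2)
        res = [hit(int(s), int(s) + 20) for s in rng.integers(0, 5000, n_re)]
        ares = [hit(int(s), int(s) + 9, name="ARE") for s in rng.integers(0, 5000, n_are)]
        pairs = {p.re_hit.start: p for p in pair_nearest(res, ares)}
        for re_h in res:
            gaps = [(abs(spacer(re_h, a)), a.start) for a in ares]
            best = min(gaps)
            assert pairs[re_h.start].are_hit.start == best[1]


class TestFlagSteric:
    @pytest.mark.parametrize("gap,ok", [(8, True), (7, False), (-3, False)])
    def test_strict_threshold_boundary(self, gap, ok):
        re_h = hit(100, 120)
        are_h = hit(120 + gap, 129 + gap, name="ARE")
        (pair,) = pair_nearest([re_h], [are_h])
        assert pair.spacer_n == gap
        feasible, infeasible = flag_steric([pair])
        assert (len(feasible) == 1) is ok
        target = (feasible or infeasible)[0]
        assert target.steric_ok is ok


class TestExportSequences:
    @pytest.fixture
    def small_world(self):
        genome = [ChromosomeRecord("chr1", "ACGT" * 100)]
        re_h, are_h = hit(100, 120), hit(150, 159, name="ARE")
        (pair,) = pair_nearest([re_h], [are_h])
        return genome, pair

    def test_span_without_flank(self, small_world):
        genome, pair = small_world
        (rec,) = export_pair_sequences([pair], genome, flank=0)
        assert len(rec.seq) == 59
        assert str(rec.seq) == genome[0].sequence[100:159]

    def test_flank_extends(self, small_world):
        genome, pair = small_world
        (rec,) = export_pair_sequences([pair], genome, flank=20)
        assert len(rec.seq) == 99

    def test_edge_clipping_warns(self, small_world, caplog):
        genome, pair = small_world
        with caplog.at_level("WARNING"):
            (rec,) = export_pair_sequences([pair], genome, flank=300)
        assert len(rec.seq) == 400  # clipped to the chromosome
        assert "clipped" in caplog.text

    def test_unknown_chromosome(self, small_world):
        _, pair = small_world
        with pytest.raises(KeyError):
            export_pair_sequences([pair], [ChromosomeRecord("chrX", "ACGT")])


def test_pairs_table_round_trip(tmp_path):
    res = [hit(100, 120), hit(300, 320)]
    ares = [hit(140, 149, name="ARE"), hit(200, 209, name="ARE")]
    pairs = pair_nearest(res, ares)
    out = tmp_path / "pairs.tsv"
    write_tables(pairs, out, fmt="tsv")
    back = read_pairs_table(out)
    assert [(p.re_hit.start, p.are_hit.start, p.spacer_n, p.orientation, p.steric_ok)
            for p in back] == [
        (p.re_hit.start, p.are_hit.start, p.spacer_n, p.orientation, p.steric_ok)
        for p in pairs
    ]
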