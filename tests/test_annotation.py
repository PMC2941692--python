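"""BED/WIG parsing, projection, SNP phasing, proximity, colors."""

import io
import math

import numpy as np
import pytest

from nucleome3d.annotation import (BedInterval, ColorRule, WigTrack,
                                   colorize, parse_bed, parse_wig,
                                   project, proximity_classify,
                                   snp_phase_report, write_bed, write_wig)
from nucleome3d.builder import place_nucleosomes
from nucleome3d.errors import ValidationError
from fixture_helpers import small_fiber as _small_fiber


class TestParseBed:
    def test_minimal_interval(self):
        out = parse_bed(io.StringIO("chr1\t0\t100\tfeat\n"))
        assert len(out) == 1
        assert len(out[0]) == 100
        assert out[0].name == "feat"

    def test_track_and_browser_lines_skipped(self):
        text = ("track name=test description=x\n"
                "browser position chr1:1-100\n"
                "chr1\t10\t20\n")
        out = parse_bed(io.StringIO(text))
        assert len(out) == 1

    def test_empty_interval_rejected_with_line_number(self):
        with pytest.raises(ValidationError, match="line 1"):
            parse_bed(io.StringIO("chr1\t100\t100\n"))

    def test_non_integer_coordinates_rejected(self):
        with pytest.raises(ValidationError, match="line 2"):
            parse_bed(io.StringIO("chr1\t0\t10\nchr1\tx\t20\n"))

    def test_six_columns(self):
        out = parse_bed(io.StringIO("chr1\t0\t10\tf\t3.5\t-\n"))
        assert out[0].score == 3.5 and out[0].strand == "-"


class TestParseWig:
    def test_fixedstep_one_based_conversion(self):
        text = "fixedStep chrom=chr1 start=1 step=1\n1.0\n2.0\n3.0\n"
        tracks = parse_wig(io.StringIO(text))
        assert len(tracks) == 1
        assert tracks[0].positions == [0, 1, 2]
        assert tracks[0].values == [1.0, 2.0, 3.0]

    def test_variablestep_span_semantics(self):
        text = "variableStep chrom=chr1 span=5\n11 1.5\n31 2.5\n"
        (t,) = parse_wig(io.StringIO(text))
        assert list(t.intervals()) == [(10, 15, 1.5), (30, 35, 2.5)]

    def test_empty_stream(self):
        assert parse_wig(io.StringIO("")) == []

    def test_value_before_declaration_rejected(self):
        with pytest.raises(ValidationError, match="declaration"):
            parse_wig(io.StringIO("1.0\n"))

    def test_non_numeric_value_rejected_with_line(self):
        text = "fixedStep chrom=chr1 start=1 step=1\nnope\n"
        with pytest.raises(ValidationError, match="line 2"):
            parse_wig(io.StringIO(text))

    def test_bedgraph_autodetected(self):
        text = "chr1\t0\t10\t2.5\nchr1\t10\t20\t3.5\n"
        (t,) = parse_wig(io.StringIO(text))
        assert t.mode == "bedGraph"
        assert list(t.intervals()) == [(0, 10, 2.5), (10, 20, 3.5)]


class TestRoundTrips:
    def test_bed_write_parse_identity(self):
        ivs = [BedInterval("chr1", 0, 100, "a", 2.0, "+"),
               BedInterval("chr2", 5, 6, "b")]
        buf = io.StringIO()
        write_bed(ivs, buf)
        buf.seek(0)
        back = parse_bed(buf)
        assert [(i.chrom, i.start, i.end, i.name) for i in back] == \
               [(i.chrom, i.start, i.end, i.name) for i in ivs]

    def test_wig_write_parse_identity(self):
        t = WigTrack("chr1", "variableStep", 5, [10, 30], [1.5, -2.0])
        buf = io.StringIO()
        write_wig([t], buf)
        buf.seek(0)
        (back,) = parse_wig(buf)
        assert back.positions == t.positions
        assert back.values == t.values
        assert back.span == t.span


class TestProjection:
    def test_coverage_conservation(self, model_100k):
        ivs = [BedInterval("chrA", 500, 1_500)]
        ann = project(ivs, model_100k, "chrA", "nucleosome", "coverage")
        assert sum(ann.values.values()) == 1_000

    def test_exact_wrap_coverage(self, model_100k):
        r = model_100k.chromosomes["chrA"].nucleosomes[2]
        ivs = [BedInterval("chrA", r.start_bp, r.end_bp)]
        ann = project(ivs, model_100k, "chrA", "nucleosome", "coverage")
        assert ann.values == {("nuc", 2): 147.0}

    def test_overlapping_intervals_add_under_sum(self, model_100k):
        ivs = [BedInterval("chrA", 0, 100, score=2.0),
               BedInterval("chrA", 50, 100, score=3.0)]
        ann = project(ivs, model_100k, "chrA", "nucleosome", "sum")
        assert ann.values[("nuc", 0)] == 2.0 * 100 + 3.0 * 50

    def test_projection_reexpansion_oracle(self, model_100k):
        # brute-force per-bp assignment must agree with interval clipping
        ivs = [BedInterval("chrA", 130, 420), BedInterval("chrA", 350, 360)]
        ann = project(ivs, model_100k, "chrA", "nucleosome", "coverage")
        from nucleome3d.builder import map_bp_to_scale
        expected = {}
        for iv in ivs:
            for bp in range(iv.start, iv.end):
                idx, elem = map_bp_to_scale(model_100k, "chrA", bp,
                                            "nucleosome")
                eid = (("nuc", idx) if idx is not None
                       else ("linker", elem.prev_index
                             if elem.prev_index is not None else -1))
                expected[eid] = expected.get(eid, 0) + 1
        assert {k: int(v) for k, v in ann.values.items()} == expected

    def test_wig_projection(self, model_100k):
        t = WigTrack("chrA", "fixedStep", 1, [0, 1, 2], [1.0, 2.0, 3.0])
        ann = project(t, model_100k, "chrA", "nucleosome", "sum")
        assert ann.values[("nuc", 0)] == 6.0

    def test_mean_aggregation(self, model_100k):
        ivs = [BedInterval("chrA", 0, 50, score=4.0)]
        ann = project(ivs, model_100k, "chrA", "nucleosome", "mean")
        assert ann.values[("nuc", 0)] == 4.0

    def test_fiber_scale_projection(self, model_100k):
        ivs = [BedInterval("chrA", 0, 2_400)]
        ann = project(ivs, model_100k, "chrA", "fiber", "coverage")
        assert sum(ann.values.values()) == 2_400

    def test_unknown_aggregation_rejected(self, model_100k):
        with pytest.raises(ValidationError):
            project([], model_100k, "chrA", "nucleosome", "median")


class TestSnpPhasing:
    def _records(self):
        records, _ = place_nucleosomes(_small_fiber(7_700_000),
                                       positions=[7_602_871])
        return records

    def test_first_wrapped_bp_has_zero_phase(self):
        recs = self._records()
        snp = BedInterval("chr20", 7_602_871, 7_602_872, "rs0")
        (row,) = snp_phase_report([snp], recs)
        assert row.record_index == 0
        assert row.offset_bp == 0
        assert row.phase_deg == 0.0

    def test_four_snps_share_the_record(self):
        # four variants inside the 147 bp wrap, as in the demonstration
        recs = self._records()
        snps = [BedInterval("chr20", p, p + 1, f"rs{i}")
                for i, p in enumerate([7_602_880, 7_602_910, 7_602_950,
                                       7_603_000])]
        rows = snp_phase_report(snps, recs)
        assert len(rows) == 4
        assert {r.record_index for r in rows} == {0}
        assert all(0.0 <= r.phase_deg < 360.0 for r in rows)
        # axial positions span the superhelix height
        assert all(abs(r.axial_nm) <= 1.65 * 2.39 / 2 + 1e-9 for r in rows)

    def test_linker_snp_designated_with_nearest_record(self):
        recs = self._records()
        snp = BedInterval("chr20", 100, 101, "far")
        (row,) = snp_phase_report([snp], recs)
        assert row.in_linker
        assert row.record_index is None
        assert row.nearest_index == 0

    def test_multi_bp_interval_rejected(self):
        recs = self._records()
        with pytest.raises(ValidationError, match="single-bp"):
            snp_phase_report([BedInterval("chr20", 0, 2)], recs)


class TestProximity:
    def _tss(self, *positions):
        return [BedInterval("chr19", p, p + 1, f"g{p}") for p in positions]

    def test_distance_5000_is_near(self):
        sites = [BedInterval("chr19", 14_990, 15_010)]
        (row,) = proximity_classify(sites, self._tss(20_000))
        assert row.distance_bp == 5_000 and row.near

    def test_distance_10000_is_far_boundary_strict(self):
        sites = [BedInterval("chr19", 9_990, 10_010)]
        (row,) = proximity_classify(sites, self._tss(20_000))
        assert row.distance_bp == 10_000 and not row.near

    def test_site_at_tss_is_near_at_zero(self):
        sites = [BedInterval("chr19", 19_990, 20_010)]
        (row,) = proximity_classify(sites, self._tss(20_000))
        assert row.distance_bp == 0 and row.near

    def test_no_tss_gives_infinite_far(self):
        sites = [BedInterval("chr19", 0, 20)]
        (row,) = proximity_classify(sites, [])
        assert math.isinf(row.distance_bp) and not row.near

    def test_nearest_of_many_tss_wins(self):
        sites = [BedInterval("chr19", 49_990, 50_010)]
        (row,) = proximity_classify(sites, self._tss(10_000, 52_000,
                                                     90_000))
        assert row.distance_bp == 2_000 and row.near


class TestColorize:
    def test_zero_maps_to_neutral(self):
        rule = ColorRule()
        (c,) = colorize([0.0], rule)
        assert c == rule.neutral

    def test_signed_symmetry(self):
        rule = ColorRule()
        pos, neg = colorize([2.0, -2.0], rule)
        assert pos == rule.positive
        assert neg == rule.negative

    def test_saturation_monotone_in_magnitude(self):
        rule = ColorRule()
        colors = colorize([0.5, 1.0, 2.0], rule)
        # distance from neutral grows with |value|
        d = [np.linalg.norm(np.array(c) - np.array(rule.neutral))
             for c in colors]
        assert d[0] < d[1] < d[2]

    def test_all_zero_signed_is_all_neutral(self):
        rule = ColorRule()
        assert colorize([0.0, 0.0], rule) == [rule.neutral, rule.neutral]

    def test_dict_interface(self):
        out = colorize({("nuc", 0): 1.0, ("nuc", 1): -1.0}, ColorRule())
        assert set(out) == {("nuc", 0), ("nuc", 1)}

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            colorize([float("nan")])
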