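"""Nuclear walk, fiber, nucleosome placement and DNA synthesis."""

import math

import numpy as np
import pytest

from nucleome3d.builder import (BuilderConfig, GenomicRange, LinkerLocation,
                                NuclearParams, build_fiber_path,
                                build_genome_model, build_nuclear_walk,
                                map_bp_to_scale, place_nucleosomes,
                                synthesize_dna)
from nucleome3d.errors import GenomicRangeError, ValidationError
from fixture_helpers import small_fiber as _small_fiber


class TestNuclearWalk:
    def test_single_loop_closes_exactly(self):
        # 3 Mbp chromosome, 3 Mbp loops, 30 kbp steps -> one 100-step loop
        path = build_nuclear_walk(3_000_000, NuclearParams(seed=2))
        assert len(path.loop_boundaries) == 1
        a, b = path.loop_boundaries[0]
        assert b - a == 100
        assert np.linalg.norm(path.points[a] - path.points[b]) < 1e-6

    def test_step_lengths_are_constant(self):
        path = build_nuclear_walk(3_000_000, NuclearParams(seed=2))
        steps = np.linalg.norm(np.diff(path.points, axis=0), axis=1)
        np.testing.assert_allclose(steps, 150.0, atol=1e-6)

    def test_same_seed_is_bitwise_identical(self):
        a = build_nuclear_walk(2_000_000, NuclearParams(seed=9))
        b = build_nuclear_walk(2_000_000, NuclearParams(seed=9))
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.bp_anchors, b.bp_anchors)

    def test_different_seeds_differ(self):
        a = build_nuclear_walk(2_000_000, NuclearParams(seed=1))
        b = build_nuclear_walk(2_000_000, NuclearParams(seed=2))
        assert not np.allclose(a.points, b.points)

    def test_confinement(self):
        params = NuclearParams(seed=4, nucleus_radius_nm=2_000.0)
        path = build_nuclear_walk(9_000_000, params)
        assert np.all(np.linalg.norm(path.points, axis=1) <= 2_000.0)

    def test_bp_anchors_strictly_increasing(self):
        path = build_nuclear_walk(3_050_000, NuclearParams(seed=3))
        assert np.all(np.diff(path.bp_anchors) > 0)
        assert path.bp_anchors[-1] == 3_050_000

    def test_rejects_subthreshold_chromosome(self):
        with pytest.raises(ValidationError):
            build_nuclear_walk(10_000, NuclearParams())

    def test_unconfined_open_walk_recovers_ideal_chain_msd(self):
        # <R^2> = N b^2 for an ideal chain; Monte-Carlo at modest size
        params = NuclearParams(nucleus_radius_nm=math.inf, close_loops=False,
                               step_bp=30_000, step_length_nm=1.0)
        n_steps, reps = 300, 100
        r2 = []
        for seed in range(reps):
            p = build_nuclear_walk(n_steps * 30_000,
                                   NuclearParams(nucleus_radius_nm=math.inf,
                                                 close_loops=False,
                                                 step_length_nm=1.0,
                                                 seed=seed))
            r2.append(np.sum((p.points[-1] - p.points[0]) ** 2))
        r2 = np.array(r2)
        se = r2.std(ddof=1) / math.sqrt(reps)
        assert abs(r2.mean() - n_steps) <= 3 * se


class TestFiberPath:
    def test_points_per_nuclear_step(self):
        nuclear = build_nuclear_walk(3_000_000, NuclearParams(seed=2))
        fiber = build_fiber_path(nuclear, 1_200, jitter_nm=0.0)
        # 30000/1200 = 25 fiber intervals per nuclear step
        assert np.all(np.diff(fiber.bp_anchors)[:-1] == 1_200)
        assert len(fiber) == 3_000_000 // 1_200 + 1

    def test_zero_jitter_lies_on_nuclear_polyline(self):
        nuclear = build_nuclear_walk(3_000_000, NuclearParams(seed=2))
        fiber = build_fiber_path(nuclear, 1_200, jitter_nm=0.0)
        # nuclear anchor points appear exactly on the fiber
        for i in range(0, len(nuclear), 7):
            j = np.searchsorted(fiber.bp_anchors, nuclear.bp_anchors[i])
            np.testing.assert_allclose(fiber.points[j], nuclear.points[i],
                                       atol=1e-9)

    def test_same_seed_identical(self):
        nuclear = build_nuclear_walk(3_000_000, NuclearParams(seed=2))
        a = build_fiber_path(nuclear, 1_200, jitter_nm=4.0, seed=5)
        b = build_fiber_path(nuclear, 1_200, jitter_nm=4.0, seed=5)
        assert np.array_equal(a.points, b.points)

    def test_covers_chromosome_without_gaps(self):
        nuclear = build_nuclear_walk(3_010_000, NuclearParams(seed=2))
        fiber = build_fiber_path(nuclear, 1_200, jitter_nm=2.0, seed=1)
        assert fiber.bp_anchors[0] == 0
        assert fiber.bp_anchors[-1] == 3_010_000
        assert np.all(np.diff(fiber.bp_anchors) > 0)

    def test_rejects_bp_per_point_not_below_step(self):
        nuclear = build_nuclear_walk(3_000_000, NuclearParams(seed=2))
        with pytest.raises(ValidationError):
            build_fiber_path(nuclear, 30_000)


class TestPlaceNucleosomes:
    def test_default_tiling_conserves_bp(self):
        records, leading = place_nucleosomes(_small_fiber(2_000))
        assert len(records) == 10
        assert leading == 0
        assert sum(r.wrap_bp + r.linker_bp_after for r in records) == 2_000
        assert all(r.linker_bp_after == 53 for r in records)

    def test_remainder_goes_to_last_linker(self):
        records, _ = place_nucleosomes(_small_fiber(2_070))
        assert len(records) == 10
        assert records[-1].linker_bp_after == 53 + 70
        assert sum(r.wrap_bp + r.linker_bp_after for r in records) == 2_070

    def test_explicit_single_position(self):
        # the demonstration nucleosome at chr20:7602872-7603018 (1-based)
        # is start 7,602,871 0-based and spans 147 bp
        fiber = _small_fiber(7_700_000)
        records, leading = place_nucleosomes(fiber, positions=[7_602_871])
        assert len(records) == 1
        assert records[0].start_bp == 7_602_871
        assert records[0].end_bp - records[0].start_bp == 147
        assert leading == 7_602_871
        assert (leading + records[0].wrap_bp
                + records[0].linker_bp_after) == 7_700_000

    def test_overlapping_positions_listed_in_error(self):
        with pytest.raises(ValidationError, match="100"):
            place_nucleosomes(_small_fiber(2_000), positions=[100, 150])

    def test_frames_are_valid_and_near_fiber(self):
        fiber = _small_fiber(2_000)
        records, _ = place_nucleosomes(fiber)
        for r in records:
            r.frame.validate()
        origins = np.array([r.frame.origin for r in records])
        mids = np.array([r.start_bp + 73.5 for r in records]) * 0.01
        assert np.all(np.abs(origins[:, 2] - mids) < 15.0)

    def test_solenoid_rotates_successive_nucleosomes(self):
        records, _ = place_nucleosomes(_small_fiber(2_000),
                                       nucleosomes_per_turn=6.0)
        # 6 per turn: records 0 and 6 share e1, 0 and 3 oppose
        np.testing.assert_allclose(records[0].frame.e1, records[6].frame.e1,
                                   atol=1e-9)
        np.testing.assert_allclose(records[0].frame.e1,
                                   -records[3].frame.e1, atol=1e-9)


class TestSynthesizeDna:
    def test_atom_count(self, model_100k):
        seg = synthesize_dna(model_100k, GenomicRange("chrA", 0, 100))
        assert len(seg.frames) == 100
        assert len(seg.atoms) == 2_000

    def test_chunked_queries_concatenate_identically(self, model_100k):
        a = synthesize_dna(model_100k, GenomicRange("chrA", 0, 500),
                           with_atoms=False)
        b = synthesize_dna(model_100k, GenomicRange("chrA", 500, 1_000),
                           with_atoms=False)
        whole = synthesize_dna(model_100k, GenomicRange("chrA", 0, 1_000),
                               with_atoms=False)
        for x, y in zip(a.frames + b.frames, whole.frames):
            assert np.allclose(x.origin, y.origin, atol=1e-9)
            assert np.allclose(x.rotation, y.rotation, atol=1e-9)

    def test_wrap_centroid_matches_record_origin(self, model_100k):
        chrom = model_100k.chromosomes["chrA"]
        r = chrom.nucleosomes[3]
        seg = synthesize_dna(model_100k,
                             GenomicRange("chrA", r.start_bp, r.end_bp),
                             with_atoms=False)
        centroid = np.mean([f.origin for f in seg.frames], axis=0)
        assert np.linalg.norm(centroid - r.frame.origin) <= 0.5

    def test_rejects_out_of_range(self, model_100k):
        with pytest.raises(GenomicRangeError):
            synthesize_dna(model_100k, GenomicRange("chrA", 0, 200_000))
        with pytest.raises(GenomicRangeError):
            synthesize_dna(model_100k, GenomicRange("chrB", 0, 100))

    def test_linker_frames_bridge_wraps_continuously(self, model_100k):
        seg = synthesize_dna(model_100k, GenomicRange("chrA", 0, 400),
                             with_atoms=False)
        origins = np.array([f.origin for f in seg.frames])
        gaps = np.linalg.norm(np.diff(origins, axis=0), axis=1)
        # no bp-to-bp jump larger than a few nm anywhere in the path
        assert gaps.max() < 5.0


class TestMapBpToScale:
    def test_bp0_maps_to_first_element_at_every_scale(self, model_100k):
        for scale in ("nuclear", "fiber", "nucleosome"):
            idx, _ = map_bp_to_scale(model_100k, "chrA", 0, scale)
            assert idx == 0

    def test_wrapped_bp_returns_record(self, model_100k):
        idx, rec = map_bp_to_scale(model_100k, "chrA", 400, "nucleosome")
        assert idx == 2
        assert rec.start_bp == 400

    def test_linker_bp_returns_linker_designation(self, model_100k):
        idx, loc = map_bp_to_scale(model_100k, "chrA", 150, "nucleosome")
        assert idx is None
        assert isinstance(loc, LinkerLocation)
        assert loc.prev_index == 0 and loc.next_index == 1

    def test_out_of_range_bp_rejected(self, model_100k):
        with pytest.raises(GenomicRangeError):
            map_bp_to_scale(model_100k, "chrA", 100_000, "fiber")


class TestGenomeModel:
    def test_bp_conservation_on_random_lengths(self):
        rng = np.random.default_rng(0)
        lengths = {f"c{i}": int(rng.integers(60_000, 200_000))
                   for i in range(3)}
        model = build_genome_model(lengths, BuilderConfig(seed=1))
        for chrom in model.chromosomes.values():
            chrom.validate_bp_conservation()

    def test_seed_determinism(self):
        a = build_genome_model({"c": 100_000}, BuilderConfig(seed=42))
        b = build_genome_model({"c": 100_000}, BuilderConfig(seed=42))
        ca, cb = a.chromosomes["c"], b.chromosomes["c"]
        assert np.array_equal(ca.nuclear.points, cb.nuclear.points)
        assert np.array_equal(ca.fiber.points, cb.fiber.points)
        assert all(np.array_equal(x.frame.origin, y.frame.origin)
                   for x, y in zip(ca.nucleosomes, cb.nucleosomes))

    def test_cross_scale_fiber_nucleosome_consistency(self, model_100k):
        chrom = model_100k.chromosomes["chrA"]
        from nucleome3d.builder import position_at_bp
        origins = np.array([r.frame.origin for r in chrom.nucleosomes])
        mids = np.array([r.start_bp + 73.5 for r in chrom.nucleosomes])
        fiber_pos = position_at_bp(chrom, mids, "fiber")
        d = np.linalg.norm(origins - fiber_pos, axis=1)
        assert np.all(d <= 15.0 + 3 * 3.0)  # solenoid radius + jitter slack
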