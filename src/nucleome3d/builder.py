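"""Construction of the four-scale genome hierarchy.

A chromosome is modelled at four scales:

nuclear
    A giant-loop random walk: Mbp-scale closed loops (equilateral random
    polygons, exact closure and exact step length) attached to a coarse
    backbone walk, confined to the nuclear sphere.
fiber
    The 30 nm chromatin fiber: the nuclear polyline subdivided by bp
    with seeded isotropic jitter.
nucleosome
    Core particles placed along the fiber — 147 bp wraps plus linkers,
    arranged as a solenoid (default 6 per turn) around the fiber axis.
DNA
    Per-bp frames and pseudo-atoms, synthesised on demand from the
    nucleosome records and never stored.

Only the first three scales are ever materialised in a
:class:`GenomeModel`; :func:`synthesize_dna` derives the fourth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import geometry as geom
from .errors import GenomicRangeError, ValidationError
from .geometry import (Atom, AtomTemplate, Frame, HelixParams,
                       SuperhelixParams, default_atom_template)

__all__ = [
    "NuclearParams",
    "NuclearPath",
    "FiberPath",
    "NucleosomeRecord",
    "ChromosomeModel",
    "GenomeModel",
    "GenomicRange",
    "BuilderConfig",
    "LinkerLocation",
    "DnaSegment",
    "build_nuclear_walk",
    "build_fiber_path",
    "place_nucleosomes",
    "build_genome_model",
    "synthesize_dna",
    "map_bp_to_scale",
    "position_at_bp",
    "read_lengths_table",
    "models_equal",
]

WRAP_BP = 147

SCALES = ("nuclear", "fiber", "nucleosome")


@dataclass(frozen=True)
class NuclearParams:
    """Giant-loop random-walk parameters.

    loop_size_bp
        Genomic size of one closed giant loop (3 Mbp default).
    step_bp / step_length_nm
        Genomic and spatial size of one walk step (30 kbp, 150 nm).
    nucleus_radius_nm
        Confinement sphere radius (5 um). ``inf`` disables confinement.
    close_loops
        When False the walk is a plain open random walk (used for
        ideal-chain statistics checks).
    """

    loop_size_bp: int = 3_000_000
    step_bp: int = 30_000
    step_length_nm: float = 150.0
    nucleus_radius_nm: float = 5_000.0
    seed: int = 0
    close_loops: bool = True
    max_retries: int = 500

    def __post_init__(self):
        if not (self.loop_size_bp >= self.step_bp > 0):
            raise ValidationError("need loop_size_bp >= step_bp > 0")
        if self.step_length_nm <= 0:
            raise ValidationError("step_length_nm must be > 0")
        if self.nucleus_radius_nm <= self.step_length_nm:
            raise ValidationError("nucleus_radius_nm must exceed step_length_nm")


@dataclass
class NuclearPath:
    points: np.ndarray          # (n, 3) nm
    bp_anchors: np.ndarray      # (n,) int, strictly increasing
    loop_boundaries: List[Tuple[int, int]]  # (start_idx, end_idx) closed loops
    seed: int

    def __len__(self):
        return len(self.points)


@dataclass
class FiberPath:
    points: np.ndarray
    bp_anchors: np.ndarray
    bp_per_point: int

    def __len__(self):
        return len(self.points)


@dataclass(frozen=True)
class NucleosomeRecord:
    """One placed core particle.

    ``frame.origin`` is the centroid of the 147 wrapped bp positions;
    ``frame.e3`` is the superhelix (cylinder) axis.  The cylinder-axis
    anchor used to regenerate the wrap is recovered from the frame via
    the fixed in-frame centroid offset of the superhelix parameters.
    """

    start_bp: int
    frame: Frame
    linker_bp_after: int
    wrap_bp: int = WRAP_BP

    def __post_init__(self):
        if self.start_bp < 0:
            raise ValidationError("start_bp must be >= 0")
        if self.wrap_bp != WRAP_BP:
            raise ValidationError(f"wrap_bp must be {WRAP_BP}")
        if self.linker_bp_after < 0:
            raise ValidationError("linker_bp_after must be >= 0")

    @property
    def end_bp(self) -> int:
        """End of the wrap (half-open)."""
        return self.start_bp + self.wrap_bp

    @property
    def span_end_bp(self) -> int:
        """End of wrap + downstream linker (half-open)."""
        return self.end_bp + self.linker_bp_after


@dataclass
class ChromosomeModel:
    name: str
    length_bp: int
    nuclear: NuclearPath
    fiber: FiberPath
    nucleosomes: List[NucleosomeRecord]
    leading_bp: int = 0  # linker bp before the first record

    def validate_bp_conservation(self) -> None:
        total = self.leading_bp + sum(r.wrap_bp + r.linker_bp_after
                                      for r in self.nucleosomes)
        if total != self.length_bp:
            raise ValidationError(
                f"{self.name}: bp not conserved ({total} != {self.length_bp})")


@dataclass(frozen=True)
class BuilderConfig:
    """All scale parameters plus the master seed, bundled.

    Per-chromosome seeds are derived deterministically from ``seed`` so
    a (manifest, seed) pair fixes the model bitwise.
    """

    nuclear: NuclearParams = field(default_factory=NuclearParams)
    bp_per_fiber_point: int = 1_200
    fiber_jitter_nm: float = 3.0
    fiber_radius_nm: float = 15.0
    nucleosome_repeat_bp: int = 200
    nucleosomes_per_turn: float = 6.0
    solenoid_radius_nm: float = 8.0
    superhelix: SuperhelixParams = field(default_factory=SuperhelixParams)
    helix: HelixParams = field(default_factory=HelixParams)
    seed: int = 0

    def __post_init__(self):
        if self.bp_per_fiber_point >= self.nuclear.step_bp:
            raise ValidationError("bp_per_fiber_point must be < nuclear step_bp")
        if self.nucleosome_repeat_bp < WRAP_BP:
            raise ValidationError("nucleosome_repeat_bp must be >= 147")


@dataclass
class GenomeModel:
    name: str
    config: BuilderConfig
    chromosomes: Dict[str, ChromosomeModel]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {n: c.length_bp for n, c in self.chromosomes.items()}

    def chromosome(self, name: str) -> ChromosomeModel:
        try:
            return self.chromosomes[name]
        except KeyError:
            raise GenomicRangeError(f"unknown chromosome {name!r}") from None


@dataclass(frozen=True)
class GenomicRange:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise GenomicRangeError(
                f"invalid range {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)")

    def __len__(self):
        return self.end - self.start


@dataclass(frozen=True)
class LinkerLocation:
    """A bp that falls between nucleosome wraps at nucleosome scale."""

    prev_index: Optional[int]   # record before the linker (None = leading)
    next_index: Optional[int]   # record after the linker (None = trailing)
    start_bp: int
    end_bp: int


@dataclass
class DnaSegment:
    """On-demand DNA-scale synthesis result for a genomic range."""

    grange: GenomicRange
    frames: List[Frame]
    atoms: List[Atom]


# --------------------------------------------------------------------------
# nuclear scale


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _random_units(rng, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1)[:, None]


def _closed_loop_steps(k: int, rng) -> np.ndarray:
    """k unit steps summing exactly to zero (closed equilateral polygon).

    Built from shuffled antipodal pairs, plus one planar 120-degree
    triple when k is odd; closure and unit length are exact.
    """
    if k < 3:
        raise ValidationError("a closed loop needs >= 3 steps")
    steps = []
    if k % 2 == 1:
        # three unit vectors at 120 degrees in a random plane
        a = _random_units(rng, 1)[0]
        b = _random_units(rng, 1)[0]
        b = b - np.dot(a, b) * a
        b /= np.linalg.norm(b)
        for ang in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            steps.append(np.cos(ang) * a + np.sin(ang) * b)
        k -= 3
    pairs = _random_units(rng, k // 2)
    for u in pairs:
        steps.append(u)
        steps.append(-u)
    steps = np.array(steps)
    rng.shuffle(steps)
    return steps


def _inside(p: np.ndarray, radius: float) -> bool:
    return bool(np.all(np.linalg.norm(np.atleast_2d(p), axis=1) <= radius))


def build_nuclear_walk(chrom_length_bp: int,
                       params: NuclearParams = NuclearParams()) -> NuclearPath:
    """Giant-loop random walk for one chromosome.

    The chromosome's ``ceil(length / step_bp)`` steps are grouped into
    closed loops of ``loop_size_bp / step_bp`` steps anchored on a
    backbone; one backbone step separates consecutive loops.  All points
    stay inside the nucleus sphere (whole-loop rejection with bounded
    retries, then rigid reflection through the anchor).
    """
    if chrom_length_bp < params.step_bp:
        raise ValidationError("chrom_length_bp must be >= step_bp")
    rng = _rng(params.seed)
    b = params.step_length_nm
    R = params.nucleus_radius_nm
    confined = math.isfinite(R)
    n_steps = math.ceil(chrom_length_bp / params.step_bp)
    loop_steps = max(3, params.loop_size_bp // params.step_bp)

    if confined:
        # start near the centre so typical loops fit without rejection
        start_r = max(0.1 * R, R - 3.0 * b * math.sqrt(loop_steps))
        start_r = min(start_r, 0.8 * R)
        p0 = _random_units(rng, 1)[0] * (start_r * rng.random() ** (1 / 3))
    else:
        p0 = np.zeros(3)

    pts = [p0]
    loop_boundaries: List[Tuple[int, int]] = []
    done = 0
    while done < n_steps:
        anchor = pts[-1]
        k = min(loop_steps, n_steps - done)
        if params.close_loops and k >= 3:
            start_idx = len(pts) - 1
            for attempt in range(params.max_retries):
                steps = _closed_loop_steps(k, rng) * b
                loop_pts = anchor + np.cumsum(steps, axis=0)
                if not confined or _inside(loop_pts, R):
                    break
                if attempt == params.max_retries - 1:
                    loop_pts = 2 * anchor - loop_pts  # rigid reflection
                    if not _inside(loop_pts, R):
                        raise ValidationError(
                            "cannot confine giant loop; increase "
                            "nucleus_radius_nm")
            pts.extend(loop_pts)
            loop_boundaries.append((start_idx, len(pts) - 1))
        else:
            for _ in range(k):
                cur = pts[-1]
                for attempt in range(params.max_retries):
                    d = _random_units(rng, 1)[0]
                    nxt = cur + b * d
                    if not confined or np.linalg.norm(nxt) <= R:
                        break
                    if attempt == params.max_retries - 1:
                        nhat = cur / np.linalg.norm(cur)
                        d = d - 2 * np.dot(d, nhat) * nhat
                        nxt = cur + b * d
                pts.append(nxt)
        done += k
        if done < n_steps:  # backbone step between loops
            cur = pts[-1]
            for attempt in range(params.max_retries):
                d = _random_units(rng, 1)[0]
                nxt = cur + b * d
                if not confined or np.linalg.norm(nxt) <= R:
                    break
                if attempt == params.max_retries - 1:
                    nhat = cur / np.linalg.norm(cur)
                    d = d - 2 * np.dot(d, nhat) * nhat
                    nxt = cur + b * d
            pts.append(nxt)
            done += 1

    points = np.array(pts)
    anchors = np.minimum(np.arange(len(points)) * params.step_bp,
                         chrom_length_bp)
    return NuclearPath(points, anchors, loop_boundaries, params.seed)


# --------------------------------------------------------------------------
# fiber scale


def _interp_along(anchors: np.ndarray, points: np.ndarray,
                  bp: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of a bp-parameterised polyline."""
    bp = np.asarray(bp, dtype=float)
    out = np.empty(bp.shape + (3,))
    for d in range(3):
        out[..., d] = np.interp(bp, anchors, points[:, d])
    return out


def build_fiber_path(nuclear: NuclearPath, bp_per_point: int = 1_200,
                     jitter_nm: float = 3.0, seed: int = 0,
                     nucleus_radius_nm: float = math.inf) -> FiberPath:
    """Subdivide the nuclear polyline into a 30 nm fiber path.

    Fiber points sit every ``bp_per_point`` bp on the bp-interpolated
    nuclear polyline, displaced by seeded isotropic Gaussian jitter of
    amplitude ``jitter_nm`` (0 gives the exact polyline); jitter that
    would leave the nucleus is resampled, then dropped.
    """
    step_bp = int(nuclear.bp_anchors[1] - nuclear.bp_anchors[0]) \
        if len(nuclear) > 1 else 0
    if step_bp and bp_per_point >= step_bp:
        raise ValidationError("bp_per_point must be < nuclear step_bp")
    length = int(nuclear.bp_anchors[-1])
    anchors = np.arange(0, length, bp_per_point)
    if anchors[-1] != length:
        anchors = np.append(anchors, length)
    base = _interp_along(nuclear.bp_anchors.astype(float), nuclear.points,
                         anchors)
    rng = _rng(seed, 1)
    if jitter_nm > 0:
        jit = rng.normal(scale=jitter_nm, size=base.shape)
        pts = base + jit
        if math.isfinite(nucleus_radius_nm):
            bad = np.linalg.norm(pts, axis=1) > nucleus_radius_nm
            for _ in range(20):
                if not bad.any():
                    break
                pts[bad] = base[bad] + rng.normal(scale=jitter_nm,
                                                  size=(bad.sum(), 3))
                bad = np.linalg.norm(pts, axis=1) > nucleus_radius_nm
            pts[bad] = base[bad]
    else:
        pts = base
    return FiberPath(pts, anchors.astype(np.int64), bp_per_point)


# --------------------------------------------------------------------------
# nucleosome scale


def _perp_normals(tangents: np.ndarray) -> np.ndarray:
    """A stable unit normal perpendicular to each tangent."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(tangents), 1))
    near_parallel = np.abs(tangents @ np.array([0.0, 0.0, 1.0])) > 0.99
    ref[near_parallel] = np.array([0.0, 1.0, 0.0])
    n = ref - (np.sum(ref * tangents, axis=1)[:, None]) * tangents
    return n / np.linalg.norm(n, axis=1)[:, None]


def place_nucleosomes(fiber: FiberPath,
                      positions: Optional[Sequence[int]] = None,
                      repeat_bp: int = 200,
                      nucleosomes_per_turn: float = 6.0,
                      solenoid_radius_nm: float = 8.0,
                      superhelix: SuperhelixParams = SuperhelixParams(),
                      ) -> Tuple[List[NucleosomeRecord], int]:
    """Place core particles along a fiber path.

    Without explicit positions nucleosomes tile with period
    ``repeat_bp`` (147 bp wrap + linker) from bp 0; the final linker
    absorbs any remainder so bp are conserved exactly.  Records are
    arranged as a solenoid: the NCP axis follows the local fiber
    tangent and successive particles rotate ``360 / nucleosomes_per_turn``
    degrees about it at radial offset ``solenoid_radius_nm``.

    Returns (records, leading_bp) where ``leading_bp`` counts linker bp
    before the first wrap (always 0 for default tiling).
    """
    length = int(fiber.bp_anchors[-1])
    if positions is None:
        if repeat_bp < WRAP_BP:
            raise ValidationError("repeat_bp must be >= 147")
        n = length // repeat_bp
        if n < 1:
            raise ValidationError(
                f"chromosome of {length} bp is shorter than one repeat")
        starts = np.arange(n, dtype=np.int64) * repeat_bp
        linkers = np.full(n, repeat_bp - WRAP_BP, dtype=np.int64)
        linkers[-1] += length - n * repeat_bp
        leading = 0
    else:
        starts = np.asarray(list(positions), dtype=np.int64)
        if len(starts) == 0:
            raise ValidationError("positions must be non-empty")
        offenders = []
        for i in range(len(starts) - 1):
            if starts[i] + WRAP_BP > starts[i + 1]:
                offenders.append((int(starts[i]), int(starts[i + 1])))
        if np.any(np.diff(starts) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if offenders:
            raise ValidationError(
                f"overlapping nucleosome positions: {offenders}")
        if starts[0] < 0 or starts[-1] + WRAP_BP > length:
            raise ValidationError("positions fall outside the chromosome")
        linkers = np.empty(len(starts), dtype=np.int64)
        linkers[:-1] = np.diff(starts) - WRAP_BP
        linkers[-1] = length - (starts[-1] + WRAP_BP)
        leading = int(starts[0])

    mids = starts.astype(float) + WRAP_BP / 2.0
    anchors_f = fiber.bp_anchors.astype(float)
    centers = _interp_along(anchors_f, fiber.points, mids)
    h = max(fiber.bp_per_point / 2.0, 1.0)
    fwd = _interp_along(anchors_f, fiber.points,
                        np.clip(mids + h, 0, length))
    back = _interp_along(anchors_f, fiber.points,
                         np.clip(mids - h, 0, length))
    tangents = fwd - back
    norms = np.linalg.norm(tangents, axis=1)
    degenerate = norms < 1e-12
    tangents[degenerate] = np.array([0.0, 0.0, 1.0])
    norms[degenerate] = 1.0
    tangents /= norms[:, None]

    n0 = _perp_normals(tangents)
    psi = 2 * np.pi * np.arange(len(starts)) / nucleosomes_per_turn
    binorm = np.cross(tangents, n0)
    radial = np.cos(psi)[:, None] * n0 + np.sin(psi)[:, None] * binorm
    axis_pts = centers + solenoid_radius_nm * radial

    c_off = geom.superhelix_centroid_offset(superhelix)
    records = []
    for i in range(len(starts)):
        e3 = tangents[i]
        e1 = radial[i]
        e2 = np.cross(e3, e1)
        # record origin = centroid of the wrapped bp, not the axis point
        origin = axis_pts[i] + c_off[0] * e1 + c_off[1] * e2 + c_off[2] * e3
        records.append(NucleosomeRecord(int(starts[i]),
                                        Frame(origin, e1, e2, e3),
                                        int(linkers[i])))
    return records, leading


# --------------------------------------------------------------------------
# whole-genome assembly


def read_lengths_table(path) -> List[Tuple[str, int]]:
    """Parse a two-column tab-separated (name, length-bp) table."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{ln}: expected two tab-separated columns")
            try:
                out.append((parts[0], int(parts[1])))
            except ValueError:
                raise ValidationError(
                    f"{path}:{ln}: length is not an integer") from None
    return out


def build_genome_model(lengths: Union[Dict[str, int], Sequence[Tuple[str, int]]],
                       config: BuilderConfig = BuilderConfig(),
                       name: str = "synthetic") -> GenomeModel:
    """Build all three stored scales for every chromosome.

    Each chromosome gets an independent seed derived from the master
    seed, so models are reproducible chromosome by chromosome.
    """
    items = list(lengths.items()) if isinstance(lengths, dict) else list(lengths)
    chroms: Dict[str, ChromosomeModel] = {}
    for i, (cname, clen) in enumerate(items):
        sub = int(np.random.SeedSequence(config.seed, spawn_key=(i,))
                  .generate_state(1)[0] % (2 ** 31))
        nuc_params = replace(config.nuclear, seed=sub)
        nuclear = build_nuclear_walk(clen, nuc_params)
        fiber = build_fiber_path(
            nuclear, config.bp_per_fiber_point, config.fiber_jitter_nm,
            seed=sub, nucleus_radius_nm=config.nuclear.nucleus_radius_nm)
        records, leading = place_nucleosomes(
            fiber, None, config.nucleosome_repeat_bp,
            config.nucleosomes_per_turn, config.solenoid_radius_nm,
            config.superhelix)
        chrom = ChromosomeModel(cname, clen, nuclear, fiber, records, leading)
        chrom.validate_bp_conservation()
        chroms[cname] = chrom
    return GenomeModel(name, config, chroms)


# --------------------------------------------------------------------------
# DNA scale (on demand)


def _axis_anchor(record: NucleosomeRecord,
                 superhelix: SuperhelixParams) -> Frame:
    """Cylinder-axis anchor frame recovered from a centroid-anchored record."""
    c = geom.superhelix_centroid_offset(superhelix)
    f = record.frame
    origin = f.origin - (c[0] * f.e1 + c[1] * f.e2 + c[2] * f.e3)
    return Frame(origin, f.e1, f.e2, f.e3)


def _slerp_frames(fa: Frame, fb: Frame, ts: np.ndarray,
                  origins: np.ndarray) -> List[Frame]:
    from scipy.spatial.transform import Rotation, Slerp
    rots = Rotation.from_matrix(np.array([fa.rotation, fb.rotation]))
    sl = Slerp([0.0, 1.0], rots)
    mats = sl(ts).as_matrix()
    return [Frame.from_rotation(origins[k], mats[k]) for k in range(len(ts))]


def _validate_range(model: GenomeModel, grange: GenomicRange) -> ChromosomeModel:
    chrom = model.chromosome(grange.chrom)
    if grange.end > chrom.length_bp:
        raise GenomicRangeError(
            f"range {grange.chrom}:{grange.start}-{grange.end} exceeds "
            f"chromosome length {chrom.length_bp}")
    return chrom


def synthesize_dna(model: GenomeModel, grange: GenomicRange,
                   template: Optional[AtomTemplate] = None,
                   with_atoms: bool = True) -> DnaSegment:
    """Per-bp frames (and atoms) for a genomic range, computed on demand.

    Wrapped bp follow the nucleosome superhelix of their record; linker
    bp interpolate between the exit frame of one wrap and the entry
    frame of the next (positions linearly, orientations by spherical
    interpolation).  The result depends only on (model, range,
    template): chunked queries concatenate to identical coordinates.
    """
    chrom = _validate_range(model, grange)
    cfg = model.config
    recs = chrom.nucleosomes
    starts = np.array([r.start_bp for r in recs])
    wrap_cache: Dict[int, List[Frame]] = {}

    def wrap_frames(i: int) -> List[Frame]:
        if i not in wrap_cache:
            wrap_cache[i] = geom.wrap_superhelix(
                cfg.superhelix, _axis_anchor(recs[i], cfg.superhelix),
                cfg.helix)
        return wrap_cache[i]

    def straight_before(entry: Frame, count: int) -> List[Frame]:
        """``count`` straight-B-DNA bp immediately upstream of ``entry``."""
        if count == 0:
            return []
        start = entry.translated(-count * cfg.helix.rise_nm * entry.e3)
        start = start.rotated_about(entry.e3, -count * cfg.helix.twist_rad)
        return geom.propagate_bdna_frames(count, start, cfg.helix)

    frames: List[Frame] = []
    bp = grange.start
    while bp < grange.end:
        i = int(np.searchsorted(starts, bp, side="right")) - 1
        if i >= 0 and bp < recs[i].end_bp:
            wf = wrap_frames(i)
            lo = bp - recs[i].start_bp
            hi = min(recs[i].end_bp, grange.end) - recs[i].start_bp
            frames.extend(wf[lo:hi])
            bp = recs[i].start_bp + hi
            continue
        # linker (or leading/trailing) region
        if i < 0:
            seg_start, seg_end = 0, recs[0].start_bp if recs else chrom.length_bp
        else:
            seg_start = recs[i].end_bp
            seg_end = recs[i + 1].start_bp if i + 1 < len(recs) else chrom.length_bp
        lo = bp
        hi = min(seg_end, grange.end)
        n_link = seg_end - seg_start
        if n_link > 0:
            if i >= 0 and i + 1 < len(recs):
                exit_f = wrap_frames(i)[-1]
                entry_f = wrap_frames(i + 1)[0]
                ts_all = (np.arange(n_link) + 1.0) / (n_link + 1.0)
                ts = ts_all[lo - seg_start:hi - seg_start]
                origins = (exit_f.origin[None, :] * (1 - ts)[:, None]
                           + entry_f.origin[None, :] * ts[:, None])
                frames.extend(_slerp_frames(exit_f, entry_f, ts, origins))
            elif i < 0 and recs:
                entry_f = wrap_frames(0)[0]
                all_f = straight_before(entry_f, n_link)
                frames.extend(all_f[lo - seg_start:hi - seg_start])
            elif i >= 0:
                exit_f = wrap_frames(i)[-1]
                trail = geom.propagate_bdna_frames(n_link + 1, exit_f,
                                                   cfg.helix)[1:]
                frames.extend(trail[lo - seg_start:hi - seg_start])
            else:  # no records at all: straight DNA from the origin
                all_f = geom.propagate_bdna_frames(n_link, Frame.identity(),
                                                   cfg.helix)
                frames.extend(all_f[lo - seg_start:hi - seg_start])
        bp = hi

    atoms: List[Atom] = []
    if with_atoms:
        tpl = template if template is not None else default_atom_template()
        atoms = geom.place_atoms(frames, tpl)
    return DnaSegment(grange, frames, atoms)


# --------------------------------------------------------------------------
# cross-scale navigation


def map_bp_to_scale(model: GenomeModel, chrom_name: str, bp: int, scale: str):
    """Locate the model element containing ``bp`` at a given scale.

    Returns ``(index, element)``.  At nucleosome scale a bp between
    wraps returns ``(None, LinkerLocation)`` naming the flanking
    records.
    """
    chrom = model.chromosome(chrom_name)
    if not (0 <= bp < chrom.length_bp):
        raise GenomicRangeError(
            f"bp {bp} outside {chrom_name} (length {chrom.length_bp})")
    if scale in ("nuclear", "fiber"):
        path = chrom.nuclear if scale == "nuclear" else chrom.fiber
        idx = int(np.searchsorted(path.bp_anchors, bp, side="right")) - 1
        idx = max(0, min(idx, len(path) - 1))
        return idx, path.points[idx]
    if scale == "nucleosome":
        recs = chrom.nucleosomes
        starts = np.array([r.start_bp for r in recs])
        i = int(np.searchsorted(starts, bp, side="right")) - 1
        if i >= 0 and bp < recs[i].end_bp:
            return i, recs[i]
        if i < 0:
            return None, LinkerLocation(None, 0 if recs else None, 0,
                                        recs[0].start_bp if recs
                                        else chrom.length_bp)
        nxt = i + 1 if i + 1 < len(recs) else None
        end = recs[i + 1].start_bp if nxt is not None else chrom.length_bp
        return None, LinkerLocation(i, nxt, recs[i].end_bp, end)
    raise ValidationError(f"unknown scale {scale!r}")


def position_at_bp(chrom: ChromosomeModel, bp, scale: str = "fiber") -> np.ndarray:
    """3D position(s) of genomic coordinate(s) by polyline interpolation."""
    path = chrom.fiber if scale == "fiber" else chrom.nuclear
    return _interp_along(path.bp_anchors.astype(float), path.points,
                         np.asarray(bp, dtype=float))


# --------------------------------------------------------------------------
# equality (used by store round-trip tests and the CLI)


def models_equal(a: GenomeModel, b: GenomeModel, tol_nm: float = 5e-4) -> bool:
    """Coordinate equality within ``tol_nm``; integer fields exact."""
    if set(a.chromosomes) != set(b.chromosomes):
        return False
    for name in a.chromosomes:
        ca, cb = a.chromosomes[name], b.chromosomes[name]
        if ca.length_bp != cb.length_bp or ca.leading_bp != cb.leading_bp:
            return False
        for pa, pb in ((ca.nuclear, cb.nuclear), (ca.fiber, cb.fiber)):
            if (len(pa) != len(pb)
                    or not np.array_equal(pa.bp_anchors, pb.bp_anchors)
                    or not np.allclose(pa.points, pb.points, atol=tol_nm)):
                return False
        if len(ca.nucleosomes) != len(cb.nucleosomes):
            return False
        for ra, rb in zip(ca.nucleosomes, cb.nucleosomes):
            if (ra.start_bp != rb.start_bp
                    or ra.linker_bp_after != rb.linker_bp_after):
                return False
            if not np.allclose(ra.frame.origin, rb.frame.origin, atol=tol_nm):
                return False
            if not np.allclose(ra.frame.rotation, rb.frame.rotation,
                               atol=tol_nm * 10):
                return False
    return True
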