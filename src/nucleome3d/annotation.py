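"""UCSC track parsing and projection onto model elements.

BED intervals are 0-based half-open; WIG declarations are 1-based per
the UCSC dialect and converted to 0-based internally.  bedGraph is
accepted as a WIG variant (detected by 4-column data lines).  Strand is
carried through parsing but ignored by projection.

Projection assigns per-bp values to the element containing each bp at
the requested scale, then aggregates per element.  At nucleosome scale
the elements are the wraps and the linkers between them; at nuclear and
fiber scale they are the bp spans between consecutive path points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .builder import (ChromosomeModel, GenomeModel, NucleosomeRecord,
                      map_bp_to_scale)
from .errors import GenomicRangeError, ValidationError
from .geometry import HelixParams, SuperhelixParams, phase_angle

__all__ = [
    "BedInterval",
    "WigTrack",
    "ScaleAnnotation",
    "ColorRule",
    "SnpPhaseRow",
    "ProximityRow",
    "parse_bed",
    "parse_wig",
    "write_bed",
    "write_wig",
    "project",
    "snp_phase_report",
    "proximity_classify",
    "colorize",
]

AGGREGATIONS = ("mean", "max", "sum", "coverage")


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = ""
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")
        if self.start < 0:
            raise ValidationError("negative interval start")
        if self.score is not None and not math.isfinite(self.score):
            raise ValidationError("score must be finite")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self):
        return self.end - self.start


@dataclass
class WigTrack:
    chrom: str
    mode: str                      # "fixedStep" | "variableStep"
    span: int
    positions: List[int]           # 0-based internal starts
    values: List[float]

    def __post_init__(self):
        if self.span < 1:
            raise ValidationError("span must be >= 1")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValidationError("positions must be strictly increasing")

    def intervals(self) -> Iterable[Tuple[int, int, float]]:
        for p, v in zip(self.positions, self.values):
            yield p, p + self.span, v


@dataclass
class ScaleAnnotation:
    """Aggregated per-element values at one scale."""

    scale: str
    aggregation: str
    values: Dict[tuple, float]     # element id -> aggregate
    coverage: Dict[tuple, int]     # element id -> annotated bp


@dataclass(frozen=True)
class ColorRule:
    """How element values map to RGB (components in [0, 1]).

    ``signed`` maps positive to green and negative to red, scaled so the
    largest |value| is fully saturated and 0 is neutral grey.
    """

    scheme: str = "signed"
    neutral: tuple = (0.6, 0.6, 0.6)
    positive: tuple = (0.0, 0.85, 0.0)
    negative: tuple = (0.85, 0.0, 0.0)
    palette: tuple = ((0.9, 0.6, 0.1), (0.2, 0.5, 0.9), (0.3, 0.8, 0.3),
                      (0.8, 0.3, 0.7))

    def __post_init__(self):
        if self.scheme not in ("signed", "sequential", "categorical"):
            raise ValidationError(f"unknown color scheme {self.scheme!r}")


# --------------------------------------------------------------------------
# parsing


def _is_header(line: str) -> bool:
    return (line.startswith("track") or line.startswith("browser")
            or line.startswith("#"))


def parse_bed(stream: TextIO) -> List[BedInterval]:
    """Parse BED 3-6; header/track/browser lines are skipped.

    Raises :class:`ValidationError` with the line number for malformed
    coordinates or empty intervals.
    """
    out = []
    for ln, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip() or _is_header(line):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 3:
            raise ValidationError(f"line {ln}: fewer than 3 BED columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ValidationError(
                f"line {ln}: non-integer coordinates") from None
        if start >= end:
            raise ValidationError(
                f"line {ln}: empty interval (start {start} >= end {end})")
        name = cols[3] if len(cols) > 3 else ""
        score = None
        if len(cols) > 4 and cols[4] not in (".", ""):
            try:
                score = float(cols[4])
            except ValueError:
                raise ValidationError(f"line {ln}: non-numeric score") from None
        strand = cols[5] if len(cols) > 5 else "."
        try:
            out.append(BedInterval(cols[0], start, end, name, score, strand))
        except ValidationError as e:
            raise ValidationError(f"line {ln}: {e}") from None
    return out


def _parse_decl(line: str, ln: int) -> Dict[str, str]:
    fields = {}
    for tok in line.split()[1:]:
        if "=" not in tok:
            raise ValidationError(f"line {ln}: bad declaration token {tok!r}")
        k, v = tok.split("=", 1)
        fields[k] = v
    return fields


def parse_wig(stream: TextIO) -> List[WigTrack]:
    """Parse WIG fixedStep/variableStep tracks (bedGraph auto-detected).

    WIG's 1-based starts become 0-based internally.  A value line before
    any declaration is a format error, except bedGraph data lines
    (chrom start end value), which use BED-style 0-based coordinates.
    """
    tracks: List[WigTrack] = []
    cur: Optional[WigTrack] = None
    mode = None
    fs_start = fs_step = None
    for ln, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or _is_header(line):
            continue
        if line.startswith("fixedStep") or line.startswith("variableStep"):
            if cur is not None:
                tracks.append(cur)
            decl = _parse_decl(line, ln)
            mode = line.split()[0]
            if "chrom" not in decl:
                raise ValidationError(f"line {ln}: declaration lacks chrom=")
            span = int(decl.get("span", 1))
            cur = WigTrack(decl["chrom"], mode, span, [], [])
            if mode == "fixedStep":
                try:
                    fs_start = int(decl["start"]) - 1  # 1-based -> 0-based
                    fs_step = int(decl.get("step", 1))
                except KeyError:
                    raise ValidationError(
                        f"line {ln}: fixedStep needs start=") from None
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) == 4 and cur is None:
            # bedGraph data line: chrom start end value, 0-based half-open
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError:
                raise ValidationError(
                    f"line {ln}: bad bedGraph line") from None
            if start >= end:
                raise ValidationError(f"line {ln}: empty bedGraph interval")
            if (tracks and tracks[-1].mode == "bedGraph"
                    and tracks[-1].chrom == cols[0]
                    and tracks[-1].span == end - start
                    and (not tracks[-1].positions
                         or start > tracks[-1].positions[-1])):
                tracks[-1].positions.append(start)
                tracks[-1].values.append(value)
            else:
                tracks.append(WigTrack(cols[0], "bedGraph", end - start,
                                       [start], [value]))
            continue
        if cur is None:
            raise ValidationError(
                f"line {ln}: value line before any declaration")
        try:
            if mode == "fixedStep":
                value = float(cols[0])
                pos = fs_start + len(cur.values) * fs_step
            else:
                pos, value = int(cols[0]) - 1, float(cols[1])
        except (ValueError, IndexError):
            raise ValidationError(f"line {ln}: non-numeric value") from None
        cur.positions.append(pos)
        cur.values.append(value)
    if cur is not None:
        tracks.append(cur)
    for t in tracks:
        # re-run the ordering invariant now that values are attached
        WigTrack(t.chrom, t.mode, t.span, t.positions, t.values)
    return tracks


def write_bed(intervals: Sequence[BedInterval], stream: TextIO) -> int:
    """Write canonical-dialect BED (as many columns as are populated)."""
    n = 0
    for iv in intervals:
        cols = [iv.chrom, str(iv.start), str(iv.end)]
        if iv.name or iv.score is not None or iv.strand != ".":
            cols.append(iv.name or ".")
        if iv.score is not None or iv.strand != ".":
            cols.append("%g" % iv.score if iv.score is not None else "0")
        if iv.strand != ".":
            cols.append(iv.strand)
        stream.write("\t".join(cols) + "\n")
        n += 1
    return n


def write_wig(tracks: Sequence[WigTrack], stream: TextIO) -> int:
    n = 0
    for t in tracks:
        if t.mode == "bedGraph":
            for s, e, v in t.intervals():
                stream.write(f"{t.chrom}\t{s}\t{e}\t{v:g}\n")
        else:
            stream.write(f"variableStep chrom={t.chrom} span={t.span}\n")
            for p, v in zip(t.positions, t.values):
                stream.write(f"{p + 1} {v:g}\n")
        n += 1
    return n


# --------------------------------------------------------------------------
# projection


def _element_edges(chrom: ChromosomeModel, scale: str):
    """Sorted bp edges and the element id owning each [edge_i, edge_i+1)."""
    if scale in ("nuclear", "fiber"):
        path = chrom.nuclear if scale == "nuclear" else chrom.fiber
        anchors = list(int(a) for a in path.bp_anchors)
        edges = anchors + ([chrom.length_bp] if anchors[-1] != chrom.length_bp
                           else [])
        if edges[-1] != chrom.length_bp:
            edges.append(chrom.length_bp)
        ids = [("point", i) for i in range(len(edges) - 1)]
        return np.array(edges), ids
    if scale == "nucleosome":
        edges = [0]
        ids = []
        recs = chrom.nucleosomes
        if chrom.leading_bp > 0:
            edges.append(chrom.leading_bp)
            ids.append(("linker", -1))
        for i, r in enumerate(recs):
            edges.append(r.end_bp)
            ids.append(("nuc", i))
            if r.linker_bp_after > 0:
                edges.append(r.span_end_bp)
                ids.append(("linker", i))
        return np.array(edges), ids
    raise ValidationError(f"unknown scale {scale!r}")


def _iter_value_intervals(track, chrom_name: str):
    if isinstance(track, WigTrack):
        if track.chrom == chrom_name:
            yield from track.intervals()
        return
    for item in track:
        if isinstance(item, WigTrack):
            if item.chrom == chrom_name:
                yield from item.intervals()
        else:
            if item.chrom == chrom_name:
                v = item.score if item.score is not None else 1.0
                yield item.start, item.end, v


def project(track, model: GenomeModel, chrom_name: str, scale: str,
            aggregation: str = "coverage") -> ScaleAnnotation:
    """Project a BED interval list or WIG track(s) onto one chromosome.

    Aggregations: ``coverage`` counts annotated bp per element (with
    multiplicity for overlapping intervals); ``sum`` adds value x bp;
    ``mean`` is sum / coverage; ``max`` is the largest single value
    touching the element.
    """
    if aggregation not in AGGREGATIONS:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    chrom = model.chromosome(chrom_name)
    edges, ids = _element_edges(chrom, scale)
    cov: Dict[tuple, int] = {}
    tot: Dict[tuple, float] = {}
    mx: Dict[tuple, float] = {}
    for start, end, value in _iter_value_intervals(track, chrom_name):
        start = max(0, start)
        end = min(chrom.length_bp, end)
        if start >= end:
            continue
        i0 = int(np.searchsorted(edges, start, side="right")) - 1
        i1 = int(np.searchsorted(edges, end, side="left"))
        for i in range(max(i0, 0), min(i1, len(ids))):
            lo = max(start, int(edges[i]))
            hi = min(end, int(edges[i + 1]))
            if lo >= hi:
                continue
            eid = ids[i]
            cov[eid] = cov.get(eid, 0) + (hi - lo)
            tot[eid] = tot.get(eid, 0.0) + value * (hi - lo)
            mx[eid] = max(mx.get(eid, -math.inf), value)
    if aggregation == "coverage":
        values = {k: float(v) for k, v in cov.items()}
    elif aggregation == "sum":
        values = tot
    elif aggregation == "mean":
        values = {k: tot[k] / cov[k] for k in tot}
    else:
        values = mx
    return ScaleAnnotation(scale, aggregation, values, cov)


# --------------------------------------------------------------------------
# demonstration statistics


@dataclass(frozen=True)
class SnpPhaseRow:
    snp: BedInterval
    record_index: Optional[int]   # None when the SNP sits in a linker
    nearest_index: int            # equals record_index when wrapped
    offset_bp: Optional[int]      # offset from wrap start (wrapped SNPs)
    phase_deg: Optional[float]
    axial_nm: Optional[float]     # position along the superhelix axis
    in_linker: bool


def snp_phase_report(snps: Sequence[BedInterval],
                     nucleosomes: Sequence[NucleosomeRecord],
                     helix: HelixParams = HelixParams(),
                     superhelix: SuperhelixParams = SuperhelixParams(),
                     ) -> List[SnpPhaseRow]:
    """Rotational phasing of single-bp SNPs relative to nucleosome wraps.

    Each wrapped SNP gets its bp offset from the wrap start, its helical
    phase angle and its axial position along the superhelix axis.  SNPs
    between wraps are flagged as linker with the nearest record index.
    """
    if not nucleosomes:
        raise ValidationError("no nucleosome records supplied")
    starts = np.array([r.start_bp for r in nucleosomes])
    rows = []
    for snp in snps:
        if len(snp) != 1:
            raise ValidationError(
                f"SNP {snp.name or snp.start} spans {len(snp)} bp; "
                "SNPs must be single-bp intervals")
        bp = snp.start
        i = int(np.searchsorted(starts, bp, side="right")) - 1
        if i >= 0 and bp < nucleosomes[i].end_bp:
            off = bp - nucleosomes[i].start_bp
            u = off / (nucleosomes[i].wrap_bp - 1)
            axial = (u - 0.5) * superhelix.turns * superhelix.pitch_nm
            rows.append(SnpPhaseRow(snp, i, i, off,
                                    phase_angle(off, helix), axial, False))
        else:
            cand = []
            if i >= 0:
                cand.append((bp - nucleosomes[i].end_bp + 1, i))
            if i + 1 < len(nucleosomes):
                cand.append((nucleosomes[i + 1].start_bp - bp, i + 1))
            nearest = min(cand)[1]
            rows.append(SnpPhaseRow(snp, None, nearest, None, None, None,
                                    True))
    return rows


@dataclass(frozen=True)
class ProximityRow:
    site: BedInterval
    distance_bp: float            # inf when no TSS exists
    near: bool


def proximity_classify(sites: Sequence[BedInterval],
                       tss: Sequence[BedInterval],
                       threshold_bp: int = 10_000) -> List[ProximityRow]:
    """Classify binding sites as near/far from the closest TSS.

    Distance is |site midpoint - TSS position| (TSS taken at its
    interval start); *near* means strictly less than ``threshold_bp``,
    so a site exactly at the threshold is far.  With no TSS every site
    is far at infinite distance.
    """
    tss_pos = np.array(sorted(t.start for t in tss), dtype=float)
    rows = []
    for site in sites:
        if len(tss_pos) == 0:
            rows.append(ProximityRow(site, math.inf, False))
            continue
        d = float(np.min(np.abs(tss_pos - site.midpoint)))
        rows.append(ProximityRow(site, d, d < threshold_bp))
    return rows


def colorize(values, rule: ColorRule = ColorRule()):
    """Map per-element values to RGB triples under a color rule.

    Accepts a dict (returns a dict) or a sequence (returns a list).
    Signed: 0 maps to neutral grey, max |value| to fully saturated
    green (positive) or red (negative); saturation is monotone in
    |value|.
    """
    keys = None
    if isinstance(values, dict):
        keys = list(values)
        vals = np.array([values[k] for k in keys], dtype=float)
    else:
        vals = np.asarray(list(values), dtype=float)
    if vals.size and not np.all(np.isfinite(vals)):
        raise ValidationError("values must be finite")

    def lerp(a, b, t):
        return tuple((1 - t) * np.asarray(a) + t * np.asarray(b))

    out = []
    if rule.scheme == "signed":
        vmax = float(np.max(np.abs(vals))) if vals.size else 0.0
        for v in vals:
            if vmax == 0.0 or v == 0.0:
                out.append(tuple(rule.neutral))
            else:
                t = abs(v) / vmax
                target = rule.positive if v > 0 else rule.negative
                out.append(lerp(rule.neutral, target, t))
    elif rule.scheme == "sequential":
        lo = float(vals.min()) if vals.size else 0.0
        hi = float(vals.max()) if vals.size else 0.0
        for v in vals:
            t = 0.0 if hi == lo else (v - lo) / (hi - lo)
            out.append(lerp(rule.neutral, rule.positive, t))
    else:  # categorical
        for v in vals:
            out.append(tuple(rule.palette[int(v) % len(rule.palette)]))
    if keys is not None:
        return dict(zip(keys, out))
    return out
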