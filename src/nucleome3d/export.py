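"""Export of atomic selections and scene descriptions.

PDB output uses fixed-column v3.3 ATOM records with coordinates in
Angstroms (internal nm x 10) and residue name ``DN``; serials are hard
capped at 99,999 — oversized selections must be subdivided rather than
silently wrapped.  PovRay output is plain scene-description text
(camera, lights, one object per primitive); XYZ is the simple
count/comment/element-x-y-z format, also in Angstroms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .annotation import ColorRule, ProximityRow, ScaleAnnotation, colorize
from .builder import (ChromosomeModel, GenomeModel, GenomicRange,
                      position_at_bp, synthesize_dna)
from .errors import (PdbOverflowError, SceneRangeError, ValidationError)
from .geometry import Atom

__all__ = [
    "Sphere", "Cylinder", "Polyline", "Box", "Camera", "Scene",
    "write_pdb", "write_povray", "write_xyz", "scene_from_model",
]

log = logging.getLogger(__name__)

NM_TO_ANGSTROM = 10.0
PDB_MAX_ATOMS = 99_999

_GREY = (0.6, 0.6, 0.6)


def _vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise ValidationError("coordinates must be finite 3-vectors")
    return a


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float
    color: Tuple[float, float, float] = _GREY

    def __post_init__(self):
        object.__setattr__(self, "center", _vec(self.center))
        if self.radius <= 0:
            raise ValidationError("sphere radius must be > 0")


@dataclass(frozen=True)
class Cylinder:
    p1: np.ndarray
    p2: np.ndarray
    radius: float
    color: Tuple[float, float, float] = _GREY

    def __post_init__(self):
        object.__setattr__(self, "p1", _vec(self.p1))
        object.__setattr__(self, "p2", _vec(self.p2))
        if self.radius <= 0:
            raise ValidationError("cylinder radius must be > 0")


@dataclass(frozen=True)
class Polyline:
    points: np.ndarray
    radius: float
    color: Tuple[float, float, float] = _GREY

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] != 3 or len(pts) < 2 or not np.all(np.isfinite(pts)):
            raise ValidationError("polyline needs >= 2 finite 3D points")
        object.__setattr__(self, "points", pts)
        if self.radius <= 0:
            raise ValidationError("polyline radius must be > 0")


@dataclass(frozen=True)
class Box:
    center: np.ndarray
    half_size: float
    color: Tuple[float, float, float] = _GREY

    def __post_init__(self):
        object.__setattr__(self, "center", _vec(self.center))
        if self.half_size <= 0:
            raise ValidationError("box half_size must be > 0")


@dataclass(frozen=True)
class Camera:
    position: np.ndarray
    look_at: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", _vec(self.position))
        object.__setattr__(self, "look_at", _vec(self.look_at))


@dataclass
class Scene:
    primitives: List[object] = field(default_factory=list)
    camera: Optional[Camera] = None
    lights: List[np.ndarray] = field(default_factory=list)

    def __len__(self):
        return len(self.primitives)


# --------------------------------------------------------------------------
# PDB


def _pdb_name_field(name: str) -> str:
    # short names start in column 14 by convention
    return f" {name:<3}" if len(name) < 4 else name


def write_pdb(atoms: Sequence[Atom], stream: TextIO,
              origin=None) -> int:
    """Write fixed-column ATOM records (+ END); returns the record count.

    Coordinates are converted nm -> Angstrom, optionally after
    subtracting ``origin`` (nm) — a selection deep inside a nuclear-
    sized model can exceed the 8-character coordinate fields unless it
    is recentred.  resSeq is the atom's bp index + 1, wrapped at 9999;
    more than 99,999 atoms is a hard error.
    """
    if len(atoms) > PDB_MAX_ATOMS:
        raise PdbOverflowError(
            f"{len(atoms)} atoms exceed the PDB serial limit of "
            f"{PDB_MAX_ATOMS}; export the region in smaller pieces")
    shift = _vec(origin) if origin is not None else np.zeros(3)
    n = 0
    for serial, atom in enumerate(atoms, 1):
        x, y, z = (atom.position - shift) * NM_TO_ANGSTROM
        if not (-999.999 <= min(x, y, z) and max(x, y, z) <= 9999.999):
            raise ValidationError(
                f"coordinate {max(abs(x), abs(y), abs(z)):.1f} A overflows "
                "the fixed PDB columns; pass origin= to recentre the "
                "selection")
        resseq = (atom.bp_index % 9999) + 1
        stream.write(
            f"ATOM  {serial:>5} {_pdb_name_field(atom.name)} {'DN':>3} A"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {atom.element:>2}\n")
        n += 1
    stream.write("END\n")
    return n


# --------------------------------------------------------------------------
# XYZ


def write_xyz(atoms: Sequence[Atom], stream: TextIO,
              comment: str = "nucleome3d selection") -> int:
    stream.write(f"{len(atoms)}\n{comment}\n")
    for atom in atoms:
        x, y, z = atom.position * NM_TO_ANGSTROM
        stream.write(f"{atom.element} {x:.3f} {y:.3f} {z:.3f}\n")
    return len(atoms)


# --------------------------------------------------------------------------
# PovRay


def _pv(v) -> str:
    return f"<{v[0]:.3f}, {v[1]:.3f}, {v[2]:.3f}>"


def _pigment(color) -> str:
    return (f"pigment {{ color rgb <{color[0]:.3f}, {color[1]:.3f}, "
            f"{color[2]:.3f}> }}")


def write_povray(scene: Scene, stream: TextIO) -> int:
    """Emit a PovRay scene; returns the primitive count.

    One object is emitted per scene primitive (polylines become a
    single ``sphere_sweep``).  A degenerate cylinder (coincident
    endpoints) is replaced by a sphere with a logged warning.
    """
    if len(scene) == 0:
        raise ValidationError("refusing to write an empty scene")
    def _anchor(p):
        if hasattr(p, "center"):
            return p.center
        if hasattr(p, "p1"):
            return p.p1
        return p.points[0]

    cam = scene.camera
    if cam is None:
        pts = np.array([_anchor(p) for p in scene.primitives])
        center = pts.mean(axis=0)
        extent = max(float(np.ptp(pts)) if len(pts) else 1.0, 1.0)
        cam = Camera(center + np.array([0.0, 0.0, 3 * extent]), center)
    stream.write("// generated by nucleome3d\n")
    stream.write("#version 3.7;\nglobal_settings { assumed_gamma 1.0 }\n")
    stream.write(f"camera {{ location {_pv(cam.position)} "
                 f"look_at {_pv(cam.look_at)} }}\n")
    lights = scene.lights or [cam.position + np.array([0.0, 1000.0, 0.0])]
    for l in lights:
        stream.write(f"light_source {{ {_pv(l)} color rgb <1, 1, 1> }}\n")
    n = 0
    for prim in scene.primitives:
        if isinstance(prim, Cylinder):
            if np.linalg.norm(prim.p2 - prim.p1) < 1e-9:
                log.warning("degenerate cylinder at %s replaced by sphere",
                            prim.p1)
                prim = Sphere(prim.p1, prim.radius, prim.color)
            else:
                stream.write(
                    f"cylinder {{ {_pv(prim.p1)}, {_pv(prim.p2)}, "
                    f"{prim.radius:.3f} {_pigment(prim.color)} }}\n")
                n += 1
                continue
        if isinstance(prim, Sphere):
            stream.write(f"sphere {{ {_pv(prim.center)}, "
                         f"{prim.radius:.3f} {_pigment(prim.color)} }}\n")
        elif isinstance(prim, Polyline):
            pts = ", ".join(_pv(p) + f", {prim.radius:.3f}"
                            for p in prim.points)
            stream.write(
                f"sphere_sweep {{ linear_spline {len(prim.points)}, "
                f"{pts} {_pigment(prim.color)} }}\n")
        elif isinstance(prim, Box):
            c, h = prim.center, prim.half_size
            stream.write(f"box {{ {_pv(c - h)}, {_pv(c + h)} "
                         f"{_pigment(prim.color)} }}\n")
        else:
            raise ValidationError(f"unknown primitive {type(prim).__name__}")
        n += 1
    return n


# --------------------------------------------------------------------------
# scene generation


def _element_color(annotation: Optional[ScaleAnnotation],
                   colors: Optional[dict], eid: tuple):
    if annotation is None or colors is None:
        return _GREY
    return colors.get(eid, _GREY)


def scene_from_model(model: GenomeModel, grange: GenomicRange, scale: str,
                     annotation: Optional[ScaleAnnotation] = None,
                     color_rule: ColorRule = ColorRule(),
                     tss: Optional[Sequence] = None,
                     tss_values: Optional[dict] = None,
                     sites: Optional[Sequence[ProximityRow]] = None,
                     max_dna_bp: int = 100_000,
                     ncp_radius_nm: float = 5.5,
                     ncp_height_nm: float = 5.5,
                     atom_radius_nm: float = 0.15) -> Scene:
    """Build a renderable Scene for a genomic range at one scale.

    nuclear/fiber: a polyline through the path points plus a sphere per
    point.  nucleosome: one cylinder per core particle (11 nm diameter
    by default) plus polyline linkers.  dna: one sphere per pseudo-atom
    (range capped at ``max_dna_bp``).  Annotation colors are applied
    per element; optional TSS expression spheres (signed green/red) and
    binding-site boxes (orange when near a TSS, yellow otherwise) can
    be overlaid.
    """
    chrom = model.chromosome(grange.chrom)
    if grange.end > chrom.length_bp:
        raise SceneRangeError(
            f"range end {grange.end} exceeds chromosome length "
            f"{chrom.length_bp}")
    colors = (colorize(annotation.values, color_rule)
              if annotation is not None else None)
    scene = Scene()

    if scale in ("nuclear", "fiber"):
        path = chrom.nuclear if scale == "nuclear" else chrom.fiber
        sel = [(i, path.points[i]) for i in range(len(path))
               if grange.start <= path.bp_anchors[i] < grange.end
               or (i + 1 < len(path)
                   and path.bp_anchors[i] < grange.end
                   and path.bp_anchors[i + 1] > grange.start)]
        if len(sel) < 1:
            raise SceneRangeError("range selects no path points")
        sphere_r = 50.0 if scale == "nuclear" else 15.0
        line_r = sphere_r / 2.5
        pts = np.array([p for _, p in sel])
        if len(pts) >= 2:
            scene.primitives.append(Polyline(pts, line_r))
        for i, p in sel:
            scene.primitives.append(
                Sphere(p, sphere_r,
                       _element_color(annotation, colors, ("point", i))))
    elif scale == "nucleosome":
        recs = [(i, r) for i, r in enumerate(chrom.nucleosomes)
                if r.start_bp < grange.end and r.span_end_bp > grange.start]
        prev_origin = None
        for i, r in recs:
            axis = r.frame.e3 * (ncp_height_nm / 2.0)
            scene.primitives.append(
                Cylinder(r.frame.origin - axis, r.frame.origin + axis,
                         ncp_radius_nm,
                         _element_color(annotation, colors, ("nuc", i))))
        for (i, r), (j, s) in zip(recs, recs[1:]):
            scene.primitives.append(
                Polyline(np.array([r.frame.origin, s.frame.origin]), 1.0,
                         _element_color(annotation, colors, ("linker", i))))
    elif scale == "dna":
        if len(grange) > max_dna_bp:
            raise SceneRangeError(
                f"DNA-scale range of {len(grange)} bp exceeds the cap of "
                f"{max_dna_bp} bp")
        seg = synthesize_dna(model, grange)
        for atom in seg.atoms:
            scene.primitives.append(Sphere(atom.position, atom_radius_nm))
    else:
        raise ValidationError(f"unknown scale {scale!r}")

    # Fig-3-style overlays: expression spheres at TSSs, boxes at sites
    if tss:
        vals = tss_values or {}
        tcolors = colorize({t.name or idx: vals.get(t.name, 0.0)
                            for idx, t in enumerate(tss)}, color_rule)
        for idx, t in enumerate(tss):
            p = position_at_bp(chrom, t.start, "fiber")
            scene.primitives.append(
                Sphere(p, 30.0, tcolors[t.name or idx]))
    if sites:
        for row in sites:
            p = position_at_bp(chrom, row.site.midpoint, "fiber")
            color = (1.0, 0.55, 0.0) if row.near else (1.0, 1.0, 0.0)
            scene.primitives.append(Box(p, 20.0, color))
    return scene
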