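"""Pure chromatin geometry.

Local orthonormal frames are the common currency between the model's
scales: every base pair, nucleosome and fiber element carries (or can be
assigned) a :class:`Frame`.  On top of frames this module implements

* ideal straight B-DNA frame propagation (:func:`propagate_bdna_frames`),
* the left-handed nucleosomal DNA superhelix (:func:`wrap_superhelix`),
* pseudo-atom placement from a per-bp template (:func:`place_atoms`),
* rotational phasing angles (:func:`phase_angle`).

All lengths are in nanometres; angles are degrees at the API surface and
radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "Frame",
    "HelixParams",
    "SuperhelixParams",
    "AtomTemplate",
    "TemplateEntry",
    "Atom",
    "default_atom_template",
    "propagate_bdna_frames",
    "wrap_superhelix",
    "superhelix_origins",
    "superhelix_arc_length",
    "superhelix_centroid_offset",
    "place_atoms",
    "phase_angle",
]

_ORTHO_TOL = 1e-9


def _as_vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValidationError(f"expected a 3-vector, got shape {a.shape}")
    return a


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValidationError("cannot normalise a zero vector")
    return v / n


@dataclass(frozen=True)
class Frame:
    """A right-handed orthonormal frame: origin plus axes e1, e2, e3 (nm).

    Construction does not validate (frames are produced in bulk along
    paths); call :meth:`validate` to assert orthonormality and
    handedness to 1e-9.
    """

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec(self.origin))
        object.__setattr__(self, "e1", _as_vec(self.e1))
        object.__setattr__(self, "e2", _as_vec(self.e2))
        object.__setattr__(self, "e3", _as_vec(self.e3))

    @staticmethod
    def identity() -> "Frame":
        return Frame(np.zeros(3), np.array([1.0, 0, 0]),
                     np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose columns are e1, e2, e3."""
        return np.column_stack([self.e1, self.e2, self.e3])

    @classmethod
    def from_rotation(cls, origin, R: np.ndarray) -> "Frame":
        return cls(origin, R[:, 0], R[:, 1], R[:, 2])

    def to_world(self, local) -> np.ndarray:
        """Map local coordinates (3,) or (n, 3) into world coordinates."""
        local = np.asarray(local, dtype=float)
        return self.origin + local @ self.rotation.T

    def rotated_about(self, axis, angle_rad: float) -> "Frame":
        """Rotate the axes (not the origin) about a world-space unit axis."""
        R = _rodrigues(_unit(_as_vec(axis)), angle_rad)
        return Frame(self.origin, R @ self.e1, R @ self.e2, R @ self.e3)

    def translated(self, delta) -> "Frame":
        return replace(self, origin=self.origin + _as_vec(delta))

    def validate(self, tol: float = _ORTHO_TOL) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=tol):
            raise ValidationError("frame axes are not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValidationError("frame is not right-handed")

    def is_close(self, other: "Frame", tol: float = 1e-9) -> bool:
        return (np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.rotation, other.rotation, atol=tol))


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues formula)."""
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@dataclass(frozen=True)
class HelixParams:
    """Ideal B-DNA double-helix parameters.

    rise_nm
        Axial rise per base-pair step (0.34 nm, canonical B form).
    bp_per_turn
        Helical repeat in bp per 360 degrees (10.5, solution value).
    handedness
        ``"right"`` (B-DNA) or ``"left"``.
    """

    rise_nm: float = 0.34
    bp_per_turn: float = 10.5
    handedness: str = "right"

    def __post_init__(self):
        if self.rise_nm <= 0:
            raise ValidationError("rise_nm must be > 0")
        if self.bp_per_turn <= 0:
            raise ValidationError("bp_per_turn must be > 0")
        if self.handedness not in ("right", "left"):
            raise ValidationError("handedness must be 'right' or 'left'")

    @property
    def twist_rad(self) -> float:
        s = 1.0 if self.handedness == "right" else -1.0
        return s * 2.0 * np.pi / self.bp_per_turn


@dataclass(frozen=True)
class SuperhelixParams:
    """Nucleosomal DNA superhelix: ~147 bp in ~1.65 left-handed turns
    around the histone octamer, radius 4.18 nm, pitch 2.39 nm
    (canonical core-particle crystal values; all configurable)."""

    radius_nm: float = 4.18
    pitch_nm: float = 2.39
    turns: float = 1.65
    wrap_bp: int = 147
    handedness: str = "left"

    def __post_init__(self):
        if self.radius_nm <= 0:
            raise ValidationError("radius_nm must be > 0")
        if self.turns <= 0:
            raise ValidationError("turns must be > 0")
        if self.wrap_bp < 2:
            raise ValidationError("wrap_bp must be >= 2")
        if self.handedness not in ("right", "left"):
            raise ValidationError("handedness must be 'right' or 'left'")


@dataclass(frozen=True)
class TemplateEntry:
    name: str
    element: str
    offset: np.ndarray  # bp-local frame coordinates, nm
    strand_tag: str  # "W" (Watson) or "C" (Crick)

    def __post_init__(self):
        if len(self.name) > 4:
            raise ValidationError("atom names are limited to 4 characters")
        if self.strand_tag not in ("W", "C"):
            raise ValidationError("strand_tag must be 'W' or 'C'")
        object.__setattr__(self, "offset", _as_vec(self.offset))


@dataclass(frozen=True)
class AtomTemplate:
    """Ordered pseudo-atom offsets applied in every bp's local frame."""

    entries: tuple

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))

    def __len__(self):
        return len(self.entries)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([e.offset for e in self.entries])


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray  # nm, world coordinates
    bp_index: int
    strand_tag: str
    base: str = "N"

    def __post_init__(self):
        if self.bp_index < 0:
            raise ValidationError("bp_index must be >= 0")
        object.__setattr__(self, "position", _as_vec(self.position))


# Reduced two-strand representation: 10 pseudo-atoms per strand per bp
# (phosphate, sugar-ring and base pseudo-atoms), 20 per bp total.  The
# radial/azimuthal layout sketches a B-DNA cross-section; it is display
# geometry, not chemistry, and is fully user-replaceable.
_STRAND_LAYOUT = [
    # name element radius_nm d_azimuth_deg z_nm
    ("P", "P", 0.94, 0.0, 0.00),
    ("OP", "O", 0.90, 6.0, 0.02),
    ("O5'", "O", 0.86, 12.0, 0.03),
    ("C5'", "C", 0.82, 18.0, 0.04),
    ("C4'", "C", 0.76, 24.0, 0.04),
    ("O4'", "O", 0.72, 30.0, 0.03),
    ("C3'", "C", 0.70, 36.0, 0.02),
    ("C2'", "C", 0.66, 42.0, 0.01),
    ("C1'", "C", 0.60, 48.0, 0.00),
    ("BA", "N", 0.25, 60.0, 0.00),
]

_MINOR_GROOVE_DEG = 154.0  # azimuthal separation of the two backbones


def default_atom_template() -> AtomTemplate:
    """The default 20-entry (10 per strand) reduced bp template."""
    entries = []
    for tag, sign, base_az in (("W", 1.0, _MINOR_GROOVE_DEG / 2),
                               ("C", -1.0, _MINOR_GROOVE_DEG / 2)):
        for name, elem, r, daz, z in _STRAND_LAYOUT:
            az = np.deg2rad(sign * (base_az + daz))
            off = np.array([r * np.cos(az), r * np.sin(az), sign * z])
            entries.append(TemplateEntry(name, elem, off, tag))
    return AtomTemplate(tuple(entries))


def propagate_bdna_frames(n_bp: int, start: Frame,
                          params: HelixParams = HelixParams()) -> list:
    """Frames for ``n_bp`` base pairs of straight ideal B-DNA.

    Frame ``i`` sits ``i * rise_nm`` along ``start.e3`` and is twisted
    about e3 by ``i * 360 / bp_per_turn`` degrees relative to ``start``.
    """
    if n_bp < 1:
        raise ValidationError("n_bp must be >= 1")
    i = np.arange(n_bp)
    theta = params.twist_rad * i
    c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
    e1 = c * start.e1 + s * start.e2
    e2 = -s * start.e1 + c * start.e2
    origins = start.origin + np.outer(i * params.rise_nm, start.e3)
    return [Frame(origins[k], e1[k], e2[k], start.e3)
            for k in range(n_bp)]


def _superhelix_arrays(params: SuperhelixParams, anchor: Frame):
    """Origins, tangents and angles of the superhelical bp path.

    ``anchor.origin`` is a point on the superhelix cylinder axis at the
    axial midpoint of the wrap; ``anchor.e3`` is the cylinder axis.
    """
    n = params.wrap_bp
    u = np.arange(n) / (n - 1)
    sign = -1.0 if params.handedness == "left" else 1.0
    sweep = params.turns * 2.0 * np.pi
    phi = sign * sweep * u
    z = (u - 0.5) * params.turns * params.pitch_nm

    cphi, sphi = np.cos(phi), np.sin(phi)
    radial = cphi[:, None] * anchor.e1 + sphi[:, None] * anchor.e2
    origins = (anchor.origin + params.radius_nm * radial
               + z[:, None] * anchor.e3)
    # d(position)/du, constant speed along u hence uniform arc spacing
    dphi = sign * sweep
    d_rad = (-sphi * dphi)[:, None] * anchor.e1 + (cphi * dphi)[:, None] * anchor.e2
    tangents = params.radius_nm * d_rad + (params.turns * params.pitch_nm) * anchor.e3
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    return origins, tangents, radial


def superhelix_origins(params: SuperhelixParams, anchor: Frame) -> np.ndarray:
    """(wrap_bp, 3) array of bp origins; fast path used by the builder."""
    return _superhelix_arrays(params, anchor)[0]


def superhelix_arc_length(params: SuperhelixParams) -> float:
    """Closed-form helical arc length of the full wrap."""
    return params.turns * float(np.hypot(2 * np.pi * params.radius_nm,
                                         params.pitch_nm))


def superhelix_centroid_offset(params: SuperhelixParams) -> np.ndarray:
    """Centroid of the wrapped bp origins, in anchor-frame coordinates.

    Over a non-integer number of turns the centroid does not coincide
    with the cylinder axis; the builder uses this fixed offset to anchor
    nucleosome records at their bp centroid.
    """
    origins = superhelix_origins(params, Frame.identity())
    return origins.mean(axis=0)


def wrap_superhelix(params: SuperhelixParams, anchor: Frame,
                    helix: HelixParams = HelixParams()) -> list:
    """Frames of one nucleosome wrap around ``anchor``.

    Every origin lies at ``radius_nm`` from the cylinder axis
    (``anchor.origin`` + span of ``anchor.e3``); bp are uniformly spaced
    in arc length over a total sweep of ``turns * 360`` degrees and an
    axial extent ``turns * pitch_nm`` centred on the anchor.  Each
    frame's e3 is the local path tangent; e1 starts radially inward and
    the frame twists about the tangent by ``360 / helix.bp_per_turn``
    degrees per bp.
    """
    origins, tangents, radial = _superhelix_arrays(params, anchor)
    n = params.wrap_bp
    frames = []
    for k in range(n):
        t = tangents[k]
        inward = -radial[k]
        e1 = _unit(inward - np.dot(inward, t) * t)
        e2 = np.cross(t, e1)
        twist = helix.twist_rad * k
        R = _rodrigues(t, twist)
        frames.append(Frame(origins[k], R @ e1, R @ e2, t))
    return frames


def place_atoms(frames: Sequence[Frame], template: AtomTemplate,
                bases: Optional[str] = None) -> list:
    """Instantiate the template in every bp frame.

    Output is bp-major, template-order minor: len(frames) * len(template)
    atoms.  ``bases``, when given, must match ``frames`` in length and
    labels each bp's atoms; otherwise bases are ``"N"``.
    """
    if bases is not None and len(bases) != len(frames):
        raise ValidationError(
            f"bases length {len(bases)} != number of frames {len(frames)}")
    atoms = []
    offs = template.offsets
    for i, fr in enumerate(frames):
        world = fr.to_world(offs)
        base = bases[i] if bases is not None else "N"
        for j, entry in enumerate(template.entries):
            atoms.append(Atom(entry.name, entry.element, world[j], i,
                              entry.strand_tag, base))
    return atoms


def phase_angle(bp_offset: int, params: HelixParams = HelixParams()) -> float:
    """Rotational phase of a bp relative to offset 0, in [0, 360) degrees.

    For a bp inside a nucleosome wrap this is its helical azimuth
    relative to the first wrapped bp — the quantity that decides whether
    e.g. a SNP faces the histone surface or the solvent.
    """
    if bp_offset < 0:
        raise ValidationError("bp_offset must be >= 0")
    return float((bp_offset * 360.0 / params.bp_per_turn) % 360.0)
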