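"""Compressed-XML persistence of the three stored scales.

At full atomic detail a human genome would need roughly
3e9 bp x 20 atoms/bp x 3 coordinates x 4 bytes of storage.  Instead the
store keeps only the nuclear, fiber and nucleosome scales per
chromosome — the DNA scale is always re-synthesised on demand — which
shrinks a whole-genome model by several hundred fold.

Layout of a model directory::

    manifest.xml                 uncompressed index + parameters
    <chrom>.<scale>.xml.gz       payloads, one per chromosome and scale

Each payload is a sequence of independently decompressible gzip members
("blocks") of at most 10,000 elements; the manifest records every
block's byte offset and bp span so a genomic range can be loaded
without decoding the whole file.  Numeric payload fields are written
with fixed 3-decimal precision (nm) and no timestamps, so writing the
same model twice yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import gzip
import math
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional

import numpy as np

from .builder import (SCALES, BuilderConfig, ChromosomeModel, FiberPath,
                      GenomeModel, GenomicRange, NuclearParams, NuclearPath,
                      NucleosomeRecord)
from .errors import (GenomicRangeError, StoreDecodeError, StoreError,
                     StoreVersionError, ValidationError)
from .geometry import Frame, HelixParams, SuperhelixParams

__all__ = [
    "StorageParams",
    "StoreManifest",
    "ModelStore",
    "PathPoint",
    "write_model",
    "read_model",
    "load_range",
    "naive_bytes",
    "storage_stats",
]

FORMAT_VERSION = "1"
BLOCK_ELEMENTS = 10_000
_GZIP_LEVEL = 6
_FMT = "%.3f"  # nm, +-0.5 pm quantisation


@dataclass(frozen=True)
class StorageParams:
    """Factors of the naive whole-genome atomic-storage estimate."""

    genome_bp: int = 3_000_000_000
    atoms_per_bp: int = 20
    coords_per_atom: int = 3
    bytes_per_coord: int = 4

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"{f.name} must be a positive integer")


def naive_bytes(params: StorageParams = StorageParams()) -> int:
    """Bytes needed to store every atom coordinate explicitly."""
    return (params.genome_bp * params.atoms_per_bp
            * params.coords_per_atom * params.bytes_per_coord)


@dataclass
class BlockInfo:
    offset: int
    nbytes: int
    bp_start: int
    bp_end: int
    count: int


@dataclass
class ScaleEntry:
    kind: str
    filename: str
    nbytes: int
    count: int
    blocks: List[BlockInfo]


@dataclass
class ChromEntry:
    name: str
    length_bp: int
    leading_bp: int
    loop_boundaries: List[tuple]
    nuclear_seed: int
    bp_per_fiber_point: int
    scales: Dict[str, ScaleEntry]


@dataclass
class StoreManifest:
    version: str
    name: str
    config: BuilderConfig
    chromosomes: Dict[str, ChromEntry]


class PathPoint(NamedTuple):
    """A nuclear- or fiber-scale element with its bp span."""

    index: int
    bp_start: int
    bp_end: int
    point: np.ndarray


# --------------------------------------------------------------------------
# config <-> attribute flattening


def _config_attrs(cfg: BuilderConfig) -> Dict[str, str]:
    n, s, h = cfg.nuclear, cfg.superhelix, cfg.helix
    return {
        "seed": str(cfg.seed),
        "bp_per_fiber_point": str(cfg.bp_per_fiber_point),
        "fiber_jitter_nm": repr(cfg.fiber_jitter_nm),
        "fiber_radius_nm": repr(cfg.fiber_radius_nm),
        "nucleosome_repeat_bp": str(cfg.nucleosome_repeat_bp),
        "nucleosomes_per_turn": repr(cfg.nucleosomes_per_turn),
        "solenoid_radius_nm": repr(cfg.solenoid_radius_nm),
        "nuclear_loop_size_bp": str(n.loop_size_bp),
        "nuclear_step_bp": str(n.step_bp),
        "nuclear_step_length_nm": repr(n.step_length_nm),
        "nuclear_radius_nm": repr(n.nucleus_radius_nm),
        "nuclear_seed": str(n.seed),
        "nuclear_close_loops": str(int(n.close_loops)),
        "superhelix_radius_nm": repr(s.radius_nm),
        "superhelix_pitch_nm": repr(s.pitch_nm),
        "superhelix_turns": repr(s.turns),
        "superhelix_wrap_bp": str(s.wrap_bp),
        "superhelix_handedness": s.handedness,
        "helix_rise_nm": repr(h.rise_nm),
        "helix_bp_per_turn": repr(h.bp_per_turn),
        "helix_handedness": h.handedness,
    }


def _config_from_attrs(a: Dict[str, str]) -> BuilderConfig:
    nuclear = NuclearParams(
        loop_size_bp=int(a["nuclear_loop_size_bp"]),
        step_bp=int(a["nuclear_step_bp"]),
        step_length_nm=float(a["nuclear_step_length_nm"]),
        nucleus_radius_nm=float(a["nuclear_radius_nm"]),
        seed=int(a["nuclear_seed"]),
        close_loops=bool(int(a["nuclear_close_loops"])))
    superhelix = SuperhelixParams(
        radius_nm=float(a["superhelix_radius_nm"]),
        pitch_nm=float(a["superhelix_pitch_nm"]),
        turns=float(a["superhelix_turns"]),
        wrap_bp=int(a["superhelix_wrap_bp"]),
        handedness=a["superhelix_handedness"])
    helix = HelixParams(
        rise_nm=float(a["helix_rise_nm"]),
        bp_per_turn=float(a["helix_bp_per_turn"]),
        handedness=a["helix_handedness"])
    return BuilderConfig(
        nuclear=nuclear,
        bp_per_fiber_point=int(a["bp_per_fiber_point"]),
        fiber_jitter_nm=float(a["fiber_jitter_nm"]),
        fiber_radius_nm=float(a["fiber_radius_nm"]),
        nucleosome_repeat_bp=int(a["nucleosome_repeat_bp"]),
        nucleosomes_per_turn=float(a["nucleosomes_per_turn"]),
        solenoid_radius_nm=float(a["solenoid_radius_nm"]),
        superhelix=superhelix, helix=helix, seed=int(a["seed"]))


# --------------------------------------------------------------------------
# element serialisation


def _point_xml(anchor: int, p: np.ndarray) -> str:
    return (f'<p a="{anchor}" x="{_FMT % p[0]}" y="{_FMT % p[1]}" '
            f'z="{_FMT % p[2]}"/>')


def _record_xml(r: NucleosomeRecord) -> str:
    f = r.frame
    nums = " ".join(_FMT % v for v in
                    (*f.origin, *f.e1, *f.e2, *f.e3))
    return f'<n s="{r.start_bp}" l="{r.linker_bp_after}" f="{nums}"/>'


def _scale_elements(chrom: ChromosomeModel, kind: str):
    """(xml_string, bp_start) per element, plus the span end per element."""
    if kind == "nucleosome":
        for r in chrom.nucleosomes:
            yield _record_xml(r), r.start_bp, r.span_end_bp
    else:
        path = chrom.nuclear if kind == "nuclear" else chrom.fiber
        anchors = path.bp_anchors
        n = len(anchors)
        for i in range(n):
            end = int(anchors[i + 1]) if i + 1 < n else chrom.length_bp
            yield _point_xml(int(anchors[i]), path.points[i]), int(anchors[i]), end


def _write_scale_file(path: str, chrom: ChromosomeModel, kind: str) -> ScaleEntry:
    blocks: List[BlockInfo] = []
    offset = 0
    count = 0
    items = list(_scale_elements(chrom, kind))
    with open(path, "wb") as fh:
        for b0 in range(0, max(len(items), 1), BLOCK_ELEMENTS):
            chunk = items[b0:b0 + BLOCK_ELEMENTS]
            if not chunk and items:
                break
            body = "".join(s for s, _, _ in chunk)
            data = f'<block kind="{kind}" first="{b0}">{body}</block>'.encode()
            member = gzip.compress(data, _GZIP_LEVEL, mtime=0)
            fh.write(member)
            bp_start = chunk[0][1] if chunk else 0
            bp_end = chunk[-1][2] if chunk else 0
            blocks.append(BlockInfo(offset, len(member), bp_start, bp_end,
                                    len(chunk)))
            offset += len(member)
            count += len(chunk)
            if not items:
                break
    return ScaleEntry(kind, os.path.basename(path), offset, count, blocks)


# --------------------------------------------------------------------------
# write / read


def write_model(model: GenomeModel, directory) -> StoreManifest:
    """Serialise all three stored scales plus an uncompressed manifest.

    Writing is deterministic: equal models produce byte-identical
    directories.
    """
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    chrom_entries: Dict[str, ChromEntry] = {}
    for name, chrom in model.chromosomes.items():
        scales: Dict[str, ScaleEntry] = {}
        for kind in SCALES:
            fname = f"{name}.{kind}.xml.gz"
            scales[kind] = _write_scale_file(os.path.join(directory, fname),
                                             chrom, kind)
        chrom_entries[name] = ChromEntry(
            name, chrom.length_bp, chrom.leading_bp,
            list(chrom.nuclear.loop_boundaries), chrom.nuclear.seed,
            chrom.fiber.bp_per_point, scales)

    manifest = StoreManifest(FORMAT_VERSION, model.name, model.config,
                             chrom_entries)
    root = ET.Element("nucleome-model", version=FORMAT_VERSION,
                      name=model.name)
    ET.SubElement(root, "config", _config_attrs(model.config))
    for name, ce in chrom_entries.items():
        loops = ";".join(f"{a}:{b}" for a, b in ce.loop_boundaries)
        ch = ET.SubElement(root, "chromosome", name=name,
                           length=str(ce.length_bp),
                           leading=str(ce.leading_bp), loops=loops,
                           seed=str(ce.nuclear_seed),
                           bp_per_fiber_point=str(ce.bp_per_fiber_point))
        for kind in SCALES:
            se = ce.scales[kind]
            sc = ET.SubElement(ch, "scale", kind=kind, file=se.filename,
                               bytes=str(se.nbytes), count=str(se.count))
            for b in se.blocks:
                ET.SubElement(sc, "block", offset=str(b.offset),
                              bytes=str(b.nbytes), bp_start=str(b.bp_start),
                              bp_end=str(b.bp_end), count=str(b.count))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(os.path.join(directory, "manifest.xml"),
               encoding="utf-8", xml_declaration=True)
    return manifest


def _parse_manifest(path: str) -> StoreManifest:
    try:
        root = ET.parse(path).getroot()
    except (ET.ParseError, OSError) as e:
        raise StoreError(f"cannot read manifest {path}: {e}") from None
    version = root.get("version")
    if version != FORMAT_VERSION:
        raise StoreVersionError(
            f"store format version {version!r} is not supported "
            f"(expected {FORMAT_VERSION})")
    cfg = _config_from_attrs(root.find("config").attrib)
    chroms: Dict[str, ChromEntry] = {}
    for ch in root.findall("chromosome"):
        scales: Dict[str, ScaleEntry] = {}
        for sc in ch.findall("scale"):
            blocks = [BlockInfo(int(b.get("offset")), int(b.get("bytes")),
                                int(b.get("bp_start")), int(b.get("bp_end")),
                                int(b.get("count")))
                      for b in sc.findall("block")]
            scales[sc.get("kind")] = ScaleEntry(
                sc.get("kind"), sc.get("file"), int(sc.get("bytes")),
                int(sc.get("count")), blocks)
        if set(scales) != set(SCALES):
            raise StoreError(
                f"chromosome {ch.get('name')} lacks a scale entry")
        loops = [tuple(int(x) for x in part.split(":"))
                 for part in ch.get("loops", "").split(";") if part]
        chroms[ch.get("name")] = ChromEntry(
            ch.get("name"), int(ch.get("length")), int(ch.get("leading")),
            loops, int(ch.get("seed")), int(ch.get("bp_per_fiber_point")),
            scales)
    return StoreManifest(version, root.get("name"), cfg, chroms)


def _parse_points(block_xml: bytes) -> List[tuple]:
    el = ET.fromstring(block_xml)
    return [(int(p.get("a")),
             np.array([float(p.get("x")), float(p.get("y")),
                       float(p.get("z"))]))
            for p in el.iter("p")]


def _parse_records(block_xml: bytes) -> List[NucleosomeRecord]:
    el = ET.fromstring(block_xml)
    out = []
    for n in el.iter("n"):
        v = np.array([float(x) for x in n.get("f").split()])
        frame = Frame(v[0:3], v[3:6], v[6:9], v[9:12])
        out.append(NucleosomeRecord(int(n.get("s")), frame, int(n.get("l"))))
    return out


class ModelStore:
    """Lazy view over an on-disk model directory.

    The manifest is parsed eagerly; each (chromosome, scale) payload is
    read on first access.  ``access_log`` records every payload file
    opened, in order — useful for verifying the laziness contract.
    """

    def __init__(self, directory: str, manifest: StoreManifest):
        self.directory = directory
        self.manifest = manifest
        self.access_log: List[str] = []
        self._cache: Dict[tuple, object] = {}

    @property
    def config(self) -> BuilderConfig:
        return self.manifest.config

    @property
    def chromosome_names(self) -> List[str]:
        return list(self.manifest.chromosomes)

    def _chrom_entry(self, chrom: str) -> ChromEntry:
        try:
            return self.manifest.chromosomes[chrom]
        except KeyError:
            raise GenomicRangeError(f"unknown chromosome {chrom!r}") from None

    def _read_blocks(self, chrom: str, kind: str,
                     blocks: Optional[List[BlockInfo]] = None) -> List[bytes]:
        entry = self._chrom_entry(chrom).scales[kind]
        path = os.path.join(self.directory, entry.filename)
        if not os.path.exists(path):
            raise StoreError(f"missing payload file {entry.filename}")
        self.access_log.append(entry.filename)
        use = blocks if blocks is not None else entry.blocks
        out = []
        with open(path, "rb") as fh:
            for b in use:
                fh.seek(b.offset)
                raw = fh.read(b.nbytes)
                try:
                    out.append(gzip.decompress(raw))
                except (OSError, EOFError) as e:
                    raise StoreDecodeError(
                        f"corrupt payload for {chrom}/{kind} "
                        f"({entry.filename}): {e}") from None
        return out

    def _load_scale(self, chrom: str, kind: str):
        key = (chrom, kind)
        if key in self._cache:
            return self._cache[key]
        ce = self._chrom_entry(chrom)
        payloads = self._read_blocks(chrom, kind)
        try:
            if kind == "nucleosome":
                recs: List[NucleosomeRecord] = []
                for raw in payloads:
                    recs.extend(_parse_records(raw))
                self._cache[key] = recs
            else:
                pts: List[tuple] = []
                for raw in payloads:
                    pts.extend(_parse_points(raw))
                anchors = np.array([a for a, _ in pts], dtype=np.int64)
                arr = np.array([p for _, p in pts])
                if kind == "nuclear":
                    self._cache[key] = NuclearPath(arr, anchors,
                                                   ce.loop_boundaries,
                                                   ce.nuclear_seed)
                else:
                    self._cache[key] = FiberPath(arr, anchors,
                                                 ce.bp_per_fiber_point)
        except (ET.ParseError, ValueError, IndexError) as e:
            raise StoreDecodeError(
                f"corrupt payload for {chrom}/{kind}: {e}") from None
        return self._cache[key]

    def nuclear(self, chrom: str) -> NuclearPath:
        return self._load_scale(chrom, "nuclear")

    def fiber(self, chrom: str) -> FiberPath:
        return self._load_scale(chrom, "fiber")

    def nucleosomes(self, chrom: str) -> List[NucleosomeRecord]:
        return self._load_scale(chrom, "nucleosome")

    def chromosome_model(self, chrom: str) -> ChromosomeModel:
        ce = self._chrom_entry(chrom)
        return ChromosomeModel(chrom, ce.length_bp, self.nuclear(chrom),
                               self.fiber(chrom), self.nucleosomes(chrom),
                               ce.leading_bp)

    def to_model(self) -> GenomeModel:
        """Eagerly load every chromosome into a GenomeModel."""
        chroms = {name: self.chromosome_model(name)
                  for name in self.chromosome_names}
        return GenomeModel(self.manifest.name, self.config, chroms)

    def stored_bytes(self) -> int:
        return sum(se.nbytes
                   for ce in self.manifest.chromosomes.values()
                   for se in ce.scales.values())

    def modeled_bp(self) -> int:
        return sum(ce.length_bp for ce in self.manifest.chromosomes.values())


def read_model(directory) -> ModelStore:
    """Open a model directory; payloads load lazily on access."""
    directory = str(directory)
    manifest_path = os.path.join(directory, "manifest.xml")
    if not os.path.exists(manifest_path):
        raise StoreError(f"missing manifest.xml in {directory}")
    return ModelStore(directory, _parse_manifest(manifest_path))


def load_range(store: ModelStore, grange: GenomicRange, scale: str):
    """Elements of one scale whose bp span intersects ``grange``.

    Uses the manifest's per-block bp index so only the intersecting
    blocks are decompressed.
    """
    if scale not in SCALES:
        raise ValidationError(f"unknown scale {scale!r}")
    ce = store._chrom_entry(grange.chrom)
    entry = ce.scales[scale]
    hit = [b for b in entry.blocks
           if b.bp_start < grange.end and b.bp_end > grange.start]
    payloads = store._read_blocks(grange.chrom, scale, hit) if hit else []
    if scale == "nucleosome":
        out = []
        for raw in payloads:
            try:
                recs = _parse_records(raw)
            except (ET.ParseError, ValueError) as e:
                raise StoreDecodeError(
                    f"corrupt payload for {grange.chrom}/{scale}: {e}"
                ) from None
            out.extend(r for r in recs
                       if r.start_bp < grange.end
                       and r.span_end_bp > grange.start)
        return out
    pts = []
    for bi, raw in zip(hit, payloads):
        try:
            parsed = _parse_points(raw)
        except (ET.ParseError, ValueError) as e:
            raise StoreDecodeError(
                f"corrupt payload for {grange.chrom}/{scale}: {e}") from None
        for j, (anchor, p) in enumerate(parsed):
            end = parsed[j + 1][0] if j + 1 < len(parsed) else bi.bp_end
            pts.append(PathPoint(0, anchor, end, p))
    return [PathPoint(i, p.bp_start, p.bp_end, p.point)
            for i, p in enumerate(pts)
            if p.bp_start < grange.end and p.bp_end > grange.start]


def storage_stats(store: ModelStore,
                  params: StorageParams = StorageParams()) -> Dict[str, float]:
    """Compression accounting for a store versus naive atomic storage.

    Extrapolates the store's bytes/bp to ``params.genome_bp`` and
    divides the naive estimate by that figure.
    """
    if not store.manifest.chromosomes:
        raise StoreError("store contains no chromosomes")
    stored = store.stored_bytes()
    bp = store.modeled_bp()
    per_bp = stored / bp
    extrapolated = per_bp * params.genome_bp
    return {
        "stored_bytes": stored,
        "stored_bytes_per_bp": per_bp,
        "extrapolated_genome_bytes": extrapolated,
        "compression_ratio": naive_bytes(params) / extrapolated,
    }
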