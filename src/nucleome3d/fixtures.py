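"""Seeded generators for every input the toolkit consumes.

These emulate, statistically, the kinds of public datasets a user would
project onto a genome model — chromosome length tables, genome-wide
nucleosome position lists, SNP sets, signal tracks, TSS/expression
tables and transcription-factor binding sites — so that every demo and
test runs without downloads.  All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import BedInterval, WigTrack
from .errors import ValidationError

__all__ = [
    "FixtureSpec",
    "TrackBundle",
    "synth_genome",
    "synth_fasta",
    "synth_nucleosome_positions",
    "synth_tracks",
    "write_lengths_table",
]

_MIN_REPEAT = 157  # 147 bp wrap + a 10 bp minimal linker


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate and at what scale.

    near_fraction controls the planted fraction of binding sites within
    ``proximity_threshold_bp`` of a TSS, so proximity classification
    always sees both classes.
    """

    seed: int = 0
    chrom_count: int = 1
    chrom_length_bp: int = 1_000_000
    chrom_length_sd: float = 0.0
    nucleosome_repeat_bp: int = 200
    repeat_jitter_sd: float = 0.0
    snp_count: int = 10
    tss_count: int = 20
    binding_site_count: int = 40
    near_fraction: float = 0.5
    proximity_threshold_bp: int = 10_000
    expression_sd: float = 1.0
    wig_point_count: int = 100

    def __post_init__(self):
        if self.chrom_count < 0 or self.snp_count < 0:
            raise ValidationError("counts must be >= 0")
        if self.chrom_count and self.chrom_length_bp < self.nucleosome_repeat_bp:
            raise ValidationError("chromosomes must hold >= 1 repeat")
        if not 0.0 <= self.near_fraction <= 1.0:
            raise ValidationError("near_fraction must be in [0, 1]")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def synth_genome(spec: FixtureSpec) -> List[Tuple[str, int]]:
    """Chromosome (name, length) table; lengths vary by a seeded normal."""
    rng = _rng(spec.seed, 0)
    out = []
    for i in range(spec.chrom_count):
        length = spec.chrom_length_bp
        if spec.chrom_length_sd > 0:
            length = int(round(rng.normal(spec.chrom_length_bp,
                                          spec.chrom_length_sd)))
            length = max(length, spec.nucleosome_repeat_bp)
        out.append((f"chr{i + 1}", length))
    return out


def synth_fasta(lengths: Sequence[Tuple[str, int]], seed: int = 0,
                line_width: int = 60) -> str:
    """Random ACGT FASTA text matching a length table."""
    rng = _rng(seed, 99)
    chunks = []
    alphabet = np.array(list("ACGT"))
    for name, length in lengths:
        seq = "".join(alphabet[rng.integers(0, 4, size=length)])
        body = "\n".join(seq[i:i + line_width]
                         for i in range(0, length, line_width))
        chunks.append(f">{name}\n{body}\n")
    return "".join(chunks)


def write_lengths_table(lengths: Sequence[Tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        for name, length in lengths:
            fh.write(f"{name}\t{length}\n")


def synth_nucleosome_positions(chrom_length: int, repeat_mean: int = 200,
                               jitter_sd: float = 0.0,
                               seed: int = 0) -> List[int]:
    """Nucleosome start positions with truncated-normal repeat jitter.

    Repeats are drawn from N(repeat_mean, jitter_sd) truncated
    symmetrically (so the mean is unbiased) and never below 157 bp,
    which keeps successive starts >= 147 bp apart.  jitter_sd = 0 gives
    exact periodic tiling.
    """
    if repeat_mean < _MIN_REPEAT:
        raise ValidationError(
            f"repeat_mean must be >= {_MIN_REPEAT} (147 bp wrap + linker)")
    rng = _rng(seed, 7)
    half_width = min(3.0 * jitter_sd, repeat_mean - _MIN_REPEAT)
    starts = []
    pos = 0
    while pos + 147 <= chrom_length - (repeat_mean - 147):
        starts.append(pos)
        if jitter_sd > 0 and half_width > 0:
            while True:
                rep = rng.normal(repeat_mean, jitter_sd)
                if abs(rep - repeat_mean) <= half_width:
                    break
            rep = int(round(rep))
        else:
            rep = repeat_mean
        pos += max(rep, _MIN_REPEAT)
    return starts


@dataclass
class TrackBundle:
    """All Fig-style demo tracks for one chromosome."""

    snps: List[BedInterval]
    tss: List[BedInterval]
    sites: List[BedInterval]
    wig: WigTrack
    expression: Dict[str, float]   # gene name -> signed log-ratio


def synth_tracks(spec: FixtureSpec, chrom: str,
                 chrom_length: int) -> TrackBundle:
    """SNPs, TSSs, binding sites, a WIG score track and expression values.

    A ``near_fraction`` of binding sites is planted within the proximity
    threshold of some TSS; the rest are rejection-sampled to be at least
    the threshold away from every TSS.  Expression log-ratios are drawn
    from a zero-mean normal.
    """
    rng = _rng(spec.seed, 11)
    thr = spec.proximity_threshold_bp

    snp_pos = np.sort(rng.choice(chrom_length, size=min(spec.snp_count,
                                                        chrom_length),
                                 replace=False))
    snps = [BedInterval(chrom, int(p), int(p) + 1, f"rs{i:06d}")
            for i, p in enumerate(snp_pos)]

    tss_pos = np.sort(rng.choice(
        np.arange(thr, max(chrom_length - thr, thr + 1)),
        size=min(spec.tss_count, max(chrom_length - 2 * thr, 1)),
        replace=False))
    tss = [BedInterval(chrom, int(p), int(p) + 1, f"gene{i:04d}")
           for i, p in enumerate(tss_pos)]

    sites = []
    for i in range(spec.binding_site_count):
        near = rng.random() < spec.near_fraction and len(tss_pos) > 0
        if near:
            center = int(rng.choice(tss_pos))
            offset = int(rng.integers(-(thr - 1), thr))
            mid = int(np.clip(center + offset, 10, chrom_length - 11))
            # clipping can only move the midpoint closer to the TSS
        else:
            for _ in range(10_000):
                mid = int(rng.integers(10, chrom_length - 10))
                if (len(tss_pos) == 0
                        or np.min(np.abs(tss_pos - mid)) >= thr):
                    break
            else:
                raise ValidationError(
                    "cannot place a far site; chromosome too crowded")
        sites.append(BedInterval(chrom, mid - 10, mid + 10,
                                 f"site{i:04d}"))
    sites.sort(key=lambda s: s.start)

    n_wig = min(spec.wig_point_count, chrom_length // 10 or 1)
    wig_pos = np.sort(rng.choice(chrom_length - 10, size=n_wig,
                                 replace=False))
    wig = WigTrack(chrom, "variableStep", 10, [int(p) for p in wig_pos],
                   [float(v) for v in rng.normal(size=n_wig)])

    expression = {t.name: float(rng.normal(0.0, spec.expression_sd))
                  for t in tss}
    return TrackBundle(snps, tss, sites, wig, expression)
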