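"""Transcription-unit boundary re-annotation and gene-orientation classification.

CDS coordinates underestimate transcription units: transcription starts
upstream of the start codon and ends at a cleavage/polyadenylation site (CPS)
downstream of the stop codon. Each gene's boundaries are therefore redefined
to the closest same-strand +1 nucleosome position upstream of the CDS 5' end
and the closest same-strand CPS downstream of the CDS 3' end, taking only
sites lying outside the original CDS. Genes missing either site are dropped
(and reported) rather than annotated with a guess.

Each re-annotated unit is then classified by its single closest
non-overlapping neighbor (strand-blind, edge-to-edge distance): same strand =
tandem, 5' ends facing across the gap = divergent, 3' ends facing =
convergent; neighbors farther than the closeness cutoff (default 500 bp)
leave the gene unpaired.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .core import (
    PLUS,
    GenomicInterval,
    TranscriptAnnotation,
    read_annotations,
)

logger = logging.getLogger(__name__)

ORIENTATIONS = ("divergent", "convergent", "tandem", "unpaired")

#: A stranded point site: (chrom, position, strand).
Site = tuple[str, int, str]


@dataclass
class TranscriptionUnit:
    """A gene with CDS coordinates and re-annotated transcription-unit bounds."""

    id: str
    cds: GenomicInterval
    tu: GenomicInterval
    plus1: int
    cps: int
    orientation: str = "unpaired"
    feature_class: str = "mRNA"

    def __post_init__(self) -> None:
        if not (self.tu.start <= self.cds.start and self.cds.end <= self.tu.end):
            raise ValueError(f"{self.id}: TU {self.tu} does not contain CDS {self.cds}")

    @property
    def interval(self) -> GenomicInterval:
        return self.tu

    @property
    def strand(self) -> str:
        return self.tu.strand

    @property
    def chrom(self) -> str:
        return self.tu.chrom


def read_point_sites(path: str | Path) -> list[Site]:
    """Read stranded point features (single-base BED records) as sites."""
    feats = read_annotations(path, format="BED")
    return [(f.chrom, f.interval.start, f.strand) for f in feats]


def reannotate_boundaries(
    cds_list: Sequence[TranscriptAnnotation],
    plus1_sites: Sequence[Site],
    cps_sites: Sequence[Site],
    ignore_strand: bool = False,
) -> tuple[list[TranscriptionUnit], list[tuple[str, str]]]:
    """Redefine gene boundaries from +1 nucleosome and CPS point sites.

    For each CDS, the 5' boundary becomes the closest same-strand +1 site
    strictly upstream of (outside) the CDS, and the 3' boundary the closest
    same-strand CPS strictly downstream of (outside) the CDS. Returns the
    re-annotated units and a report of dropped genes as (id, reason) pairs.
    """
    if not plus1_sites or not cps_sites:
        logger.warning(
            "empty site list (%d +1 sites, %d CPS sites): every gene will be dropped",
            len(plus1_sites), len(cps_sites),
        )
    p1_sorted = sorted(plus1_sites, key=lambda s: (s[0], s[1]))
    cps_sorted = sorted(cps_sites, key=lambda s: (s[0], s[1]))
    units: list[TranscriptionUnit] = []
    dropped: list[tuple[str, str]] = []
    for gene in cds_list:
        cds = gene.interval
        def _same(sites: Sequence[Site]) -> list[int]:
            return [p for c, p, s in sites
                    if c == cds.chrom and (ignore_strand or s == cds.strand)]
        p1 = _same(p1_sorted)
        cp = _same(cps_sorted)
        if cds.strand == PLUS:
            # upstream of the 5' end / downstream of the 3' end in genome coords
            up = [p for p in p1 if p < cds.start]
            down = [p for p in cp if p >= cds.end]
            plus1 = max(up) if up else None
            cps = min(down) if down else None
            bounds = (plus1, cps) if None not in (plus1, cps) else None
        else:
            up = [p for p in p1 if p >= cds.end]
            down = [p for p in cp if p < cds.start]
            plus1 = min(up) if up else None
            cps = max(down) if down else None
            bounds = (cps, plus1) if None not in (plus1, cps) else None
        if bounds is None:
            reason = "no upstream +1 nucleosome" if plus1 is None else "no downstream CPS"
            dropped.append((gene.id, reason))
            continue
        tu = GenomicInterval(cds.chrom, bounds[0], bounds[1], cds.strand)
        units.append(TranscriptionUnit(
            id=gene.id, cds=cds, tu=tu, plus1=plus1, cps=cps,
        ))
    if dropped:
        logger.warning("dropped %d/%d genes lacking boundary sites",
                       len(dropped), len(cds_list))
    return units, dropped


def _edge_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Edge-to-edge gap between non-overlapping intervals; None if they overlap."""
    if b.start >= a.end:
        return b.start - a.end
    if a.start >= b.end:
        return a.start - b.end
    return None


def classify_orientation(
    tus: Sequence[TranscriptionUnit],
    max_dist: int = 500,
) -> tuple[list[TranscriptionUnit], Counter]:
    """Label each unit by its closest non-overlapping neighbor.

    The neighbor search ignores strand, forbids overlapping calls, and keeps a
    single closest unit (ties go to the first in coordinate-sorted order).
    Genes whose closest neighbor is farther than ``max_dist`` (exclusive:
    distance <= max_dist counts as close), or that have no non-overlapping
    neighbor, are unpaired. Labels are assigned in place; per-label counts are
    returned alongside.
    """
    ordered = sorted(tus, key=lambda u: (u.chrom, u.tu.start, u.tu.end))
    for unit in tus:
        best = None
        best_dist = None
        for other in ordered:
            if other is unit or other.chrom != unit.chrom:
                continue
            d = _edge_distance(unit.tu, other.tu)
            if d is None:
                continue  # overlapping units are never chosen
            if best_dist is None or d < best_dist:
                best, best_dist = other, d
        if best is None or best_dist > max_dist:
            unit.orientation = "unpaired"
        elif best.strand == unit.strand:
            unit.orientation = "tandem"
        else:
            left = unit if unit.tu.start <= best.tu.start else best
            # opposite strands: the gap is flanked by both 3' ends when the
            # left unit points rightwards (+), by both 5' ends otherwise
            unit.orientation = "convergent" if left.strand == PLUS else "divergent"
    counts = Counter(u.orientation for u in tus)
    for label in ORIENTATIONS:
        counts.setdefault(label, 0)
    return list(tus), counts


def write_transcription_units(units: Sequence[TranscriptionUnit], path: str | Path) -> None:
    """Write TUs as BED6 plus plus1, cps and orientation columns."""
    with open(path, "w") as fh:
        for u in units:
            fh.write(
                f"{u.chrom}\t{u.tu.start}\t{u.tu.end}\t{u.id}\t0\t{u.strand}"
                f"\t{u.plus1}\t{u.cps}\t{u.orientation}\n"
            )


def write_orientation_counts(counts: Counter, dropped: int, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tcount\n")
        for label in ORIENTATIONS:
            fh.write(f"{label}\t{counts.get(label, 0)}\n")
        fh.write(f"dropped\t{dropped}\n")
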