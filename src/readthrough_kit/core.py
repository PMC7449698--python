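"""Genomic coordinate model, annotation and coverage I/O, and windowed quantification.

All coordinates are 0-based half-open ``[start, end)`` (BED convention) on named
chromosomes. GFF3 input is converted at the boundary. Coverage is held as dense
per-base depth vectors, one per strand per chromosome, with a lazily applied
multiplicative scale factor so that raw depths survive normalization untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."

FEATURE_CLASSES = {
    "snoRNA", "mRNA", "CUT", "SUT", "XUT", "NUT", "SRAT", "denovo", "other",
}


class CoordinateError(ValueError):
    """Raised for invalid genomic coordinates or unknown chromosomes."""


class ParseError(ValueError):
    """Raised when an annotation or coverage file fails to parse."""


class EmptyWindowError(ValueError):
    """Raised when a requested window is fully clamped away at a chromosome edge."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open stranded interval ``[start, end)`` on a chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open bounds; ``0 <= start < end`` is enforced.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in (PLUS, MINUS, UNSTRANDED):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def five_prime(self) -> int:
        """Coordinate of the 5' end in the direction of transcription."""
        return self.start if self.strand != MINUS else self.end - 1

    def three_prime(self) -> int:
        """Coordinate of the 3' end in the direction of transcription."""
        return self.end - 1 if self.strand != MINUS else self.start


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A named transcribed feature: a stranded interval with a feature class."""

    id: str
    interval: GenomicInterval
    feature_class: str = "other"

    def __post_init__(self) -> None:
        if self.interval.strand == UNSTRANDED:
            raise CoordinateError(
                f"transcribed feature {self.id!r} must be stranded"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class StrandedCoverageTrack:
    """Dense per-base stranded depth with a lazy normalization scale.

    ``depths`` maps chromosome name to a ``(plus, minus)`` pair of float arrays
    whose length equals the chromosome length. ``scale`` multiplies every signal
    read out of the track (1.0 = raw). Depth arrays are never mutated by scaling.
    """

    depths: dict[str, tuple[np.ndarray, np.ndarray]]
    scale: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        for chrom, (plus, minus) in self.depths.items():
            if len(plus) != len(minus):
                raise CoordinateError(f"{chrom}: strand vectors differ in length")
            for arr in (plus, minus):
                if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                    raise CoordinateError(
                        f"{chrom}: depths must be finite and non-negative"
                    )

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int], sample_id: str = "") -> "StrandedCoverageTrack":
        depths = {
            c: (np.zeros(n, dtype=float), np.zeros(n, dtype=float))
            for c, n in chrom_sizes.items()
        }
        return cls(depths=depths, sample_id=sample_id)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(p) for c, (p, _) in self.depths.items()}

    def strand_depth(self, chrom: str, strand: str) -> np.ndarray:
        """Raw (unscaled) depth vector for one strand; zeros if chrom absent."""
        if chrom not in self.depths:
            logger.warning(
                "track %s has no coverage for %s; treating as zero",
                self.sample_id or "<unnamed>", chrom,
            )
            raise KeyError(chrom)
        plus, minus = self.depths[chrom]
        return plus if strand == PLUS else minus


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": int}, comment="#")
    return dict(zip(df["chrom"], df["length"]))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def _dedup_names(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}_{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_annotations(
    path: str | Path,
    format: str = "BED",
    chrom_sizes: Mapping[str, int] | None = None,
    feature_class: str = "other",
) -> list[TranscriptAnnotation]:
    """Read stranded features from BED6 or GFF3.

    BED records pass through unchanged; GFF3 coordinates (1-based inclusive) are
    converted to 0-based half-open. Record order is preserved and duplicate names
    are de-duplicated by suffixing ``_1``, ``_2``, ...

    Parameters
    ----------
    path : path to the annotation file.
    format : ``"BED"`` or ``"GFF3"``.
    chrom_sizes : optional; when given, records on unknown chromosomes raise
        :class:`CoordinateError`.
    feature_class : class label assigned to every record.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown annotation format {format!r}")
    records: list[tuple[str, int, int, str, str]] = []  # chrom,start,end,name,strand
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    if len(fields) < 6:
                        raise ValueError("BED6 needs at least 6 columns")
                    chrom, start, end, name, _score, strand = fields[:6]
                    start, end = int(start), int(end)
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    chrom, _src, _type, start, end, _score, strand, _phase, attrs = fields[:9]
                    start, end = int(start) - 1, int(end)  # 1-based inclusive -> half-open
                    name = _gff3_name(attrs)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            records.append((chrom, start, end, name, strand))
    names = _dedup_names([r[3] for r in records])
    out = []
    for (chrom, start, end, _n, strand), name in zip(records, names):
        if chrom_sizes is not None and chrom not in chrom_sizes:
            raise CoordinateError(f"{path}: unknown chromosome {chrom!r}")
        out.append(TranscriptAnnotation(
            id=name,
            interval=GenomicInterval(chrom, start, end, strand),
            feature_class=feature_class,
        ))
    return out


def _gff3_name(attrs: str) -> str:
    kv = {}
    for part in attrs.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            kv[k.strip()] = v.strip()
    return kv.get("Name") or kv.get("ID") or "feature"


def write_annotations(features: Sequence[TranscriptAnnotation], path: str | Path) -> None:
    """Write features as BED6 (name field = id, score 0)."""
    with open(path, "w") as fh:
        for f in features:
            iv = f.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.id}\t0\t{iv.strand}\n")


# -- coverage I/O -----------------------------------------------------------

def _read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    vectors = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    last_end: dict[str, int] = {}
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str, "start": int, "end": int, "value": float})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in vectors:
            raise CoordinateError(f"{path}: unknown chromosome {chrom!r}")
        if not (0 <= start < end <= chrom_sizes[chrom]):
            raise CoordinateError(
                f"{path}: interval {chrom}:{start}-{end} out of bounds"
            )
        for s, e in spans[chrom]:
            if start < e and s < end:
                raise ParseError(
                    f"{path}: overlapping bedGraph intervals on {chrom} "
                    f"([{s},{e}) and [{start},{end})): depth is ambiguous"
                )
        spans[chrom].append((start, end))
        vectors[chrom][start:end] = value
    return vectors


def read_coverage(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_sizes: Mapping[str, int],
    sample_id: str = "",
) -> StrandedCoverageTrack:
    """Read a pair of per-strand bedGraph files into a dense coverage track.

    Positions absent from the files get depth 0. Overlapping intervals within a
    file are an error (the depth there would be ambiguous).
    """
    plus = _read_bedgraph(plus_path, chrom_sizes)
    minus = _read_bedgraph(minus_path, chrom_sizes)
    depths = {c: (plus[c], minus[c]) for c in chrom_sizes}
    return StrandedCoverageTrack(depths=depths, sample_id=sample_id)


def _write_bedgraph(vectors: Mapping[str, np.ndarray], path: str | Path) -> None:
    # run-length encode each chromosome; zero runs are omitted
    with open(path, "w") as fh:
        for chrom in vectors:
            v = np.asarray(vectors[chrom])
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{val:.6g}\n")


def write_coverage(track: StrandedCoverageTrack, prefix: str | Path) -> tuple[Path, Path]:
    """Write raw depths as ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``.

    The scale factor is *not* baked into the files; they round-trip through
    :func:`read_coverage` bit-identically at interval granularity.
    """
    prefix = Path(prefix)
    plus_path = prefix.with_name(prefix.name + ".plus.bedgraph")
    minus_path = prefix.with_name(prefix.name + ".minus.bedgraph")
    _write_bedgraph({c: p for c, (p, _) in track.depths.items()}, plus_path)
    _write_bedgraph({c: m for c, (_, m) in track.depths.items()}, minus_path)
    return plus_path, minus_path


# -- window geometry and quantification -------------------------------------

def downstream_window(
    feature: TranscriptAnnotation,
    length: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """The ``length`` bp window immediately downstream of a feature's 3' end.

    Downstream is strand-aware: past ``end`` on the plus strand, before ``start``
    on the minus strand. The window is clamped to the chromosome and never
    rescaled; a fully clamped (empty) window raises :class:`EmptyWindowError`.
    """
    if length <= 0:
        raise ValueError("window length must be positive")
    iv = feature.interval
    if iv.strand == MINUS:
        start, end = iv.start - length, iv.start
    else:
        start, end = iv.end, iv.end + length
    start = max(start, 0)
    if chrom_sizes is not None:
        end = min(end, chrom_sizes[iv.chrom])
    if start >= end:
        raise EmptyWindowError(
            f"{feature.id}: downstream window is empty after clamping"
        )
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def region_signal(track: StrandedCoverageTrack, region: GenomicInterval) -> float:
    """Summed per-base depth over a region, times the track's scale factor.

    Stranded regions sum the matching strand only; unstranded regions sum both.
    A chromosome missing from the track contributes zero (logged warning).
    """
    if region.chrom not in track.depths:
        logger.warning(
            "track %s has no coverage for %s; region signal is 0",
            track.sample_id or "<unnamed>", region.chrom,
        )
        return 0.0
    n = track.chrom_sizes[region.chrom]
    if region.end > n:
        raise CoordinateError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {n}"
        )
    plus, minus = track.depths[region.chrom]
    sl = slice(region.start, region.end)
    if region.strand == PLUS:
        total = float(plus[sl].sum())
    elif region.strand == MINUS:
        total = float(minus[sl].sum())
    else:
        total = float(plus[sl].sum() + minus[sl].sum())
    return total * track.scale


ANCHOR_POINTS = ("TSS", "TES", "CPS", "plus1")


def _anchor_position(feature, anchor: str) -> int:
    """Genomic coordinate of a named anchor point for a feature.

    TSS/TES come from the feature's own interval; CPS and plus1 require the
    feature to carry ``cps`` / ``plus1`` attributes (TranscriptionUnit does).
    """
    if anchor == "TSS":
        return feature.interval.five_prime()
    if anchor == "TES":
        return feature.interval.three_prime()
    if anchor in ("CPS", "plus1"):
        attr = "cps" if anchor == "CPS" else "plus1"
        pos = getattr(feature, attr, None)
        if pos is None:
            raise AttributeError(f"{feature.id}: no {anchor} anchor available")
        return int(pos)
    raise ValueError(f"unknown anchor point {anchor!r}")


def binned_matrix(
    track: StrandedCoverageTrack,
    anchors: Sequence[tuple[TranscriptAnnotation, str]],
    upstream: int,
    downstream: int,
    binsize: int = 25,
) -> np.ndarray:
    """Per-bin mean depth around anchor points, one row per feature.

    The window runs from ``upstream`` bp before to ``downstream`` bp after each
    anchor *in the direction of transcription*; bins are ordered 5'->3' (rows of
    minus-strand features are reversed). Bins partially out of bounds average
    over in-bounds bases only; fully out-of-bounds bins are NaN, as is the whole
    row of a feature whose anchor point is unavailable.
    """
    if (upstream + downstream) % binsize != 0:
        raise ValueError("upstream+downstream must be divisible by binsize")
    nbins = (upstream + downstream) // binsize
    out = np.full((len(anchors), nbins), np.nan)
    for i, (feature, anchor) in enumerate(anchors):
        try:
            pos = _anchor_position(feature, anchor)
        except AttributeError:
            logger.warning("%s: anchor %s unavailable; row set to NaN",
                           feature.id, anchor)
            continue
        chrom = feature.chrom
        if chrom not in track.depths:
            continue
        depth = track.strand_depth(chrom, feature.strand)
        n = len(depth)
        minus = feature.strand == MINUS
        # genomic window: on plus, [pos-upstream, pos+downstream);
        # on minus, [pos-downstream+1, pos+upstream+1)
        if not minus:
            gstart = pos - upstream
        else:
            gstart = pos - downstream + 1
        for b in range(nbins):
            if not minus:
                bs = gstart + b * binsize
            else:  # bin 0 is the most 5' (rightmost) bin on the minus strand
                bs = gstart + (nbins - 1 - b) * binsize
            be = bs + binsize
            cs, ce = max(bs, 0), min(be, n)
            if cs >= ce:
                continue  # fully out of bounds -> NaN
            out[i, b] = float(depth[cs:ce].mean()) * track.scale
    return out
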