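"""Spike-in normalization and whole-chromosome copy-number screening.

Samples are sequenced as a 9:1 mixture of experimental and spike-in material,
so reads mapping to the spike-in genome give each sample an absolute yardstick:
dividing a fixed constant by the spike-in read count yields a per-sample scale
factor, and scaled tracks are directly comparable across samples. Everything
downstream (3' extension indices, class fold changes, log2-ratio tracks) is a
ratio of scaled signals, so the constant itself cancels.

The ploidy screen compares per-chromosome mean coverage between a test and a
reference sample; whole-chromosome gains show up as a per-chromosome log2 ratio
shifted away from the genome-wide median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import StrandedCoverageTrack, TranscriptAnnotation

logger = logging.getLogger(__name__)

DEFAULT_NORM_CONSTANT = 1e6
DEFAULT_PLOIDY_THRESHOLD = 0.32  # |re-centered log2 ratio|; ~1.25x


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeInSample:
    """Read counts for one sample: experimental genome vs spike-in genome."""

    sample_id: str
    experimental_reads: int
    spikein_reads: int


@dataclass
class PloidyScreenReport:
    """Per-chromosome coverage ratios and the chromosomes flagged as aneuploid.

    ``ratios`` holds the raw per-chromosome log2(test/reference) of mean depth;
    ``recentered`` subtracts the across-chromosome median so a residual global
    scale difference between the two samples cannot flag everything at once.
    Chromosomes whose reference coverage is zero are ``indeterminate``.
    """

    ratios: dict[str, float]
    recentered: dict[str, float]
    flagged: set[str]
    indeterminate: set[str]
    threshold: float
    mean_test: dict[str, float] = field(default_factory=dict)
    mean_ref: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.ratios:
            rows.append({
                "chromosome": chrom,
                "mean_test": self.mean_test.get(chrom, np.nan),
                "mean_ref": self.mean_ref.get(chrom, np.nan),
                "log2_ratio": self.ratios[chrom],
                "recentered": self.recentered[chrom],
                "flagged": chrom in self.flagged,
                "indeterminate": chrom in self.indeterminate,
            })
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_spikein_table(path: str | Path) -> list[SpikeInSample]:
    """Read the per-sample TSV: sample_id, experimental_reads, spikein_reads."""
    df = pd.read_csv(path, sep="\t")
    return [
        SpikeInSample(str(r.sample_id), int(r.experimental_reads), int(r.spikein_reads))
        for r in df.itertuples(index=False)
    ]


def spike_scale_factor(sample: SpikeInSample, constant: float = DEFAULT_NORM_CONSTANT) -> float:
    """Per-sample normalization factor: ``constant / spikein_reads``.

    Multiplying a raw track's depths by this factor puts all samples on the
    common per-million-spike-in-reads scale.
    """
    if sample.spikein_reads <= 0:
        raise NormalizationError(
            f"{sample.sample_id}: spike-in failed (spikein_reads = "
            f"{sample.spikein_reads})"
        )
    return constant / sample.spikein_reads


def normalize_track(track: StrandedCoverageTrack, factor: float) -> StrandedCoverageTrack:
    """Attach a spike-in scale factor to a raw track (lazy scaling).

    The underlying depth vectors are shared, not copied; only the scale changes.
    Re-normalizing an already-scaled track is an error.
    """
    if factor <= 0:
        raise NormalizationError(f"scale factor must be positive, got {factor}")
    if track.scale != 1.0:
        raise NormalizationError(
            f"track {track.sample_id!r} already has scale {track.scale}; "
            "refusing to re-normalize"
        )
    return StrandedCoverageTrack(
        depths=track.depths, scale=factor, sample_id=track.sample_id
    )


def log2_ratio_track(
    a: StrandedCoverageTrack,
    b: StrandedCoverageTrack,
    pseudocount: float = 1.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-base ``log2((a + pseudocount) / (b + pseudocount))`` on each strand.

    Scaled depths are used (each track's scale factor is applied per base).
    Returns a map chromosome -> (plus, minus) signed arrays.
    """
    if a.chrom_sizes != b.chrom_sizes:
        raise NormalizationError("tracks have different chromosome-size tables")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in a.depths:
        pair = []
        for ai, bi in zip(a.depths[chrom], b.depths[chrom]):
            num = ai * a.scale + pseudocount
            den = bi * b.scale + pseudocount
            if pseudocount <= 0 and (np.any(num <= 0) or np.any(den <= 0)):
                raise NormalizationError(
                    "pseudocount <= 0 with zero-depth bases: log2 ratio undefined"
                )
            # log2(num) - log2(den) rather than log2(num/den): makes the
            # a/b vs b/a antisymmetry exact in floating point
            pair.append(np.log2(num) - np.log2(den))
        out[chrom] = (pair[0], pair[1])
    return out


def chromosome_ploidy_screen(
    test: StrandedCoverageTrack,
    reference: StrandedCoverageTrack,
    threshold: float = DEFAULT_PLOIDY_THRESHOLD,
) -> PloidyScreenReport:
    """Flag chromosomes whose coverage deviates as a block between two samples.

    For each chromosome the mean scaled depth (both strands pooled) is computed
    in test and reference; the per-chromosome log2 ratio is re-centered by
    subtracting the median ratio across chromosomes, and chromosomes with
    ``|re-centered ratio| > threshold`` are flagged. A chromosome with zero
    reference coverage is reported as indeterminate, never silently passed.
    """
    if test.chrom_sizes != reference.chrom_sizes:
        raise NormalizationError("tracks have different chromosome-size tables")
    ratios: dict[str, float] = {}
    mean_test: dict[str, float] = {}
    mean_ref: dict[str, float] = {}
    indeterminate: set[str] = set()
    for chrom, n in test.chrom_sizes.items():
        tp, tm = test.depths[chrom]
        rp, rm = reference.depths[chrom]
        mt = float(tp.sum() + tm.sum()) / n * test.scale
        mr = float(rp.sum() + rm.sum()) / n * reference.scale
        mean_test[chrom] = mt
        mean_ref[chrom] = mr
        if mr == 0.0:
            indeterminate.add(chrom)
            ratios[chrom] = float("nan")
            logger.warning("%s: zero reference coverage; ploidy indeterminate", chrom)
        else:
            ratios[chrom] = float(np.log2(mt / mr)) if mt > 0 else float("-inf")
    finite = [r for c, r in ratios.items() if c not in indeterminate and np.isfinite(r)]
    center = float(np.median(finite)) if finite else 0.0
    recentered = {
        c: (r - center if c not in indeterminate else float("nan"))
        for c, r in ratios.items()
    }
    flagged = {
        c for c, r in recentered.items()
        if c not in indeterminate and abs(r) > threshold
    }
    return PloidyScreenReport(
        ratios=ratios, recentered=recentered, flagged=flagged,
        indeterminate=indeterminate, threshold=threshold,
        mean_test=mean_test, mean_ref=mean_ref,
    )


def exclude_chromosomes(
    features: Sequence[TranscriptAnnotation],
    chroms: set[str] | Sequence[str],
) -> list[TranscriptAnnotation]:
    """Drop features on the given chromosomes (aneuploidy exclusion helper)."""
    chroms = set(chroms)
    kept = [f for f in features if f.chrom not in chroms]
    dropped = len(features) - len(kept)
    if dropped:
        logger.info("excluded %d features on %s", dropped, sorted(chroms))
    return kept
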