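"""Quantitative readthrough statistics.

The central statistic is the 3' extension index (3'EI): the ratio of
spike-in-normalized signal in a fixed window (default 150 bp) immediately
downstream of a feature's annotated 3' end (TES), mutant over wild type. A
termination-defective mutant keeps transcribing past the TES, inflating the
window signal; a 3'EI at or above 1.5 flags the feature as read through.

Also here: pooled fold changes for noncoding RNA classes (CUT/SUT/XUT/NUT/
SRAT), anchored per-feature window signals reusable across RNA-seq, 4tU-seq,
MNase-seq and ChIP-seq tracks, a Wilcoxon rank-sum comparison for such window
sets, replicate Pearson correlation, and the ChIP-qPCR percent-of-input
occupancy formula.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    EmptyWindowError,
    GenomicInterval,
    StrandedCoverageTrack,
    TranscriptAnnotation,
    _anchor_position,
    downstream_window,
    region_signal,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 150
DEFAULT_THRESHOLD = 1.5
DEFAULT_EPS = 1.0


@dataclass(frozen=True)
class ExtensionIndexRecord:
    """Mutant/WT post-TES signal for one feature and the resulting 3'EI."""

    feature_id: str
    window: GenomicInterval
    mut_signal: float
    wt_signal: float
    ei3: float
    flagged: bool = False


def three_prime_extension_index(
    mut: StrandedCoverageTrack,
    wt: StrandedCoverageTrack,
    features: Sequence[TranscriptAnnotation],
    window: int = DEFAULT_WINDOW,
    eps: float = DEFAULT_EPS,
) -> tuple[list[ExtensionIndexRecord], list[str]]:
    """Compute the 3' extension index for each feature.

    For each feature the ``window`` bp downstream of its TES is taken
    (strand-aware, clamped to the chromosome) and
    ``ei3 = (mut_signal + eps) / (wt_signal + eps)`` computed from normalized
    signals. ``eps`` guards silent windows; with ``eps = 0`` a silent WT window
    is an error. Records are sorted by feature id; features whose window is
    fully clamped away are excluded and returned as the second element.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    sizes = mut.chrom_sizes
    records: list[ExtensionIndexRecord] = []
    excluded: list[str] = []
    for feat in features:
        try:
            win = downstream_window(feat, window, sizes)
        except EmptyWindowError:
            excluded.append(feat.id)
            continue
        m = region_signal(mut, win)
        w = region_signal(wt, win)
        if eps == 0 and w == 0:
            raise ZeroDivisionError(
                f"{feat.id}: wt window signal is 0 and eps is 0"
            )
        records.append(ExtensionIndexRecord(
            feature_id=feat.id, window=win,
            mut_signal=m, wt_signal=w, ei3=(m + eps) / (w + eps),
        ))
    if excluded:
        logger.warning("excluded %d features with empty clamped windows: %s",
                       len(excluded), excluded)
    records.sort(key=lambda r: r.feature_id)
    return records, excluded


def flag_readthrough(
    records: Sequence[ExtensionIndexRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[ExtensionIndexRecord], float]:
    """Flag records with ``ei3 >= threshold`` (inclusive) and report the fraction.

    Returns the flagged records (with ``flagged=True`` set) and
    ``len(flagged) / len(records)``.
    """
    if not records:
        raise ValueError("no extension-index records: flagged fraction undefined")
    flagged = [
        ExtensionIndexRecord(
            feature_id=r.feature_id, window=r.window,
            mut_signal=r.mut_signal, wt_signal=r.wt_signal,
            ei3=r.ei3, flagged=True,
        )
        for r in records if r.ei3 >= threshold
    ]
    return flagged, len(flagged) / len(records)


def write_extension_index(
    records: Sequence[ExtensionIndexRecord],
    path: str | Path,
    threshold: float = DEFAULT_THRESHOLD,
    eps: float = DEFAULT_EPS,
) -> None:
    """3'EI TSV: one row per feature plus a trailing summary comment."""
    n_flagged = sum(1 for r in records if r.ei3 >= threshold)
    with open(path, "w") as fh:
        fh.write(f"# window pseudocount eps={eps:g}; flag threshold={threshold:g}\n")
        fh.write("feature_id\tchrom\twindow_start\twindow_end\tstrand"
                 "\twt_signal\tmut_signal\tei3\tflagged\n")
        for r in records:
            fh.write(
                f"{r.feature_id}\t{r.window.chrom}\t{r.window.start}"
                f"\t{r.window.end}\t{r.window.strand}\t{r.wt_signal:.6g}"
                f"\t{r.mut_signal:.6g}\t{r.ei3:.6g}\t{r.ei3 >= threshold}\n"
            )
        frac = n_flagged / len(records) if records else float("nan")
        fh.write(f"# n={len(records)} n_flagged={n_flagged} fraction={frac:.6g}\n")


def class_fold_change(
    mut: StrandedCoverageTrack,
    wt: StrandedCoverageTrack,
    class_features: Sequence[TranscriptAnnotation],
    eps: float = DEFAULT_EPS,
    per_feature: bool = False,
) -> float:
    """Mutant/WT fold change for a noncoding RNA class.

    Signal is summed over each feature's own annotated interval and strand,
    pooled across the class, and the single ratio
    ``(sum_mut + eps) / (sum_wt + eps)`` returned — one number per class.
    ``per_feature=True`` instead averages the per-feature ratios.
    """
    if not class_features:
        raise ValueError("empty feature class")
    classes = {f.feature_class for f in class_features}
    if len(classes) > 1:
        raise ValueError(f"mixed feature classes: {sorted(classes)}")
    mut_sig = [region_signal(mut, f.interval) for f in class_features]
    wt_sig = [region_signal(wt, f.interval) for f in class_features]
    if per_feature:
        return float(np.mean([(m + eps) / (w + eps)
                              for m, w in zip(mut_sig, wt_sig)]))
    return (sum(mut_sig) + eps) / (sum(wt_sig) + eps)


def region_set_signal(
    track: StrandedCoverageTrack,
    features: Sequence,
    anchor: Literal["TES", "CPS"] = "TES",
    offset_start: int = 0,
    offset_end: int = DEFAULT_WINDOW,
) -> tuple[np.ndarray, list[str]]:
    """Per-feature signal in a window placed relative to an anchor point.

    The window spans ``[anchor + offset_start, anchor + offset_end)`` in the
    direction of transcription (e.g. 0..150 = the 150 bp downstream of the
    CPS; -100..500 = 100 bp upstream to 500 bp downstream). Works identically
    on RNA-seq, 4tU-seq, MNase-seq and ChIP-seq tracks. Features missing the
    anchor or with fully clamped windows are excluded and reported.
    """
    if offset_end <= offset_start:
        raise ValueError("offset_end must exceed offset_start")
    sizes = track.chrom_sizes
    values: list[float] = []
    excluded: list[str] = []
    for feat in features:
        try:
            pos = _anchor_position(feat, anchor)
        except AttributeError:
            excluded.append(feat.id)
            continue
        iv = feat.interval
        if iv.strand == "-":
            start, end = pos - offset_end + 1, pos - offset_start + 1
        else:
            start, end = pos + offset_start, pos + offset_end
        start = max(start, 0)
        end = min(end, sizes.get(iv.chrom, end))
        if start >= end:
            excluded.append(feat.id)
            continue
        region = GenomicInterval(iv.chrom, start, end, iv.strand)
        values.append(region_signal(track, region))
    if excluded:
        logger.warning("region_set_signal: excluded %d features (%s)",
                       len(excluded), excluded[:5])
    return np.asarray(values, dtype=float), excluded


def region_rank_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for two signal sets.

    Small tie-free samples (both n <= 20) use the exact null distribution;
    otherwise the normal approximation with tie correction is used. If every
    value is identical across both samples the comparison is vacuous and
    p = 1 is returned by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.info("rank test: all values identical; p = 1 by convention")
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def replicate_correlation(
    a: StrandedCoverageTrack,
    b: StrandedCoverageTrack,
    features: Sequence[TranscriptAnnotation],
) -> float:
    """Pearson r between two replicates' per-feature normalized signals.

    Returns NaN (with a warning) when either signal vector has zero variance.
    """
    xs = np.array([region_signal(a, f.interval) for f in features])
    ys = np.array([region_signal(b, f.interval) for f in features])
    finite = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[finite], ys[finite]
    if len(xs) < 3:
        raise ValueError("need at least 3 features with finite signal")
    if xs.std() == 0 or ys.std() == 0:
        logger.warning("replicate correlation undefined: zero variance")
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def qpcr_occupancy(efficiency: float, ct_input: float, ct_ip: float) -> float:
    """ChIP-qPCR occupancy as a fraction of input.

    ``efficiency ** (ct_input - ct_ip)`` — the primer amplification efficiency
    per cycle raised to the input-minus-IP cycle-threshold difference. A
    perfect primer has efficiency 2 (doubling per cycle).
    """
    if not (1 < efficiency <= 2):
        raise ValueError(f"amplification efficiency must be in (1, 2], got {efficiency}")
    if not (math.isfinite(ct_input) and math.isfinite(ct_ip)):
        raise ValueError("cycle-threshold values must be finite")
    return efficiency ** (ct_input - ct_ip)


def write_class_folds(
    folds: Mapping[str, tuple[int, float, float, float]],
    path: str | Path,
) -> None:
    """Class fold-change TSV: class, n_features, wt_total, mut_total, fold."""
    with open(path, "w") as fh:
        fh.write("class\tn_features\twt_total\tmut_total\tfold\n")
        for cls in sorted(folds):
            n, wt_total, mut_total, fold = folds[cls]
            fh.write(f"{cls}\t{n}\t{wt_total:.6g}\t{mut_total:.6g}\t{fold:.6g}\n")
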