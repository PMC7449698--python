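"""Seeded generator of toy genomes and coverage tracks for pipeline testing.

The generator lays out a small yeast-like genome — protein-coding genes,
snoRNAs and annotated noncoding RNA classes packed onto a few chromosomes
with intergenic spacing — and emits the exact text formats the pipeline
consumes (BED6 annotations, per-strand bedGraph coverage, a chromosome-size
table and a spike-in read-count table).

Coverage is a plateau model: every feature is expressed at a sample-wide
depth on its own strand, and every feature leaks a basal plateau at the same
depth into its 150 bp post-TES window (imperfect termination is never zero,
and the extension index is a *ratio*: the mutant effect multiplies this
baseline, so a designed post-TES fold is recovered exactly as the 3'EI).
Mutant samples add depth*(fold-1) in the post-TES windows of a designated
readthrough set, scale noncoding classes by per-class folds, optionally add
antisense plateaus and whole-chromosome copy gains, and can replace every
base with a Poisson draw of its mean. Identical (config, seed) inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import Site
from .core import (
    MINUS,
    PLUS,
    GenomicInterval,
    StrandedCoverageTrack,
    TranscriptAnnotation,
    write_annotations,
    write_chrom_sizes,
    write_coverage,
)
from .normalization import SpikeInSample

DEFAULT_CHROMOSOMES = (("chrI", 90_000), ("chrII", 90_000), ("chrIII", 90_000))


class PackingError(ValueError):
    """The configured features do not fit on the configured chromosomes."""


@dataclass(frozen=True)
class SampleSpec:
    """One simulated sample: its role, depth, effects and noise model."""

    sample_id: str
    role: str = "WT"  # "WT" or "mutant"
    depth: float = 50.0
    spikein_reads: int | None = None  # default: baseline experimental reads / 9
    readthrough_fold: dict[str, float] = field(default_factory=dict)
    class_fold: dict[str, float] = field(default_factory=dict)
    antisense_fraction: float = 0.0
    aneuploid_chroms: dict[str, float] = field(default_factory=dict)
    noise: str = "none"  # "none" or "poisson"

    def __post_init__(self) -> None:
        if self.role not in ("WT", "mutant"):
            raise ValueError(f"role must be WT or mutant, got {self.role!r}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if any(f < 0 for f in self.readthrough_fold.values()):
            raise ValueError("readthrough folds must be non-negative")
        if any(f < 0 for f in self.class_fold.values()):
            raise ValueError("class folds must be non-negative")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Layout and per-sample description of a synthetic experiment."""

    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    n_genes: int = 20
    n_snornas: int = 73
    class_counts: dict[str, int] = field(default_factory=dict)  # e.g. {"NUT": 30}
    spacing: tuple[int, int] = (400, 800)  # uniform intergenic gap, bp
    gene_length: tuple[int, int] = (1000, 2000)
    snorna_length: tuple[int, int] = (100, 300)
    ncrna_length: tuple[int, int] = (300, 800)
    plus1_offset: int = 60  # +1 nucleosome dyad, bp upstream of CDS 5' end
    cps_offset: int = 120  # CPS, bp downstream of CDS 3' end
    readthrough_window: int = 150
    samples: tuple[SampleSpec, ...] = ()


@dataclass
class SyntheticGenome:
    """All annotations of one simulated genome."""

    chrom_sizes: dict[str, int]
    genes: list[TranscriptAnnotation]
    snornas: list[TranscriptAnnotation]
    ncrnas: dict[str, list[TranscriptAnnotation]]
    plus1_sites: list[Site]
    cps_sites: list[Site]
    config: SimulationConfig

    @property
    def all_features(self) -> list[TranscriptAnnotation]:
        out = list(self.genes) + list(self.snornas)
        for feats in self.ncrnas.values():
            out.extend(feats)
        return out


def simulate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Place genes, snoRNAs and ncRNA-class features on the toy chromosomes.

    Features are laid left-to-right with intergenic gaps drawn from the
    configured spacing distribution and random strands; the feature order is a
    seeded shuffle so every class is spread across chromosomes. Each gene gets
    a +1 nucleosome dyad ``plus1_offset`` bp upstream of its CDS 5' end and a
    CPS ``cps_offset`` bp downstream of its 3' end, so boundary re-annotation
    succeeds for every gene. Raises :class:`PackingError` (before writing
    anything) if the features do not fit.
    """
    rng = np.random.default_rng(config.seed)
    descriptors: list[tuple[str, str]] = []  # (kind, id)
    descriptors += [("gene", f"gene{i+1:04d}") for i in range(config.n_genes)]
    descriptors += [("snoRNA", f"snR{i+1:03d}") for i in range(config.n_snornas)]
    for cls in sorted(config.class_counts):
        descriptors += [(cls, f"{cls}{i+1:04d}")
                        for i in range(config.class_counts[cls])]
    order = rng.permutation(len(descriptors))

    length_ranges = {
        "gene": config.gene_length,
        "snoRNA": config.snorna_length,
    }
    margin = config.readthrough_window + config.cps_offset + 50
    # balanced fill: place each feature on the least-occupied chromosome so
    # every chromosome carries signal (the ploidy screen needs that)
    cursors = {name: margin for name, _ in config.chromosomes}
    genome = SyntheticGenome(
        chrom_sizes=dict(config.chromosomes),
        genes=[], snornas=[], ncrnas={c: [] for c in config.class_counts},
        plus1_sites=[], cps_sites=[], config=config,
    )
    for idx in order:
        kind, feat_id = descriptors[idx]
        lo, hi = length_ranges.get(kind, config.ncrna_length)
        length = int(rng.integers(lo, hi + 1))
        gap = int(rng.integers(config.spacing[0], config.spacing[1] + 1))
        strand = PLUS if rng.random() < 0.5 else MINUS
        chrom = min(cursors, key=lambda c: (cursors[c], c))
        chrom_len = genome.chrom_sizes[chrom]
        start = cursors[chrom] + gap
        if start + length + margin > chrom_len:
            fitting = [c for c in cursors
                       if cursors[c] + gap + length + margin <= genome.chrom_sizes[c]]
            if not fitting:
                raise PackingError(
                    f"feature {feat_id} does not fit: increase chromosome "
                    "lengths or reduce feature counts"
                )
            chrom = min(fitting, key=lambda c: (cursors[c], c))
            start = cursors[chrom] + gap
        iv = GenomicInterval(chrom, start, start + length, strand)
        feat_class = {"gene": "mRNA", "snoRNA": "snoRNA"}.get(kind, kind)
        feat = TranscriptAnnotation(id=feat_id, interval=iv, feature_class=feat_class)
        if kind == "gene":
            genome.genes.append(feat)
            if strand == PLUS:
                genome.plus1_sites.append((chrom, start - config.plus1_offset, PLUS))
                genome.cps_sites.append((chrom, iv.end + config.cps_offset, PLUS))
            else:
                genome.plus1_sites.append((chrom, iv.end + config.plus1_offset, MINUS))
                genome.cps_sites.append((chrom, start - config.cps_offset, MINUS))
        elif kind == "snoRNA":
            genome.snornas.append(feat)
        else:
            genome.ncrnas[kind].append(feat)
        cursors[chrom] = start + length
    return genome


def _post_tes_window(feat: TranscriptAnnotation, length: int,
                     chrom_len: int) -> tuple[int, int]:
    iv = feat.interval
    if iv.strand == MINUS:
        return max(iv.start - length, 0), iv.start
    return iv.end, min(iv.end + length, chrom_len)


def _baseline_area(genome: SyntheticGenome, depth: float) -> float:
    """Expected noise-free coverage area at unit class folds (WT baseline)."""
    total = 0.0
    for feat in genome.all_features:
        chrom_len = genome.chrom_sizes[feat.chrom]
        s, e = _post_tes_window(feat, genome.config.readthrough_window, chrom_len)
        total += len(feat.interval) + (e - s)
    return total * depth


def simulate_coverage(
    genome: SyntheticGenome,
    spec: SampleSpec,
    seed: int,
) -> tuple[StrandedCoverageTrack, SpikeInSample]:
    """Build one sample's raw stranded coverage and its spike-in record.

    All features get a plateau of the sample depth over their interval and
    their post-TES window. Mutant effects (readthrough folds, class folds,
    antisense, aneuploidy) are applied per the sample spec; Poisson noise
    replaces each base with an integer draw of its mean. The spike-in read
    count defaults to one ninth of the baseline experimental read equivalent
    (the 9:1 mixture is of input material, identical across samples, so the
    default is the same for every sample at equal depth).
    """
    cfg = genome.config
    track = StrandedCoverageTrack.zeros(genome.chrom_sizes, sample_id=spec.sample_id)
    d = spec.depth

    def _add(chrom: str, strand: str, start: int, end: int, value: float) -> None:
        arr = track.depths[chrom][0 if strand == PLUS else 1]
        arr[start:end] += value

    for feat in genome.all_features:
        iv = feat.interval
        body = d
        if feat.feature_class in spec.class_fold:
            body = d * spec.class_fold[feat.feature_class]
        _add(iv.chrom, iv.strand, iv.start, iv.end, body)
        ws, we = _post_tes_window(feat, cfg.readthrough_window,
                                  genome.chrom_sizes[iv.chrom])
        window_depth = d
        if feat.id in spec.readthrough_fold:
            window_depth = d * spec.readthrough_fold[feat.id]
        if we > ws:
            _add(iv.chrom, iv.strand, ws, we, window_depth)
        if spec.antisense_fraction > 0:
            anti = MINUS if iv.strand == PLUS else PLUS
            _add(iv.chrom, anti, iv.start, iv.end, spec.antisense_fraction * d)

    for chrom, ratio in spec.aneuploid_chroms.items():
        if ratio < 0:
            raise ValueError(f"aneuploid copy ratio must be non-negative ({chrom})")
        plus, minus = track.depths[chrom]
        plus *= ratio
        minus *= ratio

    if spec.noise == "poisson":
        rng = np.random.default_rng(
            [seed % (2**31), zlib.crc32(spec.sample_id.encode()) % (2**31)]
        )
        for chrom in track.depths:
            plus, minus = track.depths[chrom]
            track.depths[chrom] = (
                rng.poisson(plus).astype(float),
                rng.poisson(minus).astype(float),
            )
    else:
        for chrom in track.depths:
            plus, minus = track.depths[chrom]
            track.depths[chrom] = (np.round(plus, 6), np.round(minus, 6))

    experimental = int(round(sum(
        float(p.sum() + m.sum()) for p, m in track.depths.values()
    )))
    if spec.spikein_reads is not None:
        spikein = spec.spikein_reads
    else:
        spikein = max(1, int(round(_baseline_area(genome, d) / 9.0)))
    sample = SpikeInSample(spec.sample_id, experimental, spikein)
    return track, sample


def write_run_inputs(
    genome: SyntheticGenome,
    samples: Sequence[tuple[StrandedCoverageTrack, SpikeInSample]],
    outdir: str | Path,
) -> Path:
    """Write a complete pipeline input directory and its manifest.

    Emits chrom.sizes, cds.bed, snorna.bed, one <class>.bed per ncRNA class,
    plus1.bed, cps.bed, per-sample bedGraph pairs, spikein.tsv and a
    manifest.json recording the config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(genome.chrom_sizes, outdir / "chrom.sizes")
    write_annotations(genome.genes, outdir / "cds.bed")
    write_annotations(genome.snornas, outdir / "snorna.bed")
    for cls, feats in genome.ncrnas.items():
        write_annotations(feats, outdir / f"{cls.lower()}.bed")
    with open(outdir / "plus1.bed", "w") as fh:
        for i, (chrom, pos, strand) in enumerate(genome.plus1_sites, 1):
            fh.write(f"{chrom}\t{pos}\t{pos+1}\tplus1_{i}\t0\t{strand}\n")
    with open(outdir / "cps.bed", "w") as fh:
        for i, (chrom, pos, strand) in enumerate(genome.cps_sites, 1):
            fh.write(f"{chrom}\t{pos}\t{pos+1}\tcps_{i}\t0\t{strand}\n")
    with open(outdir / "spikein.tsv", "w") as fh:
        fh.write("sample_id\texperimental_reads\tspikein_reads\n")
        for _track, rec in samples:
            fh.write(f"{rec.sample_id}\t{rec.experimental_reads}\t{rec.spikein_reads}\n")
    for track, _rec in samples:
        write_coverage(track, outdir / track.sample_id)
    manifest = {
        "seed": genome.config.seed,
        "config": _config_dict(genome.config),
        "n_genes": len(genome.genes),
        "n_snornas": len(genome.snornas),
        "ncrna_counts": {c: len(f) for c, f in genome.ncrnas.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["chromosomes"] = [list(c) for c in config.chromosomes]
    d["samples"] = [dataclasses.asdict(s) for s in config.samples]
    return d


def simulate_experiment(config: SimulationConfig, outdir: str | Path) -> Path:
    """Generate genome + all configured samples and write the run directory."""
    genome = simulate_genome(config)
    samples = [simulate_coverage(genome, spec, config.seed)
               for spec in config.samples]
    return write_run_inputs(genome, samples, outdir)
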