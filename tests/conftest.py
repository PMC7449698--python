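import numpy as np
import pytest

from readthrough_kit import (
    SampleSpec,
    SimulationConfig,
    StrandedCoverageTrack,
    simulate_coverage,
    simulate_genome,
)


def random_track(rng: np.random.Generator, chrom_sizes: dict[str, int],
                 max_depth: int = 60, sample_id: str = "rand") -> StrandedCoverageTrack:
    """A blocky random coverage track (runs of constant depth, plenty of zeros)."""
    depths = {}
    for chrom, n in chrom_sizes.items():
        arrs = []
        for _ in range(2):
            arr = np.zeros(n, dtype=float)
            pos = 0
            while pos < n:
                run = int(rng.integers(1, 40))
                val = float(rng.integers(0, max_depth)) if rng.random() < 0.6 else 0.0
                arr[pos:pos + run] = val
                pos += run
            arrs.append(arr)
        depths[chrom] = (arrs[0], arrs[1])
    return StrandedCoverageTrack(depths=depths, sample_id=sample_id)


@pytest.fixture(scope="session")
def toy_experiment():
    """A 73-snoRNA WT/mutant experiment, noise-free: 30 features at fold 3."""
    readthrough = {f"snR{i+1:03d}": 3.0 for i in range(30)}
    cfg = SimulationConfig(
        seed=11,
        n_genes=15,
        n_snornas=73,
        class_counts={"NUT": 25, "SRAT": 15},
        samples=(
            SampleSpec("WT", role="WT"),
            SampleSpec("mutant", role="mutant", readthrough_fold=readthrough,
                       class_fold={"NUT": 2.19, "SRAT": 4.2}),
        ),
    )
    genome = simulate_genome(cfg)
    tracks = {
        spec.sample_id: simulate_coverage(genome, spec, cfg.seed)
        for spec in cfg.samples
    }
    return cfg, genome, tracks
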