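import numpy as np
import pytest

from glycochrom.intervals import GeneModel, GenomeSpec, GenomicInterval, PeakSet


@pytest.fixture
def toy_genome() -> GenomeSpec:
    return GenomeSpec({"chrA": 100_000, "chrB": 100_000})


@pytest.fixture
def toy_genes(toy_genome) -> list[GeneModel]:
    return [
        GeneModel("gplus", "chrA", 10_000, 16_000, "+"),
        GeneModel("gminus", "chrA", 30_000, 36_000, "-"),
        GeneModel("gshort", "chrB", 50_000, 50_800, "+"),
    ]


def random_peakset(rng: np.random.Generator, n: int, chrom_len: int = 100_000,
                   chroms=("chrA",), max_width: int = 2_000) -> PeakSet:
    """Uniformly placed random intervals, possibly overlapping each other."""
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - max_width))
        width = int(rng.integers(1, max_width))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return PeakSet(ivs)


def bitmap(peaks: PeakSet, chrom: str, length: int) -> np.ndarray:
    """Per-base boolean coverage oracle for a single toy chromosome."""
    mask = np.zeros(length, dtype=bool)
    for iv in peaks:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask
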