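import numpy as np
import pytest

from quantepi.core import GenomicInterval, QuantTrack


@pytest.fixture
def step_track() -> QuantTrack:
    """Two-bin track: [0,100)=1.0, [100,200)=3.0 on chr1."""
    return QuantTrack.from_records(
        [("chr1", 0, 100, 1.0), ("chr1", 100, 200, 3.0)]
    )


def random_track(
    rng: np.random.Generator,
    chrom: str = "chr1",
    length: int = 1000,
    max_intervals: int = 12,
) -> QuantTrack:
    """Small random step track with gaps, for brute-force comparisons."""
    n = int(rng.integers(0, max_intervals + 1))
    cuts = np.sort(rng.choice(length, size=min(2 * n, length), replace=False))
    records = []
    for i in range(0, len(cuts) - 1, 2):
        s, e = int(cuts[i]), int(cuts[i + 1])
        if e > s and rng.random() < 0.8:  # leave some gaps
            records.append((chrom, s, e, float(rng.uniform(0, 5))))
    return QuantTrack.from_records(records, chrom_lengths={chrom: length})


def per_base_signal(track: QuantTrack, chrom: str, length: int) -> np.ndarray:
    """Explicit per-base expansion of a track (oracle for interval math)."""
    out = np.zeros(length)
    starts, ends, values = track.arrays(chrom)
    for s, e, v in zip(starts, ends, values):
        out[s:e] = v
    return out


@pytest.fixture
def interval():
    return GenomicInterval
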