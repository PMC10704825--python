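import numpy as np
import pandas as pd
import pytest

from plantkaryo import BinTrack, GenomeLayout


@pytest.fixture
def small_layout():
    """Two chromosomes of a rapeseed-like A/C split."""
    return GenomeLayout((("A1", 4_000_000), ("C1", 5_000_000)),
                        {"A1": "A", "C1": "C"})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_track(ratios_by_chrom, bin_size=100_000, gc=0.4):
    """BinTrack with normalized/ratio columns filled directly, for unit tests
    of stages downstream of normalization."""
    frames = []
    for chrom, ratios in ratios_by_chrom.items():
        ratios = np.asarray(ratios, dtype=float)
        starts = np.arange(len(ratios)) * bin_size
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_size,
            "count": np.maximum((ratios * 100).astype(int), 0),
            "gc": gc,
            "masked": False,
            "normalized": ratios * 100.0,
            "ratio": ratios,
        }))
    return BinTrack(pd.concat(frames, ignore_index=True))


@pytest.fixture
def make_ratio_track():
    return make_track
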