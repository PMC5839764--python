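import numpy as np
import pandas as pd
import pytest

from shm_atlas import TargetRegion


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_region():
    # 24 bp with WRCY (AGCT at 2..6) and scattered C/G
    seq = "TTAGCTATGGCCAATTAGCTATCG"
    return TargetRegion("toy", "toygene", "chrT", 0, len(seq), seq)


def make_counts(region, depth=1000, mutations=()):
    """Clean count table for a region with optional (pos, alt, count) spikes."""
    rows = []
    for pos, ref in enumerate(region.sequence):
        counts = {b: 0 for b in "ACGT"}
        if ref in counts:
            counts[ref] = depth
        for m_pos, alt, n in mutations:
            if m_pos == pos:
                counts[alt] += n
                if ref in counts:
                    counts[ref] -= n
        rows.append(
            {
                "region_id": region.region_id,
                "pos": pos,
                "ref": ref,
                "depth": depth,
                **counts,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def make_counts_factory():
    return make_counts
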