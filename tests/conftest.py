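import numpy as np
import pandas as pd
import pytest

from fourc.genome import BaitRegion, GenomeLayout


@pytest.fixture
def layout() -> GenomeLayout:
    return GenomeLayout([("chr17", 10_000_000), ("chr3", 8_000_000), ("chr2", 6_000_000)])


@pytest.fixture
def bait(layout) -> BaitRegion:
    # primers at 1,000,100 / 1,000,300 -> bait [999600, 1000800), ~1.2 kb
    return BaitRegion.from_primers("chr17", 1_000_100, 1_000_300, layout)


def make_tags(rows) -> pd.DataFrame:
    """rows: (read_id, end, chrom, pos[, strand, unique])."""
    from fourc.io import tags_frame

    full = []
    for r in rows:
        r = tuple(r)
        if len(r) == 4:
            r = r + ("+", True)
        elif len(r) == 5:
            r = r + (True,)
        full.append(r)
    return tags_frame(full)


def pair(read_id, chrom1, pos1, chrom2, pos2, unique1=True, unique2=True):
    return [
        (read_id, "forward", chrom1, pos1, "+", unique1),
        (read_id, "reverse", chrom2, pos2, "-", unique2),
    ]
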