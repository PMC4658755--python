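from __future__ import annotations

import numpy as np
import pytest

from dfprint.genomic_core import CutProfile, GenomicInterval, ReadSource


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_profile(
    rng: np.random.Generator,
    length: int = 50,
    chrom: str = "chrT",
    start: int = 100,
    rate: float = 0.5,
) -> CutProfile:
    iv = GenomicInterval(chrom, start, start + length)
    return CutProfile(
        iv,
        rng.poisson(rate, size=length).astype(np.int64),
        rng.poisson(rate, size=length).astype(np.int64),
    )


def source_from_profile(profile: CutProfile, tmp_path, read_length: int = 36) -> ReadSource:
    """Write a profile as SAM text and open it as an indexed read source."""
    from dfprint.synthetic_data import emit_sam

    sam = tmp_path / "reads.sam"
    sam.write_text(emit_sam(profile, read_length=read_length))
    return ReadSource(sam)


# hand-written 3-read SAM: one + read at [100,136), one - read at [100,136),
# one + read at [300,336) (outside typical test intervals)
HAND_SAM = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:chrT\tLN:1000
read1\t0\tchrT\t101\t60\t36M\t*\t0\t0\t*\t*
read2\t16\tchrT\t101\t60\t36M\t*\t0\t0\t*\t*
read3\t0\tchrT\t301\t60\t36M\t*\t0\t0\t*\t*
"""


@pytest.fixture
def hand_sam_source(tmp_path) -> ReadSource:
    sam = tmp_path / "hand.sam"
    sam.write_text(HAND_SAM)
    return ReadSource(sam)
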