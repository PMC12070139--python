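import numpy as np
import pytest

from meningrisk.cnv import ArmDefinition, LocusDefinition, Segment
from meningrisk.io import default_arms, default_loci


@pytest.fixture(scope="session")
def arms():
    return default_arms()


@pytest.fixture(scope="session")
def loci():
    return default_loci()


@pytest.fixture
def toy_arm():
    """A 10 kb arm for hand-checkable interval arithmetic."""
    return ArmDefinition("chrT", "p", 0, 10_000)


@pytest.fixture
def toy_locus():
    return LocusDefinition("CDKN2A/B", "chrT", 4_000, 4_200)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_fraction(segments, arm, loss_log2=-0.1):
    """Independent per-base oracle for the arm-loss fraction."""
    lost = np.zeros(arm.end - arm.start, dtype=bool)
    for seg in segments:
        if seg.chrom != arm.chrom or seg.log2_ratio > loss_log2:
            continue
        lo = max(seg.start, arm.start) - arm.start
        hi = min(seg.end, arm.end) - arm.start
        if hi > lo:
            lost[lo:hi] = True
    return int(lost.sum()) / (arm.end - arm.start)


def make_segment(chrom, start, end, log2):
    return Segment(chrom, start, end, log2)
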