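import numpy as np
import pytest

from tgctevo.model import GenomicSegment, SomaticVariant


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def diploid_segment():
    return GenomicSegment("1", 1, 100_000_000, 1, 1)


@pytest.fixture
def gained_segment_21():
    return GenomicSegment("2", 1, 100_000_000, 2, 1)


def make_variant(chrom="1", pos=1000, alt_depth=30, depth=100, tnc=None):
    return SomaticVariant(
        chrom=chrom, pos=pos, ref="C", alt="T",
        tumour_ref_depth=depth - alt_depth, tumour_alt_depth=alt_depth,
        normal_ref_depth=40, normal_alt_depth=0,
        trinucleotide_class=tnc,
    )
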