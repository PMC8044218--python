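import numpy as np
import pytest

from repeat_regprof.config import AnalysisConfig
from repeat_regprof.formats_io import GenomicInterval, RepeatAnnotation, TFBSRecord


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_interval(chrom="chr1", start=0, end=100, strand=".", name="."):
    return GenomicInterval(chrom, start, end, strand, name)


def make_element(chrom="chr1", start=10_000, end=16_000, strand="+",
                 consensus_start=1, rep_name="L1PA2"):
    return RepeatAnnotation(
        interval=GenomicInterval(chrom, start, end, strand, rep_name),
        rep_name=rep_name, rep_class="LINE", rep_family="L1",
        consensus_start=consensus_start,
        consensus_end=consensus_start + (end - start) - 1,
    )


def make_site(chrom="chr1", start=0, end=100, tf="ESR1"):
    return TFBSRecord(interval=GenomicInterval(chrom, start, end, ".", tf), tf=tf)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=2_000,
                     max_len=120):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
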