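import pytest

from ecseq.io import TargetLocus
from ecseq.simulate import random_amplicon


@pytest.fixture
def amplicon():
    """A reproducible 100 bp amplicon on contig sim1 at position 1000."""
    return random_amplicon("amp1", length=100)


@pytest.fixture
def snv_target(amplicon):
    """A mid-amplicon SNV whose alt differs from the reference base."""
    off = 50
    ref = amplicon.sequence[off]
    alt = {"A": "G", "C": "G", "G": "C", "T": "C"}[ref]
    return TargetLocus(amplicon.contig, amplicon.start + off, ref, alt, "snv50")
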