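import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snailplot import SequenceRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(ident, length, gc=None, n=0):
    """Build a record from length, optional GC count, and N count."""
    atgc = length - n
    if gc is None:
        gc = atgc // 2
    return SequenceRecord(id=ident, length=length, gc_count=gc, at_count=atgc - gc, n_count=n)


def records_from_lengths(lengths, n_fraction=0.0):
    recs = []
    for i, length in enumerate(lengths):
        n = int(round(length * n_fraction))
        recs.append(make_record(f"s{i}", length, n=n))
    return recs


@pytest.fixture
def five_scaffolds():
    """Lengths 50,40,30,20,10 used by several worked examples."""
    return records_from_lengths([50, 40, 30, 20, 10])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">s1 description\nACGTNNacgtn\n>s2\nGGGGCCCCAAAA\nTTTT\n")
    return path
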