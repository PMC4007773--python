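import numpy as np
import pytest

from mirisoform import (
    PreprocessConfig,
    Read,
    ReferenceSet,
    make_mir30_fixture,
)


@pytest.fixture(scope="session")
def mir30():
    """4-member miR-30-like family with reads at the programmed 1:2:7 ratio."""
    ref, reads, ratio = make_mir30_fixture(n_reads=2000, seed=11)
    return ref, reads, ratio


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def default_cfg():
    return PreprocessConfig()


def make_read(seq, quality=40, read_id="r"):
    return Read(read_id, seq, tuple([quality] * len(seq)))


@pytest.fixture()
def tiny_reference():
    return ReferenceSet(
        mature={
            "mir-alpha-5p": "TGTAAACATCCTTGACTGGAAG",
            "mir-beta-3p": "CAACTAGACTGTGAGCTTCTAG",
        },
        hairpins={
            "mir-alpha": ("GGCATCGAT" "TGTAAACATCCTTGACTGGAAG"
                          "CTGACTGACTGACTGATCGATCGTAGC"),
            "mir-beta": ("TTACGGACT" "CAACTAGACTGTGAGCTTCTAG"
                         "AGGCTAGCTAGCTAGCTGATCGATCAG"),
        },
        version_label="test",
    )
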