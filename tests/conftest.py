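import numpy as np
import pytest

from indelsweep.alignment import HaplotypeAlignment
from indelsweep.synth import make_references


@pytest.fixture
def toy_alignment() -> HaplotypeAlignment:
    """Four sequences, three sites, ten total pairwise differences."""
    return HaplotypeAlignment(
        ids=["a", "b", "c", "d"],
        seqs=["AAA", "AAT", "ATT", "TTT"],
    )


@pytest.fixture
def two_pop_alignment() -> HaplotypeAlignment:
    rng = np.random.default_rng(42)
    anc = "".join(rng.choice(list("ACGT"), 60))
    seqs, pops = [], []
    for i in range(8):
        s = list(anc)
        if i < 4:  # fixed difference at column 10
            s[10] = "T" if anc[10] != "T" else "G"
        if i % 2:
            s[30] = "C" if anc[30] != "C" else "A"
        seqs.append("".join(s))
        pops.append("NL" if i < 4 else "ZK")
    return HaplotypeAlignment(
        ids=[f"s{i}" for i in range(8)], seqs=seqs, pop=pops
    )


@pytest.fixture(scope="session")
def indel_refs():
    return make_references(flank=150, del_len=49, seed=11)
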