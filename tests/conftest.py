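import numpy as np
import pytest

from tcrrecon.io import Clonotype, build_sample

# enough distinct in-frame junctions for small hand-built samples
_JUNCTIONS = [
    "TGTGCCAGCAGT" + mid + "TTT"
    for mid in ("GAA", "GGA", "CCA", "ACA", "TCA", "CTA", "ATA", "GTA", "AAA", "CAA")
]


def make_clonotype(i: int, count: int, v: str = None, j: str = "TRBJ2-1") -> Clonotype:
    nt = _JUNCTIONS[i % len(_JUNCTIONS)]
    from tcrrecon.io import translate_junction

    return Clonotype(
        v_call=v or f"TRBV{5 + i}-1*01",
        j_call=j,
        cdr3_nt=nt,
        count=count,
        cdr3_aa=translate_junction(nt),
    )


def make_sample(counts, sample_id="s", **metadata):
    """Small validated sample with one distinct clonotype per count."""
    clonotypes = [make_clonotype(i, c) for i, c in enumerate(counts)]
    return build_sample(sample_id, clonotypes, **metadata)


@pytest.fixture
def four_equal_sample():
    return make_sample([5, 5, 5, 5])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
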