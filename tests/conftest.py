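import numpy as np
import pytest

from dipscreen.constructs import InsertDesign, TargetConstruct, translate_cds
from dipscreen.data import load_aslov2_design, load_gal4_vp64

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate_cds(a + b + c) != "*"
]


def random_cds(length: int, seed: int) -> str:
    """Random stop-free CDS of the given length (multiple of 3)."""
    assert length % 3 == 0
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_CODONS) for _ in range(length // 3))


@pytest.fixture(scope="session")
def toy_target() -> TargetConstruct:
    """600-nt random stop-free CDS; k-mers are unique with overwhelming probability."""
    return TargetConstruct(name="toy600", cds=random_cds(600, seed=42))


@pytest.fixture(scope="session")
def small_design() -> InsertDesign:
    """Short 60-nt domain insert (same frame arithmetic as the real one)."""
    return InsertDesign(domain_seq=random_cds(60, seed=7), tsd_len=5)


@pytest.fixture(scope="session")
def gal4_target() -> TargetConstruct:
    return load_gal4_vp64()


@pytest.fixture(scope="session")
def lov_design() -> InsertDesign:
    return load_aslov2_design()
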