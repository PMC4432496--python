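import numpy as np
import pytest

from vntrcode.ru_library import load_packaged_library
from vntrcode.segmentation import SegmentationParams


@pytest.fixture(scope="session")
def lib():
    return load_packaged_library()


@pytest.fixture(scope="session")
def params():
    return SegmentationParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def sva_f_clean_set(lib):
    """Ten mutation-free SVA_F-like elements with their schemata."""
    from vntrcode.segmentation import segment_vntr
    from vntrcode.synthetic_data import generate_subfamily_set, load_packaged_grammar

    g = load_packaged_grammar("sva_f")
    g.mutation_rate = 0.0
    els, truths = generate_subfamily_set(g, 10, seed=4, lib=lib)
    schemata = [segment_vntr(e, lib) for e in els]
    return els, truths, schemata


def mutate(seq: str, n_subs: int, rng) -> str:
    """Apply n random substitutions (used to build noisy units in tests)."""
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
    return "".join(s)
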