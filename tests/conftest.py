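import pathlib

import pytest

from ptm_evoscan.datamodel_io import CladeHierarchy
from ptm_evoscan.synthetic_data import GeneratorParams, generate_bundle


@pytest.fixture
def tiny_hierarchy() -> CladeHierarchy:
    """Four nested levels over five species plus the reference."""
    hs = "homo_sapiens"
    return CladeHierarchy(
        [
            ("Apes", frozenset({hs, "pan"})),
            ("Primates", frozenset({hs, "pan", "macaca"})),
            ("Mammals", frozenset({hs, "pan", "macaca", "mus"})),
            ("Eukaryotes", frozenset({hs, "pan", "macaca", "mus", "yeast"})),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> pathlib.Path:
    """A 10-protein synthetic bundle shared by I/O and pipeline tests."""
    out = tmp_path_factory.mktemp("bundle")
    generate_bundle(GeneratorParams(seed=11, n_proteins=10), out)
    return out
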