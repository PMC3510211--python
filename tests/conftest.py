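"""Shared fixtures: hand-built substrate records and a reusable synthetic dataset."""

import pytest

from cleavesite.simulate import generate, make_preset
from cleavesite.substrates import (
    ProteaseDataset,
    SubstrateRecord,
    extract_windows,
)


@pytest.fixture
def tiny_dataset() -> ProteaseDataset:
    """Three short substrates with known cleavage sites (caspase-like P1 Asp)."""
    return ProteaseDataset(
        protease_id="TEST.1",
        substrates=[
            SubstrateRecord("sub1", "TEST.1", "AAADEVDGAAA", (7,)),
            SubstrateRecord("sub2", "TEST.1", "MKKDEVDSKKLMNDEVDGPQR", (7, 17)),
            SubstrateRecord("sub3", "TEST.1", "GGGGDEVDGGGG", (8,)),
        ],
    )


@pytest.fixture(scope="session")
def caspase_data():
    """Synthetic caspase-3-like dataset shared by model-level tests (fixed seed)."""
    spec = make_preset("caspase3_like")
    dataset, annotations, manifest = generate(spec, 60, seed=7)
    return dataset, annotations, manifest


@pytest.fixture(scope="session")
def caspase_windows(caspase_data):
    dataset, annotations, _ = caspase_data
    return extract_windows(dataset, span=(4, 2), negative_ratio=3.0, seed=7,
                           annotations=annotations)
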