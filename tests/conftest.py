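"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from barcodedms.design import (
    CodingSequence,
    build_full_design,
    generate_codebook,
)
from barcodedms.readproc import FragmentReference
from barcodedms.simulate import (
    SimulationConfig,
    random_cds,
    random_context,
    simulate_library,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240212)


@pytest.fixture(scope="session")
def codebook_small():
    """Codebook large enough to barcode a 1,068-codon CDS (2,136 members)."""
    return generate_codebook(k=12, target_size=2500, seed=5)


@pytest.fixture(scope="session")
def cds_full(rng):
    """A 3,204-nt (1,068-codon) synthetic coding sequence."""
    return random_cds(1068, np.random.default_rng(42), id="cds3204")


@pytest.fixture(scope="session")
def contexts(rng):
    r = np.random.default_rng(7)
    return random_context(r, 60), random_context(r, 20)


@pytest.fixture(scope="session")
def full_design(cds_full, codebook_small, contexts):
    """The complete 43-fragment oPool design."""
    up, down = contexts
    return build_full_design(
        cds_full,
        codebook_small,
        upstream_context=up,
        downstream_context=down,
        seed=3,
    )


@pytest.fixture(scope="session")
def toy_cds():
    return random_cds(25, np.random.default_rng(99), id="toy25")


@pytest.fixture(scope="session")
def toy_design(toy_cds, contexts):
    up, down = contexts
    codebook = generate_codebook(k=12, target_size=80, seed=13)
    return build_full_design(
        toy_cds, codebook, upstream_context=up, downstream_context=down, seed=13
    )


@pytest.fixture(scope="session")
def toy_ref(toy_design):
    return FragmentReference.from_design(toy_design, 1)


@pytest.fixture(scope="session")
def clean_truth():
    """Zero-error simulated library over one 25-codon fragment."""
    config = SimulationConfig(
        seed=17,
        cds_length_codons=25,
        barcodes_per_variant=5,
        transformant_count=8_000,
    )
    return simulate_library(config)
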