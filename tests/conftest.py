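import numpy as np
import pytest

from hexamir.synth import (
    make_catalog,
    make_genome,
    make_transcriptome,
    simulate_libraries,
)


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic experiment reused across integration tests."""
    contigs, truth = make_genome(
        n_contigs=2, contig_len=8000, n_hairpins=8, seed=11
    )
    make_catalog(truth, seed=12, n_decoys=10)
    make_transcriptome(truth, n_transcripts=12, seed=13)
    libs, tallies = simulate_libraries(truth, depth=20_000, seed=14)
    return {"contigs": contigs, "truth": truth, "libs": libs, "tallies": tallies}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
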