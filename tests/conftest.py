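import numpy as np
import pytest

from specswap import (
    MSA,
    KineticsSpec,
    MsaSpec,
    RateLawParams,
    StructureSpec,
    simulate_kinetics,
    simulate_msa,
    simulate_structure,
)


@pytest.fixture
def tiny_msa() -> MSA:
    """Four 6-column sequences with known column compositions."""
    return MSA(
        (
            ("s1", "ACDAA-"),
            ("s2", "ACEAW-"),
            ("s3", "ACDA--"),
            ("s4", "AC-GC-"),
        )
    )


@pytest.fixture
def random_msa() -> MSA:
    return simulate_msa(MsaSpec(n_sequences=20, n_columns=50, modal_fractions=0.5, seed=11))


@pytest.fixture
def planted_structure():
    distances = (2.0, 3.4, 5.0, 10.0, 12.0, 16.3, 20.0, 25.0)
    model, table = simulate_structure(StructureSpec(planted_distances=distances, seed=4))
    return model, table, distances


@pytest.fixture
def noiseless_kinetics():
    truth = RateLawParams(kcat=100.0, Km_AA=2.0, Km_cosub=0.5)
    spec = KineticsSpec(truth=truth, noise=0.0, seed=0)
    return simulate_kinetics(spec), truth
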