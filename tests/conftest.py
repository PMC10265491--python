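"""Shared fixtures: one forged genome per session plus small helpers."""

import numpy as np
import pytest

from genefam.synthetic_data import ForgeConfig, forge_genome


@pytest.fixture(scope="session")
def forged():
    """Default-condition forged genome with planted ground truth."""
    return forge_genome(ForgeConfig(rng_seed=11))


@pytest.fixture(scope="session")
def forged_models(forged):
    return forged.models_by_id()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_cds(rng, n_codons: int, with_stop: bool = True) -> str:
    """Random stop-free CDS for tests (uniform over sense codons)."""
    from genefam.synthetic_data import _AA_TO_CODONS

    codons = [c for cods in _AA_TO_CODONS.values() for c in cods]
    codons.sort()
    body = "".join(codons[int(rng.integers(len(codons)))] for _ in range(n_codons))
    return body + ("TAA" if with_stop else "")
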