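import numpy as np
import pytest

from coregscan import MiRRecord, PREMotifConfig, UTRRecord


@pytest.fixture
def mir21() -> MiRRecord:
    """miR-21-5p: mature 5'-UAGCUUAUCAGACUGAUGUUGA-3' (seed 2-7 AGCUUA)."""
    return MiRRecord("miR-21-5p", "UAGCUUAUCAGACUGAUGUUGA", family="miR-21",
                     conservation_class="broadly_conserved")


@pytest.fixture
def default_config() -> PREMotifConfig:
    return PREMotifConfig()


@pytest.fixture
def strict_config() -> PREMotifConfig:
    """The narrow optimal-element reading: position 5 limited to A/U."""
    return PREMotifConfig(canonical_pos5_alphabet=frozenset("AU"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220929)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture
def snca_like_record(rng) -> UTRRecord:
    """A 574-nt record mimicking the short-form SNCA 3'UTR length."""
    return UTRRecord("SNCA", "NM_000345.3", random_rna(rng, 574))
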