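import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from idppi.features import PaacConfig
from idppi.sequences import STANDARD_AA, ProteinSequence

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_sequence(rng: np.random.Generator, length: int, seq_id: str = "seq") -> ProteinSequence:
    residues = "".join(rng.choice(list(STANDARD_AA), size=length))
    return ProteinSequence(id=seq_id, residues=residues)


@pytest.fixture(scope="session")
def paac_cfg() -> PaacConfig:
    """Default configuration (lambda=50, w=0.05, the five packaged scales)."""
    return PaacConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
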