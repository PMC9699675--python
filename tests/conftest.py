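import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from octomir.seed_targets import MatureMiRNA
from octomir.synthetic import SyntheticConfig

LET7_MATURE = "UGAGGUAGUAGGUUGUAUAGUU"
LET7_MRE = "CTACCTCA"


@pytest.fixture
def let7() -> MatureMiRNA:
    return MatureMiRNA(name="let-7", mature_seq=LET7_MATURE, family="let-7", age_class="bilaterian")


@pytest.fixture
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_genes=30, n_mirnas=5, rng_seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
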