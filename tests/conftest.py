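import numpy as np
import pytest
from hypothesis import settings

from memri.twopool import (BiexpComponents, InversionState, TwoPoolParams,
                           rates_from_twopool)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=40)
settings.load_profile("suite")

#: baseline control operating point of the cell-pellet experiment
BASELINE_PSR = 0.0377
BASELINE_KMF = 14.8
BASELINE_T2_MS = 49.7
BASELINE_R1 = 0.5


@pytest.fixture(scope="session")
def baseline_pools() -> TwoPoolParams:
    return TwoPoolParams(r1f=BASELINE_R1, r1m=BASELINE_R1,
                         kmf=BASELINE_KMF, psr=BASELINE_PSR,
                         t2f=60e-3, t2m=10e-6)


@pytest.fixture(scope="session")
def baseline_inversion() -> InversionState:
    return InversionState(delta_f=-1.0, delta_m=0.83)


@pytest.fixture(scope="session")
def baseline_components(baseline_pools, baseline_inversion
                        ) -> BiexpComponents:
    return rates_from_twopool(baseline_pools, baseline_inversion)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250703)
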