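import math

import pytest
from hypothesis import HealthCheck, settings

from atcmfit import ATCMParams, SaturationParams

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Radioligand pK at the wild-type receptor in sodium buffer.
PKA_WT = 10.45


@pytest.fixture(scope="session")
def pka_wt() -> float:
    return PKA_WT


@pytest.fixture(scope="session")
def sat_wt() -> SaturationParams:
    """Saturation regime: Kd 0.04 nM, Bmax 237 fmol/mg, modest nonspecific slope."""
    return SaturationParams(pKd=PKA_WT, Bmax=237.0, ns_slope=1e10)


@pytest.fixture(scope="session")
def mips1726_wt() -> ATCMParams:
    """High-affinity, strongly negatively cooperative modulator regime."""
    return ATCMParams(pKA=PKA_WT, pKB=7.52, Bmax=237.0, log_alpha_rad=-1.90)


@pytest.fixture(scope="session")
def mips1868_wt() -> ATCMParams:
    """Modulator regime with KB 100 nM and cooperativity 0.04."""
    return ATCMParams(pKA=PKA_WT, pKB=7.00, Bmax=237.0, log_alpha_rad=-1.45)


@pytest.fixture(scope="session")
def sb269652_wt() -> ATCMParams:
    """Prototype NAM regime: KB 355 nM, cooperativity 0.35 with the
    radioligand and 0.29 with the orthosteric agonist (pKi 5.59)."""
    return ATCMParams(
        pKA=PKA_WT,
        pKB=6.45,
        Bmax=237.0,
        log_alpha_rad=-0.45,
        log_alpha_comp=-0.54,
        pKI=5.59,
    )


@pytest.fixture(scope="session")
def mips1071_wt() -> ATCMParams:
    """Competitive orthosteric fragment regime (Ki 1.3 µM, cooperativity 0)."""
    return ATCMParams(pKA=PKA_WT, pKB=5.90, Bmax=237.0, log_alpha_rad=-math.inf)
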