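import numpy as np
import pytest

from micellenmr import ExchangeParams, FieldSpec, SolventSpec


@pytest.fixture(scope="session")
def field_14t() -> FieldSpec:
    """The 14.1 T spectrometer (1H 599.98 MHz)."""
    return FieldSpec.from_proton_frequency(599.98e6)


@pytest.fixture(scope="session")
def micelle_exchange() -> ExchangeParams:
    """Two-site exchange parameters of the peptide-loaded micelle regime:
    2.8% minor state, kex 253/s, dw 5.2e3 rad/s, intrinsic rates
    31.25 and 5.26 /s."""
    return ExchangeParams.from_minor(p_b=0.028, k_ex=253.0,
                                     delta_omega=5.2e3, r2_a=31.25,
                                     r2_b=5.26)


@pytest.fixture(scope="session")
def water_303k() -> SolventSpec:
    return SolventSpec(temperature=303.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
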