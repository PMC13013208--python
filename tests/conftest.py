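import numpy as np
import pytest

from growdom import (
    DomainSpec,
    GrowthLaw,
    KernelSpec,
    ModelParams,
    PackingForm,
    ReferenceGrid,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def aggregation_params():
    """Constitutive constants of the aggregation case study (mu=1.2)."""
    return ModelParams(
        D=1e-3, omega=1.0, rho=0.0, U=1.0,
        packing=PackingForm("clipped", P=0.8),
        kernel=KernelSpec(xi=0.4, mu=1.2),
    )


@pytest.fixture
def exp_domain_L():
    """Exponentially growing Type L domain, L0=2, alpha=0.1, T=10."""
    return DomainSpec(
        growth=GrowthLaw(kind="exponential", L0=2.0, alpha=0.1),
        placement="L", t0=0.0, T=10.0,
    )


@pytest.fixture
def exp_domain_S():
    """Exponentially growing Type S domain, L0=11, alpha=0.007, T=240."""
    return DomainSpec(
        growth=GrowthLaw(kind="exponential", L0=11.0, alpha=0.007),
        placement="S", t0=0.0, T=240.0,
    )


@pytest.fixture
def grid256():
    return ReferenceGrid(256)
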