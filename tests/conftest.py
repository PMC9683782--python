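import numpy as np
import pytest

from morbidosim import CultureState, GrowthModel, StrainPhenotype


@pytest.fixture
def ancestor() -> StrainPhenotype:
    """Drug-susceptible baseline strain: r = 1/h, IC50 = 4 ug/mL, n = 2."""
    return StrainPhenotype(growth_rate=1.0, ic50=4.0, hill_coef=2.0)


@pytest.fixture
def model() -> GrowthModel:
    return GrowthModel(mutation_rate=0.0)


@pytest.fixture
def vial(ancestor) -> CultureState:
    return CultureState(time=0.0, volume=12.0, drug_conc=0.0,
                        subpops={ancestor: 0.01})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
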