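import numpy as np
import pytest

from copath.design import balanced_design
from copath.simulate import PlantedModuleSpec, simulate_pseudobulk


@pytest.fixture(scope="session")
def design7():
    """Balanced 2x2 design with 7 samples per genotype (28 samples)."""
    return balanced_design(7)


@pytest.fixture(scope="session")
def design3():
    return balanced_design(3)


@pytest.fixture(scope="session")
def planted_expression(design7):
    """Three planted modules (E4, NLF, interaction effects) plus background."""
    specs = [
        PlantedModuleSpec("A", 30, effect_e4=1.5, noise_sd=0.3),
        PlantedModuleSpec("B", 30, effect_nlf=1.5, noise_sd=0.3),
        PlantedModuleSpec("C", 30, effect_interaction=2.0, noise_sd=0.3),
    ]
    expr, modules, effects = simulate_pseudobulk(design7, specs, 60, seed=11)
    return expr, modules, effects
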