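import warnings

import pytest

from siactors import simodel
from siactors.population import PopulationConfig, generate_farm_population

# The printed source tables contain rows that do not sum to 100%; the loaders
# renormalize and warn.  The warnings are expected throughout the suite.
warnings.filterwarnings("ignore", message=".*renormalizing")


@pytest.fixture(scope="session")
def default_population():
    return generate_farm_population(PopulationConfig(seed=7))


@pytest.fixture(scope="session")
def calibrated():
    """Calibration results and calibrated networks for both sectors."""
    out = {}
    for sector in ("dairy", "fruit"):
        result = simodel.calibrate(sector)
        net = simodel.assemble_si_network(sector, result.params)
        out[sector] = (result, net)
    return out
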