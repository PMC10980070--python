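import numpy as np
import pytest

from soilregimes.crm import TIMEPOINTS_HR
from soilregimes.synthetic import SoilPanelSpec, make_soil_panel, simulate_counts


@pytest.fixture(scope="session")
def day_grid():
    """The experiment's measurement grid in days."""
    return np.asarray(TIMEPOINTS_HR) / 24.0


@pytest.fixture(scope="session")
def small_panel():
    """A 6-soil planted panel reused across regime/count tests."""
    return make_soil_panel(SoilPanelSpec(n_soils=6), seed=7)


@pytest.fixture(scope="session")
def count_panel(small_panel):
    """Synthetic count tables for two soils of the small panel."""
    table, truth = simulate_counts(
        small_panel, soil_ids=["S02", "S05"], n_asv=2000, seed=3
    )
    return table, truth
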