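import numpy as np
import pandas as pd
import pytest

from panelcal import synthetic


@pytest.fixture(scope="session")
def default_panel():
    """A mid-sized panel with the default planted careless profiles."""
    design = synthetic.PanelDesign(n_target=2500, seed=101)
    panel, truth = synthetic.generate_panel(
        design, synthetic.default_careless_profiles(), seed=101
    )
    return design, panel, truth


@pytest.fixture(scope="session")
def clean_panel():
    """A panel with no planted careless respondents."""
    design = synthetic.PanelDesign(n_target=2000, seed=55)
    panel, truth = synthetic.generate_panel(design, None, seed=55)
    return design, panel, truth


@pytest.fixture()
def tiny_unbiased_design():
    """Small design with no selection bias and equal quota fill."""
    return synthetic.PanelDesign(
        n_target=800,
        seed=9,
        stratum_fill={"male": 1.0, "female": 1.0},
        bias_profile={},
    )
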