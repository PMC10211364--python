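import pytest
from hypothesis import settings

from chronoveg.datasets import survey_abundance, survey_densities

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from chronoveg.synthetic import simulate_chronosequence, thornscrub_config

SMALL_INVENTORY = """site,plot,species,basal_diameter_cm,height_m
10,P1,Acacia farnesiana,3.2,2.1
10,P1,Acacia farnesiana,1.5,1.4
10,P1,Havardia pallens,2.0,1.8
>30,P1,Diospyros texana,8.0,5.5
>30,P1,Havardia pallens,4.1,3.9
>30,P1,Cordia boissieri,6.3,4.2
"""


@pytest.fixture
def small_inventory(tmp_path):
    """Six stems, two sites with one plot each."""
    path = tmp_path / "inv.csv"
    path.write_text(SMALL_INVENTORY)
    return path


@pytest.fixture(scope="session")
def survey():
    """Published per-site densities (N ha^-1) as an AbundanceMatrix."""
    return survey_abundance()


@pytest.fixture(scope="session")
def survey_frame():
    return survey_densities()


@pytest.fixture(scope="session")
def sim_chrono():
    """One deterministic draw from the shipped thornscrub configuration."""
    return simulate_chronosequence(thornscrub_config(seed=11))
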