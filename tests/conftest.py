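import numpy as np
import pytest

from tllue import SyntheticSiteConfig, load_pft_parameters, make_site


@pytest.fixture(scope="session")
def pft_table():
    return load_pft_parameters()


@pytest.fixture(scope="session")
def clean_site():
    """Three noise-free synthetic years at a mid-latitude deciduous site."""
    cfg = SyntheticSiteConfig(pft_code="DBF", latitude=45.0, years=3,
                              true_eps_msh=3.75, true_eps_msu=0.92,
                              noise_cv=0.0, gap_fraction=0.0, seed=42)
    records, truth = make_site(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
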