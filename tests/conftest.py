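import pytest

from sgchem.simulate import SimulationDesign, simulate_study


@pytest.fixture(scope="session")
def clean_design():
    """Default factorial design with the noise channels silenced: no decoy
    peaks and no unrelated features, so generator ground truth is exact."""
    return SimulationDesign(seed=1, decoy_peaks=0, n_noise_features=0,
                            intensity_sigma=0.3)


@pytest.fixture(scope="session")
def clean_study(clean_design):
    """(library, spectra, feature table, qPCR dataset, ground truth)."""
    return simulate_study(clean_design)
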