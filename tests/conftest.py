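import numpy as np
import pytest

from ctfpa import AcquisitionProtocol, AifParams, PhantomGeometry, TissueSpec
from ctfpa.synthetic import rasterize_subject


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def aif_params():
    return AifParams.from_peak()


@pytest.fixture(scope="session")
def tissue_specs():
    return {
        "carcinoma": TissueSpec("carcinoma", 42.0, mtt=20.0, baseline_hu=38.0),
        "parenchyma": TissueSpec("parenchyma", 106.8, mtt=20.0, baseline_hu=45.0),
    }


@pytest.fixture(scope="session")
def clean_subject(protocol, geometry, aif_params, tissue_specs):
    """Noise-free subject with a 20 s transit time (no outflow before the AIF peak)."""
    return rasterize_subject(protocol, geometry, aif_params, tissue_specs,
                             noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_subject(protocol, geometry, aif_params, tissue_specs):
    return rasterize_subject(protocol, geometry, aif_params, tissue_specs,
                             noise_sigma=5.0, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
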