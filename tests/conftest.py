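import numpy as np
import pytest

from fetalt2star import (
    AcquisitionSpec,
    PhantomSpec,
    TissueParams,
    build_label_volume,
    render_multiecho,
)


@pytest.fixture(scope="session")
def acq_default():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def phantom48():
    """Small noiseless phantom at 30 weeks shared across tests."""
    spec = PhantomSpec(gestational_age=30.0, grid_shape=(48, 48, 48), seed=1)
    labels = build_label_volume(spec)
    tissue = TissueParams.from_reference(spec.gestational_age)
    volume = render_multiecho(labels, tissue, AcquisitionSpec())
    return spec, labels, tissue, volume


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
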