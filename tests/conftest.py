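import pytest

from cuefuse.observer_models import Mechanism, ObserverParams, SessionDesign
from cuefuse.synthetic_fmri import EncodingModel, ScanDesign, generate_experiment


@pytest.fixture(scope="session")
def design() -> SessionDesign:
    return SessionDesign()


@pytest.fixture(scope="session")
def fusion_observer() -> ObserverParams:
    return ObserverParams(sigma_d=1.0, sigma_m=1.0, mechanism=Mechanism.FUSION)


@pytest.fixture(scope="session")
def independence_observer() -> ObserverParams:
    return ObserverParams(sigma_d=1.0, sigma_m=1.0, mechanism=Mechanism.INDEPENDENCE)


@pytest.fixture(scope="session")
def small_scan_design() -> ScanDesign:
    return ScanDesign()


@pytest.fixture(scope="session")
def independence_dataset(small_scan_design):
    """Synthetic scan with no fused channel (quadratic-sum regime)."""
    model = EncodingModel.random(n_voxels=150, seed=11, fused_gain=0.0, noise_sd=25.0)
    return generate_experiment(model, small_scan_design, seed=12)


@pytest.fixture(scope="session")
def fusion_dataset(small_scan_design):
    """Synthetic scan with a strong fused channel."""
    model = EncodingModel.random(n_voxels=150, seed=11, fused_gain=2.0, noise_sd=25.0)
    return generate_experiment(model, small_scan_design, seed=12)
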