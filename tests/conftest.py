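import numpy as np
import pytest

from littdce.curves import ConcentrationCurve
from littdce.pk_models import ToftsParams, tofts_forward
from littdce.signal_model import AcquisitionProtocol
from littdce.synthetic_data import population_aif


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def t_minutes(protocol) -> np.ndarray:
    return protocol.frame_times() / 60.0


@pytest.fixture(scope="session")
def aif(t_minutes) -> ConcentrationCurve:
    return population_aif(t_minutes)


@pytest.fixture(scope="session")
def tofts_truth() -> ToftsParams:
    # pre-treatment cohort mean transfer constant, typical interstitial fraction
    return ToftsParams(ktrans=0.22, ve=0.3)


@pytest.fixture(scope="session")
def clean_tissue_curve(tofts_truth, aif) -> ConcentrationCurve:
    return tofts_forward(tofts_truth, aif)


@pytest.fixture
def noisy_curve_factory(clean_tissue_curve):
    """Tissue curve with i.i.d. Gaussian noise at a fraction of the peak."""

    def make(seed: int, noise_frac: float = 0.02) -> ConcentrationCurve:
        rng = np.random.default_rng(seed)
        sigma = noise_frac * clean_tissue_curve.values.max()
        return ConcentrationCurve(
            clean_tissue_curve.times,
            clean_tissue_curve.values
            + rng.normal(0.0, sigma, len(clean_tissue_curve)),
        )

    return make
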