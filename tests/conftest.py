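import numpy as np
import pytest

from pdarkit.simulate import LEDTruth, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def degrader_truth():
    """A degrader-like drug: strong PTBP1/BCL2L12/DKO protection."""
    return LEDTruth(
        lf0=0.02, lfp=0.85, dr=0.1, do=12.0,
        genotype_factors={"PTBP1-KO": 0.2, "BCL2L12-KO": 0.3, "BAX-BAK-DKO": 0.05},
    )


@pytest.fixture(scope="session")
def panel_config(degrader_truth):
    """Small noiseless panel: reference degrader, an independent lethal
    drug without knockout protection, and a non-lethal drug."""
    return SimConfig(
        seed=7,
        noise_sd=0.0,
        drug_params={
            ("triptolide", 1.0): degrader_truth,
            ("staurosporine", 3.16): LEDTruth(lf0=0.02, lfp=0.8, dr=0.15, do=8.0),
            ("rapamycin", 10.0): LEDTruth(lf0=0.02, lfp=0.08, dr=0.05, do=24.0),
        },
    )
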