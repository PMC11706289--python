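import numpy as np
import pytest

from aphasiamap import GridGeometry, SimulationConfig, build_cohort


@pytest.fixture(scope="session")
def toy_grid() -> GridGeometry:
    return GridGeometry.isotropic((24, 24, 24), 4.0)


@pytest.fixture(scope="session")
def null_cohort():
    """A global-null cohort: lesions present, all ROI->dimension betas zero."""
    cfg = SimulationConfig(n_participants=60, seed=42, betas=np.zeros((4, 4)))
    return build_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong Temporal->Paraphasia effect with modest noise; n = 60."""
    betas = np.zeros((4, 4))
    betas[2, 0] = 0.9  # Temporal -> Paraphasia
    cfg = SimulationConfig(
        n_participants=60, seed=7, betas=betas, noise_sd=(6.0, 6.0, 6.0, 6.0)
    )
    return build_cohort(cfg)
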