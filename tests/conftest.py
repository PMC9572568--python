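import numpy as np
import pytest

from spikedspec import DesignSpec, StudyConfig, generate_dataset, run_full_study


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced 3x3 design: fast, fully structured (pure + spiked per combo)."""
    spec = DesignSpec(n_pure_per_combo=4, n_spiked_per_combo=6,
                      noise_sd=2e-4, seed=7)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def full_dataset():
    """The full default design (513 samples) at the default seed."""
    return generate_dataset(DesignSpec(seed=0))


@pytest.fixture(scope="session")
def study_report():
    """One full study at the default configuration (seed 0); shared because
    it is the most expensive object the suite builds."""
    return run_full_study(StudyConfig(seed=0))
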