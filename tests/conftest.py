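import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from canopyflux import imaging, synth

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def geometry():
    return imaging.ImageGeometry()


@pytest.fixture(scope="session")
def zero_noise_experiment():
    """Noise-free perpendicular-gradient experiment (exact ground truth)."""
    return synth.simulate_experiment(
        params=synth.TruePlantParams().without_noise(), seed=11
    )


@pytest.fixture(scope="session")
def noisy_experiment():
    """Default-noise perpendicular-gradient experiment."""
    return synth.simulate_experiment(seed=11)


def segment_experiment(exp, threshold=10000):
    """Render every scheduled frame and segment it into a PCS series."""
    rows = [
        (im.plant_id, im.day, imaging.measure_pcs(im, threshold).pcs_cm2)
        for im in exp.iter_images()
    ]
    return pd.DataFrame(rows, columns=["plant_id", "day", "pcs_cm2"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
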