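import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from tacdose.data import TimeActivitySample, VoiSeries  # noqa: E402
from tacdose.tac_models import ModelId, TacParams, evaluate  # noqa: E402

STUDY_TIMES_H = (19.0, 42.0, 66.0, 170.0)


def make_series(params: TacParams, model: ModelId = ModelId.MONO,
                times=STUDY_TIMES_H, volume_ml: float = 20.0, mean_HU: float = 50.0,
                patient_id: str = "P01", voi_id: str = "L01",
                voi_type: str = "lesion", noise_cv: float = 0.0,
                rng: np.random.Generator | None = None) -> VoiSeries:
    """Series sampled exactly (or noisily) from a known TAC."""
    samples = []
    for t in times:
        a = float(evaluate(model, params, t))
        if noise_cv > 0.0:
            a *= max(1.0 + noise_cv * rng.standard_normal(), 1e-3)
        samples.append(TimeActivitySample(t, a, volume_ml, mean_HU))
    return VoiSeries(patient_id, voi_id, voi_type, samples)


@pytest.fixture
def mono_params() -> TacParams:
    return TacParams(a0=50.0, lambda_bio=5e-3)


@pytest.fixture
def mono_series(mono_params) -> VoiSeries:
    return make_series(mono_params)
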