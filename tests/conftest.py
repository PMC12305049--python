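import numpy as np
import pytest

from medusleep.synthetic import BehaviorGenParams, gen_cohort
from medusleep.workflow import cohort_day_night, score_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def control_cohort_result():
    """Full-pipeline result for the seeded 10-animal control cohort
    (2 days / 2 nights, default calibrated parameters). Session-scoped:
    the end-to-end run is the most expensive fixture in the suite."""
    traces, truths = gen_cohort("control", 10, 2, params=BehaviorGenParams(), seed=1)
    hypnos = score_cohort(traces)
    day_pct, night_pct = cohort_day_night(hypnos)
    return {"hypnograms": hypnos, "truths": truths,
            "day_pct": day_pct, "night_pct": night_pct}
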