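import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, max_examples=60)
settings.load_profile("repro")

from plggvol.growth import GrowthParams
from plggvol.measurements import LesionMeasurement, ParticipantSeries, TimePoint
from plggvol.simulate import CohortConfig, simulate_cohort


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="zero solid volume")
        warnings.filterwarnings("ignore", message=".*no pretreatment image.*")
        warnings.filterwarnings("ignore", message=".*acceptance fraction.*")
        yield


def make_series(volumes, times=None, pid="P1", new_lesion_at=()):
    """Series with one lesion per image carrying only a solid volume."""
    if times is None:
        times = [0.0 if i == 0 else 61.0 * i for i in range(len(volumes))]
    tps = [
        TimePoint(
            participant_id=pid,
            t_days=t,
            lesions=(LesionMeasurement("L1", base_volume=v),),
            new_lesion=(t in new_lesion_at),
        )
        for t, v in zip(times, volumes)
    ]
    return ParticipantSeries(pid, tps)


@pytest.fixture
def simple_series():
    return make_series([10.0, 12.5, 8.0])


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-participant cohort reused by slower integration tests."""
    cfg = CohortConfig(
        n_participants=10, n_late_assessments=5, class_counts=(4, 5, 6), seed=3
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def dip_regrow_params():
    """Identifiable trajectory: clear shrinkage then regrowth within 600 d."""
    return GrowthParams(lam=0.004, gamma0=0.02, eps=0.01, V_b=20.0)
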