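import datetime as dt

import numpy as np
import pytest

from walkir import (
    CohortConfig,
    IRParameters,
    SessionPrescription,
    SubjectBaseline,
    build_trimp_series,
    generate_prescriptions,
)


@pytest.fixture
def worked_example_session() -> SessionPrescription:
    """The published worked example: 10 x 1-min walks at 60 steps/min, 1-min rests."""
    return SessionPrescription(
        date=dt.date(2018, 1, 1),
        cadence=60,
        walk_unit_min=1,
        rest_unit_min=1,
        repetitions=10,
        performed_fraction=1.0,
    )


@pytest.fixture
def worked_example_baseline() -> SubjectBaseline:
    return SubjectBaseline(habitual_speed=100, p0_pfwd=114, p0_6mwd=287)


@pytest.fixture(scope="session")
def tito_trimps():
    """A standard 27-week TiTo TRIMP series (habitual 100 steps/min, cap 95%)."""
    baseline = SubjectBaseline(habitual_speed=100, p0_pfwd=114, p0_6mwd=287)
    sessions = generate_prescriptions(baseline, CohortConfig(), weeks=27, cap=0.95)
    return build_trimp_series(sessions, baseline)


@pytest.fixture
def published_mean_params_pfwd() -> IRParameters:
    return IRParameters(p0=114, k1=0.03, k2=0.03, tau1=45, tau2=25)


@pytest.fixture
def published_mean_params_6mwd() -> IRParameters:
    return IRParameters(p0=287, k1=0.02, k2=0.03, tau1=37, tau2=26)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
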