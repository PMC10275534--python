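import numpy as np
import pytest

from bgconn.pipeline import PipelineConfig, cohort_connectivity
from bgconn.synthetic import GroundTruthSpec, default_atlas, simulate_cohort
from bgconn.types import ParcelTimeSeries


#: small design for fast end-to-end tests: 20 parcels across the 7
#: networks, 6 trials per run, 2 task runs
SMALL_KWARGS = dict(
    n_parcels=20,
    network_sizes=(3, 3, 3, 3, 2, 3, 3),
    n_task_runs=2,
    n_trials_per_run=9,
    rest_duration_s=160.0,
    spike_prob=0.0,
)


def small_spec(**overrides) -> GroundTruthSpec:
    kwargs = {**SMALL_KWARGS, "n_subjects": 3, "seed": 42}
    kwargs.update(overrides)
    return GroundTruthSpec(**kwargs)


@pytest.fixture
def toy_ts():
    """Deterministic 2-parcel series for container-level tests."""
    rng = np.random.default_rng(0)
    return ParcelTimeSeries(
        data=rng.normal(size=(40, 2)), tr_s=2.0, parcel_ids=("a", "b")
    )


def sinusoid_ts(period_s: float, tr_s: float = 2.0, duration_s: float = 480.0,
                amplitude: float = 1.0) -> ParcelTimeSeries:
    t = np.arange(0, duration_s, tr_s)
    x = amplitude * np.sin(2 * np.pi * t / period_s)
    return ParcelTimeSeries(data=x[:, None], tr_s=tr_s, parcel_ids=("p1",))


# ---------------------------------------------------------------------------
# shared cohort at the study-condition defaults (session-scoped: the
# simulation and connectivity estimation are reused by several suites)


@pytest.fixture(scope="session")
def cohort20_spec():
    return GroundTruthSpec(n_subjects=20, seed=2024)


@pytest.fixture(scope="session")
def cohort20(cohort20_spec):
    return simulate_cohort(cohort20_spec)


@pytest.fixture(scope="session")
def cohort20_matrices(cohort20):
    config = PipelineConfig(include_raw_task=True)
    matrices, qc_table, excluded = cohort_connectivity(cohort20, config)
    assert not excluded
    return matrices


@pytest.fixture(scope="session")
def atlas100(cohort20_spec):
    return default_atlas(cohort20_spec)
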