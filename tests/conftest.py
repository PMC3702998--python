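import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prestim_extinct import paradigm, synthetic
from prestim_extinct.config import (
    GroundTruth,
    PipelineConfig,
    reduced_dcm_paradigm,
    strong_modulation_truth,
)

matplotlib.use("Agg")

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# study-condition seeds, fixed once for the whole suite
SCHEDULE_SEED = 101
RESPONSE_SEED = 202
NOISE_SEED = 303


def make_labelled_schedule(n_runs=9, seed=SCHEDULE_SEED, resp_seed=RESPONSE_SEED, **kw):
    sch = paradigm.generate_schedule(n_runs=n_runs, seed=seed, **kw)
    sch = paradigm.simulate_responses(sch, seed=resp_seed)
    return paradigm.classify_trials(sch)


@pytest.fixture(scope="session")
def default_schedule():
    """Full-scale labelled schedule: 9 runs x 35 trials."""
    return make_labelled_schedule()


@pytest.fixture(scope="session")
def default_dataset(default_schedule):
    """Default-truth synthetic ROI dataset at the paradigm's full scale."""
    return synthetic.generate_dataset(default_schedule, GroundTruth(), seed=NOISE_SEED)


@pytest.fixture(scope="session")
def reduced_schedule():
    """Scaled-down labelled schedule for model-inversion studies."""
    p = reduced_dcm_paradigm()
    sch = paradigm.generate_schedule(
        n_runs=p.n_runs,
        composition=paradigm.default_composition(p.n_bilateral, p.n_unilateral),
        seed=SCHEDULE_SEED,
        run_length=p.run_length,
    )
    sch = paradigm.simulate_responses(sch, p_extinguish=0.45, seed=RESPONSE_SEED)
    return paradigm.classify_trials(sch)


@pytest.fixture(scope="session")
def strong_dataset(reduced_schedule):
    """High-SNR dataset from the strongly modulated (both, both) truth."""
    return synthetic.generate_dataset(
        reduced_schedule, strong_modulation_truth(), seed=NOISE_SEED
    )


@pytest.fixture(scope="session")
def dcm_confounds(reduced_schedule):
    from prestim_extinct import glm

    X0, _ = glm.nuisance_matrix(
        reduced_schedule.n_scans, reduced_schedule.run_length, reduced_schedule.tr
    )
    return X0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config(tmp_path):
    """Smallest end-to-end configuration that still exercises every stage."""
    cfg = PipelineConfig(
        seed=5,
        out_dir=str(tmp_path / "out"),
        paradigm=reduced_dcm_paradigm(),
        truth=strong_modulation_truth(),
    )
    cfg.paradigm.n_runs = 1
    cfg.paradigm.n_bilateral = 6
    cfg.paradigm.n_unilateral = 1
    cfg.paradigm.run_length = 70
    cfg.dcm.max_iter = 48
    return cfg
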