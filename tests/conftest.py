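import numpy as np
import pytest

from sizeconstancy.distance_network import (
    DistanceNetwork,
    TrainingConfig,
    make_training_grid,
    perceived_distance_teacher,
    train_readout,
)
from sizeconstancy.experiments import run_experiment, sperandio_protocol
from sizeconstancy.tuning import (
    default_disparity_population,
    default_vergence_population,
)


@pytest.fixture(scope="session")
def disparity_pop():
    return default_disparity_population()


@pytest.fixture(scope="session")
def vergence_pop():
    return default_vergence_population()


@pytest.fixture(scope="session")
def trained_default():
    """Network trained on the perceived-distance teacher at module defaults,
    with its grid, teacher and the design matrix (shared across tests)."""
    net = DistanceNetwork()
    cfg = TrainingConfig(seed=11)
    grid = make_training_grid(cfg)
    teacher = perceived_distance_teacher(grid, max_distance=cfg.max_distance)
    train_readout(net, cfg, teacher=teacher, grid=grid)
    return {
        "net": net,
        "cfg": cfg,
        "grid": grid,
        "teacher": teacher,
        "X": net.design_matrix(grid),
    }


@pytest.fixture(scope="session")
def experiment_readout():
    """Distance readout trained with the experiments' working-range teacher
    (the feedback loop used by the built-in paradigms)."""
    net = DistanceNetwork()
    cfg = TrainingConfig(seed=5, max_distance=2.0)
    train_readout(net, cfg)
    return net


@pytest.fixture(scope="session")
def sperandio_result():
    """Full two-presentation experiment with the trained readout loop."""
    spec = sperandio_protocol(seed=5)
    return spec, run_experiment(spec)
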