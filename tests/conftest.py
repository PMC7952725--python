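import numpy as np
import pytest

from emgvalence.config import RunConfig, SimulationConfig, TrialSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_exp1_cfg():
    """Scaled-down film-style config for fast raw-signal tests."""
    return SimulationConfig(
        n_participants=4,
        trial_spec=[
            TrialSpec(30.0, "anger", True, 2.5),
            TrialSpec(25.0, "neutral", True, 5.0),
            TrialSpec(30.0, "amusement", True, 7.5),
        ],
        device_spec={"wired": 1000.0, "wearable": 500.0},
        seed=7,
    )


@pytest.fixture
def tiny_exp2_cfg():
    """Scaled-down exergame-style config with artifacts, wearable only."""
    return SimulationConfig(
        n_participants=4,
        trial_spec=[
            TrialSpec(25.0, "frame", False, 6.0),
            TrialSpec(30.0, "frame", False, 6.0),
            TrialSpec(20.0, "frame", False, 6.0),
        ],
        device_spec={"wearable": 500.0},
        gamma10_cs=-0.05,
        gamma10_zm=0.05,
        artifact_rate_per_min=4.0,
        artifact_duration_s=2.0,
        seed=11,
    )


@pytest.fixture
def tiny_run_cfg(tiny_exp1_cfg, tmp_path):
    cfg = RunConfig(preset="exp1", seed=7, outdir=str(tmp_path / "run"))
    cfg.sim = tiny_exp1_cfg
    return cfg
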