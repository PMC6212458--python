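import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from vpalloc.fitting import ModelSpec
from vpalloc.simulate import DesignConfig, generate_experiment

# Representative generating parameters: chosen to reproduce the task's
# observed error scale (~1.2 dva mean error at high priority) for 10-dva
# targets; see docs/methods.md.
GEN_PRECISION = {"Jbar_total": 3.0, "tau": 0.5}
GEN_LAM = 5.0


@pytest.fixture(scope="session")
def exp1_flexible_trials():
    """600 estimation-only trials from the Flexible model at the group-mean allocation."""
    spec = ModelSpec(experiment=1, strategy="flexible")
    theta = {**GEN_PRECISION, "p_high": 0.49, "p_med": 0.28}
    return spec, theta, generate_experiment(spec, theta, DesignConfig(), rng_seed=101)


@pytest.fixture(scope="session")
def exp2_flexible_trials():
    """600 joint error+wager trials from the Flexible model."""
    spec = ModelSpec(experiment=2, strategy="flexible")
    theta = {**GEN_PRECISION, "p_high": 0.44, "p_med": 0.31, "lam": GEN_LAM}
    return spec, theta, generate_experiment(spec, theta, DesignConfig(), rng_seed=202)


@pytest.fixture(scope="session")
def exp2_cohort():
    """Six synthetic wager-experiment participants for behavioral analyses."""
    spec = ModelSpec(experiment=2, strategy="flexible")
    theta = {**GEN_PRECISION, "p_high": 0.44, "p_med": 0.31, "lam": GEN_LAM}
    ss = np.random.SeedSequence(303)
    import pandas as pd

    frames = [
        generate_experiment(
            spec, theta, DesignConfig(), rng_seed=child.generate_state(1)[0] % 2**31,
            participant=pid,
        )
        for pid, child in enumerate(ss.spawn(6))
    ]
    return pd.concat(frames, ignore_index=True)
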