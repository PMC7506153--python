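import logging
from dataclasses import replace

import numpy as np
import pytest

from radstage.pipeline import RunConfig, run_pipeline

logging.getLogger("radstage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_run():
    """The full default pipeline: 100 subjects, 70/30 split, fixed seed."""
    return run_pipeline(RunConfig(seed=1))


def small_run_config(seed: int = 3) -> RunConfig:
    """A reduced but complete pipeline configuration (16 subjects)."""
    cfg = RunConfig(seed=seed, cv_folds=3, mrmr_keep=8, n_lambda=25)
    cfg.phantom = replace(cfg.phantom, n_subjects=16)
    return cfg


@pytest.fixture(scope="session")
def small_run():
    return run_pipeline(small_run_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
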