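import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import gazetrade as gz


@pytest.fixture(scope="session")
def default_config():
    return gz.TaskConfig()


@pytest.fixture(scope="session")
def default_schedule(default_config):
    return gz.generate_task(default_config, seed=0)


@pytest.fixture(scope="session")
def small_config():
    """A shortened session: one color set, 102 trials."""
    return gz.TaskConfig(color_probs_per_block=((0.0, 0.5, 1.0),),
                         block_composition=((24, 12, 12), (54, 0, 0)))


@pytest.fixture(scope="session")
def demo_cohort():
    """Four simulated participants on the full design."""
    return gz.generate_cohort(gz.CohortSpec(n_participants=4, seed=5))


@pytest.fixture(scope="session")
def demo_participant(demo_cohort):
    return demo_cohort.participants[0]


@pytest.fixture(scope="session")
def demo_params():
    rng = np.random.default_rng(0)
    return gz.sample_params(gz.default_generating_hyperparams(), 1, rng)[0]


def make_combined_trial(p_color_left=0.0, p_color_right=1.0,
                        up_left=3, up_right=9, trial=0):
    """A fixed combined trial with deterministic ring layouts."""
    def ring(up):
        return tuple(i < up for i in range(12))
    left = gz.Stimulus(side="left", color_id=0, p_color=p_color_left,
                       up_count=up_left, orientations=ring(up_left))
    right = gz.Stimulus(side="right", color_id=1, p_color=p_color_right,
                        up_count=up_right, orientations=ring(up_right))
    return gz.Trial(block=0, trial=trial, trial_type="combined",
                    left=left, right=right)
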