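import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from moodrpe.model import MoodParams
from moodrpe.task import Gamble, Session, TrialRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_trial_session() -> Session:
    """Trial 1: certain +1 chosen; trial 2: gamble with EV +0.5 chosen,
    outcome +1 revealed (RPE +0.5); one probe after trial 2."""
    trials = [
        TrialRecord(index=1, choice="certain", cr=1.0, outcome=1.0,
                    revealed=True, offered_certain=1.0,
                    offered_gamble=Gamble(2.0, 0.0, 0.5)),
        TrialRecord(index=2, choice="gamble", ev=0.5, outcome=1.0,
                    revealed=True, rpe=0.5, offered_certain=0.2,
                    offered_gamble=Gamble(1.0, 0.0, 0.5)),
    ]
    return Session(variant="lab", trials=trials, probe_after=[2])


@pytest.fixture
def grid_params() -> MoodParams:
    """Generating parameters with gamma on the default fitting grid."""
    return MoodParams(w0=0.5, gamma=0.4, w_cr=0.25, w_ev=0.25, w_rpe=0.25)


@pytest.fixture
def lab_session():
    from moodrpe.cohort import ChoiceParams, build_session_template, simulate_choices

    template = build_session_template("lab", seed=11)
    return simulate_choices(template, ChoiceParams(), seed=12)
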