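import numpy as np
import pytest

from knee_nma.data import NetworkDataset, Trial, TrialArm
from knee_nma.simulate import default_scenario, generate_network


def continuous_arm(trial_id, treatment, n=100, mean=-1.0, sd=2.5, scale_max=10.0):
    return TrialArm(
        trial_id=trial_id,
        treatment=treatment,
        n=n,
        mean_change=mean,
        sd_change=sd,
        scale_max=scale_max,
    )


def binary_arm(trial_id, treatment, n=100, events=10):
    return TrialArm(trial_id=trial_id, treatment=treatment, n=n, events=events)


def jsw_arm(trial_id, treatment, n=100, narrowing=0.3, sd=0.5):
    return TrialArm(
        trial_id=trial_id, treatment=treatment, n=n, mean_narrowing_mm=narrowing, sd_mm=sd
    )


def two_arm_continuous_dataset(rows, outcome_kind="pain_smd"):
    """rows: list of (trial_id, treat_a, mean_a, treat_b, mean_b) with shared n/sd."""
    trials = []
    for tid, ta, ma, tb, mb in rows:
        trials.append(
            Trial(
                trial_id=tid,
                arms=(continuous_arm(tid, ta, mean=ma), continuous_arm(tid, tb, mean=mb)),
            )
        )
    return NetworkDataset(trials=tuple(trials), outcome_kind=outcome_kind)


@pytest.fixture(scope="session")
def pain_scenario():
    return default_scenario("pain_smd")


@pytest.fixture(scope="session")
def pain_network(pain_scenario):
    """One fixed draw of the default 54-trial pain network plus its truth."""
    return generate_network(pain_scenario, seed=20250926)


@pytest.fixture(scope="session")
def ae_network():
    scn = default_scenario("withdrawal_ae")
    return generate_network(scn, seed=20250926)
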