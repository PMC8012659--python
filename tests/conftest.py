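import numpy as np
import pytest

from spikecode.data import CLASSES, NeuronRecord, TrialRecord
from spikecode.simulate import SimulationSpec, default_archetype, simulate_neuron


def make_trial(spikes, class_label="c1", task="TPDT", outcome="hit",
               trial_id="t0", pb=7.0):
    events = {"pd": -3.0, "p1_on": 0.0, "p1_off": 1.0, "p2_on": 3.0,
              "p2_off": 4.0, "pu": 6.0, "ku": 6.3, "pb": pb}
    return TrialRecord(trial_id=trial_id, class_label=class_label, task=task,
                       outcome=outcome, event_times=events,
                       spike_times=np.asarray(spikes, float))


def poisson_trial(rng, rate=10.0, class_label="c1", outcome="hit",
                  task="TPDT", trial_id="t0"):
    """Homogeneous Poisson trial spanning the full task epoch."""
    n = rng.poisson(rate * 11.5)
    spikes = np.sort(rng.uniform(-3.0, 8.5, n))
    return make_trial(spikes, class_label, task, outcome, trial_id)


def flat_neuron(seed=0, rate=10.0, trials_per_class=6, with_errors=False,
                neuron_id="flat"):
    """Class-independent Poisson neuron (a null for every coding analysis)."""
    rng = np.random.default_rng(seed)
    trials = []
    for c in CLASSES:
        for k in range(trials_per_class):
            trials.append(poisson_trial(rng, rate, c, "hit",
                                        trial_id=f"{c}h{k}"))
        if with_errors:
            for k in range(2):
                trials.append(poisson_trial(rng, rate, c, "error",
                                            trial_id=f"{c}e{k}"))
    return NeuronRecord(neuron_id=neuron_id, trials=trials)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sensory_neuron():
    rng = np.random.default_rng(11)
    return simulate_neuron(default_archetype("sensory"),
                           SimulationSpec(seed=11), "sens0", rng)


@pytest.fixture(scope="session")
def categorical_neuron():
    rng = np.random.default_rng(12)
    return simulate_neuron(default_archetype("categorical"),
                           SimulationSpec(seed=12), "cat0", rng)
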