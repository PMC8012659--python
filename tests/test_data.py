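"""Rate estimation, PSTHs, z-scoring and session round-trips."""

import numpy as np
import pytest

from spikecode.data import (NeuronRecord, SessionFormatError, backtransform,
                            class_psth, estimate_rate, population_tensor,
                            read_session, time_grid, write_session,
                            zscore_rates)
from spikecode.simulate import SimulationSpec, simulate_population

from conftest import flat_neuron, make_trial


class TestEstimateRate:
    def test_uniform_spikes_give_uniform_rate(self):
        spikes = np.arange(0.05, 1.0, 0.1)  # 10 spikes, one per 100 ms
        rs = estimate_rate(make_trial(spikes), 200, 50, t_start=0.2, t_end=0.8)
        assert np.allclose(rs.values, 10.0)

    def test_zero_spikes_gives_zero_series(self):
        rs = estimate_rate(make_trial([]), 200, 50, t_start=-1, t_end=7.5)
        assert np.all(rs.values == 0)

    def test_single_spike_window_algebra(self):
        trial = make_trial([0.1])
        rs = estimate_rate(trial, 200, 50, t_start=0.1, t_end=0.3)
        # bin centered 0.1: window [0, 0.2) holds the spike -> 1/0.2 = 5 sp/s
        assert rs.values[0] == pytest.approx(5.0)
        # bin centered 0.25: window [0.15, 0.35) is empty
        assert rs.values[np.isclose(rs.bin_centers, 0.25)][0] == 0.0

    def test_default_grid_has_170_bins(self):
        assert time_grid(-1.0, 7.5, 50.0).size == 170

    def test_square_kernel_conserves_spikes(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 1, 57))
        # non-overlapping 100-ms windows tile [0, 1)
        rs = estimate_rate(make_trial(spikes), 100, 100,
                           t_start=0.05, t_end=1.06)  # 10 windows tile [0, 1)
        assert rs.values.sum() * 0.1 == pytest.approx(57)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_rate(make_trial([0.5]), 200, 50, t_start=1.0, t_end=1.0)


class TestPsth:
    def test_identical_trains_give_identical_class_means(self):
        spikes = [0.1, 0.5, 2.0]
        trials = [make_trial(spikes, c, trial_id=f"{c}{k}")
                  for c in ("c1", "c2", "c3", "c4") for k in range(2)]
        nr = NeuronRecord(neuron_id="n", trials=trials)
        _, cr, gm = class_psth(nr)
        assert np.allclose(cr, cr[:, [0]])
        assert np.allclose(gm, cr[:, 0])

    def test_grand_mean_is_unweighted_class_mean(self):
        # two classes at 10 sp/s, two at 20 sp/s (regular trains)
        slow = np.arange(-2.95, 8.4, 0.1)
        fast = np.arange(-2.975, 8.4, 0.05)
        trials = [make_trial(slow, c, trial_id=f"{c}a") for c in ("c1", "c2")]
        trials += [make_trial(fast, c, trial_id=f"{c}a") for c in ("c3", "c4")]
        nr = NeuronRecord(neuron_id="n", trials=trials)
        _, cr, gm = class_psth(nr)
        inner = slice(20, 150)  # away from train edges
        assert np.allclose(gm[inner], 15.0)

    def test_missing_class_raises_with_class_name(self):
        trials = [make_trial([0.1], c, trial_id=c) for c in ("c1", "c2", "c4")]
        nr = NeuronRecord(neuron_id="n", trials=trials)
        with pytest.raises(ValueError, match="c3"):
            class_psth(nr)

    def test_population_grand_mean_invariant(self):
        neurons = [flat_neuron(seed=s, neuron_id=f"n{s}") for s in range(3)]
        pop = population_tensor(neurons)
        assert np.allclose(pop.grand_mean, pop.class_rates.mean(axis=2))


class TestZScore:
    def test_known_mean_sd_gives_exact_z(self):
        # regular trains whose spacing divides the 200-ms window give exactly
        # constant rate estimates: hits at 10 and 20 sp/s -> mean 15, sd 5
        slow = np.arange(-2.97, 8.4, 0.1)    # 10 sp/s
        fast = np.arange(-2.97, 8.4, 0.05)   # 20 sp/s
        trials = []
        for c in ("c1", "c2", "c3", "c4"):
            trials.append(make_trial(slow, c, trial_id=f"{c}a"))
            trials.append(make_trial(fast, c, trial_id=f"{c}b"))
        nr = NeuronRecord(neuron_id="n", trials=trials)
        centers, z, mean, sd = zscore_rates(nr, t_start=0.0, t_end=7.0)
        assert mean == pytest.approx(15.0)
        assert sd == pytest.approx(5.0)
        # a trial at 25 sp/s sits at z = (25 - 15) / 5 = 2
        trial25 = make_trial(np.arange(-2.97, 8.4, 0.04), "c1", trial_id="x")
        _, z25, _, _ = zscore_rates(nr, [trial25], t_start=0.0, t_end=7.0)
        assert np.allclose(z25, 2.0)

    def test_trial_at_hit_mean_has_zero_z(self, sensory_neuron):
        hits = sensory_neuron.select(task="TPDT", outcome="hit")
        _, z, mean, sd = zscore_rates(sensory_neuron, hits)
        # average z over all hit trials and bins is 0 by construction
        assert abs(z.mean()) < 1e-12

    def test_backtransform_inverts_zscore(self, sensory_neuron):
        centers, z, mean, sd = zscore_rates(sensory_neuron)
        hits = sensory_neuron.select(task="TPDT")
        from spikecode.data import trial_rate_matrix
        _, rates = trial_rate_matrix(hits)
        assert np.allclose(backtransform(z, mean, sd), rates)

    def test_backtransform_of_zero_gives_population_mean(self):
        assert backtransform(np.zeros(3), 12.5, 2.0) == pytest.approx(12.5)


class TestSessionIO:
    def test_round_trip_preserves_semantics(self, tmp_path):
        neurons, _ = simulate_population(SimulationSpec(n_neurons=2, seed=5))
        write_session(neurons, tmp_path)
        back = read_session(tmp_path)
        assert len(back) == len(neurons)
        for a, b in zip(neurons, sorted(back, key=lambda n: n.neuron_id)):
            assert a.neuron_id == b.neuron_id
            assert len(a.trials) == len(b.trials)
            for ta, tb in zip(a.trials, b.trials):
                assert ta.class_label == tb.class_label
                assert ta.outcome == tb.outcome
                assert np.allclose(ta.spike_times, tb.spike_times, atol=1e-4)

    def test_jsonl_dialect_round_trips(self, tmp_path):
        neurons, _ = simulate_population(SimulationSpec(n_neurons=1, seed=6))
        write_session(neurons, tmp_path, spikes_format="jsonl")
        back = read_session(tmp_path)
        assert sum(len(n.trials) for n in back) == len(neurons[0].trials)

    def test_unknown_outcome_label_is_a_parse_error(self, tmp_path):
        neurons, _ = simulate_population(SimulationSpec(n_neurons=1, seed=7))
        write_session(neurons, tmp_path)
        trials = (tmp_path / "trials.tsv").read_text().replace("hit", "miss")
        (tmp_path / "trials.tsv").write_text(trials)
        with pytest.raises(SessionFormatError, match="miss"):
            read_session(tmp_path)

    def test_event_order_violation_is_an_error(self, tmp_path):
        neurons, _ = simulate_population(SimulationSpec(n_neurons=1, seed=8))
        write_session(neurons, tmp_path)
        import pandas as pd
        df = pd.read_csv(tmp_path / "trials.tsv", sep="\t")
        df.loc[0, "pb"] = df.loc[0, "pu"] - 1.0  # pb < pu
        df.to_csv(tmp_path / "trials.tsv", sep="\t", index=False)
        with pytest.raises(SessionFormatError):
            read_session(tmp_path)
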