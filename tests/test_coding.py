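"""AUROC, permutation significance, binary words, profiles, choice probability."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecode.coding import (CodingWordSeries, PAIR_ORDER, UNASSIGNED, auroc,
                              choice_probability, classify_profiles,
                              digit_series, enumerate_label_words,
                              permutation_test_auroc,
                              population_coding_fraction, stability_filter)

from conftest import flat_neuron


class TestAuroc:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3], [1, 2, 3], 0.5),      # identical samples
        ([1, 2], [3, 4], 1.0),            # disjoint
        ([3, 4], [1, 2], 0.0),
        ([1, 3], [2, 4], 0.75),           # 3 wins of 4 ordered pairs
    ])
    def test_worked_examples(self, x, y, expected):
        assert auroc(x, y) == pytest.approx(expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            auroc([], [1.0])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.lists(st.floats(-50, 50), min_size=1, max_size=12))
    def test_antisymmetry(self, x, y):
        assert auroc(x, y) + auroc(y, x) == pytest.approx(1.0)

    def test_matches_exhaustive_pair_count(self, rng):
        x = rng.integers(0, 6, 9).astype(float)
        y = rng.integers(0, 6, 7).astype(float)
        wins = sum((yi > xi) + 0.5 * (yi == xi) for xi in x for yi in y)
        assert auroc(x, y) == pytest.approx(wins / (9 * 7))


class TestPermutationTest:
    def test_disjoint_samples_significant(self):
        res = permutation_test_auroc(np.arange(5.), np.arange(10., 15.), seed=0)
        assert res.significant and res.auroc == 1.0

    def test_degenerate_equal_data_not_significant(self):
        res = permutation_test_auroc(np.ones(6), np.ones(6), seed=0)
        assert res.p_value == 1.0 and not res.significant

    def test_seed_fixes_p_value(self):
        x, y = np.arange(8.), np.arange(8.) + 0.5
        p1 = permutation_test_auroc(x, y, seed=9).p_value
        p2 = permutation_test_auroc(x, y, seed=9).p_value
        assert p1 == p2

    def test_type_one_error_near_alpha(self, rng):
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            x, y = rng.normal(size=8), rng.normal(size=8)
            hits += permutation_test_auroc(x, y, n_perm=200, seed=rng).significant
        rate = hits / n_rep
        # binomial 99% envelope around alpha = 0.05
        assert rate < 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / n_rep)


class TestStabilityRule:
    @pytest.mark.parametrize("raw, expected", [
        ([1, 1, 1, 1, 0], [1, 1, 1, 1, UNASSIGNED]),
        ([1, 1, 1, 0, 1, 1, 1], [UNASSIGNED] * 7),
        ([0] * 6, [0] * 6),
        ([1, 1], [UNASSIGNED] * 2),
    ])
    def test_run_length_rule(self, raw, expected):
        assert list(stability_filter(np.array(raw))) == expected


class TestWordLibrary:
    def test_exactly_7_of_64_words_are_labeled(self):
        words = enumerate_label_words()
        assert len(words) == 64
        labeled = [w for w, p in words.items() if p != "noncoding"]
        assert len(labeled) == 7

    def test_specific_words(self):
        words = enumerate_label_words()
        assert words[(0, 1, 1, 1, 1, 0)] == "P1"
        assert words[(1, 0, 1, 1, 0, 1)] == "P2"
        assert words[(1, 1, 0, 0, 1, 1)] == "decision"
        assert words[(1, 1, 1, 0, 0, 0)] == "class_c1"
        assert words[(1, 1, 1, 1, 1, 1)] == "noncoding"

    def test_agrees_with_independent_rule_rederivation(self):
        # oracle: rebuild each profile word from the textual rules using set
        # partitions, independently of the implementation's construction
        classes = ("c1", "c2", "c3", "c4")
        pairs = list(combinations(classes, 2))

        def word_from_equal_sets(groups):
            in_same = {}
            for g in groups:
                for a in g:
                    in_same[a] = g
            return tuple(0 if b in in_same.get(a, ()) else 1 for a, b in pairs)

        oracle = {
            word_from_equal_sets([("c1", "c2"), ("c3", "c4")]): "P1",
            word_from_equal_sets([("c1", "c3"), ("c2", "c4")]): "P2",
            word_from_equal_sets([("c1", "c4"), ("c2", "c3")]): "decision",
        }
        for k in classes:
            rest = tuple(c for c in classes if c != k)
            oracle[word_from_equal_sets([rest])] = f"class_{k}"
        assert len(oracle) == 7  # all seven words pairwise distinct
        words = enumerate_label_words()
        for w, profile in oracle.items():
            assert words[w] == profile
        for w, profile in words.items():
            if profile != "noncoding":
                assert oracle[w] == profile


class TestProfiles:
    def test_constant_p1_word_codes_p1_throughout(self):
        digits = np.tile([0, 1, 1, 1, 1, 0], (10, 1))
        series = CodingWordSeries(np.arange(10.), digits)
        res = classify_profiles(series)
        assert res["coding"]["P1"].all()
        assert res["coder_flags"]["P1"]

    def test_alternating_profiles_never_code(self):
        p1, p2 = [0, 1, 1, 1, 1, 0], [1, 0, 1, 1, 0, 1]
        digits = np.array([p1 if i % 2 == 0 else p2 for i in range(10)])
        res = classify_profiles(CodingWordSeries(np.arange(10.), digits))
        assert not any(res["coder_flags"].values())

    def test_all_different_word_is_noncoding(self):
        digits = np.tile([1, 1, 1, 1, 1, 1], (6, 1))
        res = classify_profiles(CodingWordSeries(np.arange(6.), digits))
        assert res["labels"] == ["noncoding"] * 6


class TestDigitSeries:
    def test_separated_classes_produce_assigned_digits(self, rng):
        # c1 far from the rest over all bins -> stable class_c1 word
        n_bins, n_trials = 8, 10
        class_rates = {
            "c1": rng.normal(50, 1, (n_trials, n_bins)),
            "c2": rng.normal(10, 1, (n_trials, n_bins)),
            "c3": rng.normal(10, 1, (n_trials, n_bins)),
            "c4": rng.normal(10, 1, (n_trials, n_bins)),
        }
        series = digit_series(class_rates, n_perm=200, seed=0)
        assert series.labels.count("class_c1") >= 6

    def test_too_few_bins_leave_all_unassigned(self, rng):
        class_rates = {c: rng.normal(10, 1, (6, 3)) for c in
                       ("c1", "c2", "c3", "c4")}
        series = digit_series(class_rates, n_perm=200, seed=0)
        assert np.all(series.digits == UNASSIGNED)

    def test_under_two_trials_per_class_unassigned(self, rng):
        class_rates = {c: rng.normal(10, 1, (6, 8)) for c in
                       ("c1", "c2", "c3", "c4")}
        class_rates["c2"] = class_rates["c2"][:1]
        series = digit_series(class_rates, n_perm=200, seed=0)
        c2_pairs = [j for j, p in enumerate(PAIR_ORDER) if "c2" in p]
        assert np.all(series.digits[:, c2_pairs] == UNASSIGNED)


class TestPopulationFraction:
    def test_zero_neurons_rejected(self):
        with pytest.raises(ValueError):
            population_coding_fraction([], "P1")

    def test_fraction_counts_coders(self):
        digits_p1 = np.tile([0, 1, 1, 1, 1, 0], (6, 1))
        digits_non = np.tile([1, 1, 1, 1, 1, 1], (6, 1))
        res = [classify_profiles(CodingWordSeries(np.arange(6.), d))
               for d in (digits_p1, digits_p1, digits_non, digits_non)]
        frac = population_coding_fraction(res, "P1")
        assert np.allclose(frac, 50.0)


class TestChoiceProbability:
    def test_identical_hit_error_distributions_overlap_fully(self):
        nr = flat_neuron(seed=3, with_errors=True)
        _, cp, excluded = choice_probability(nr)
        assert not excluded
        assert abs(np.nanmean(cp) - 0.5) < 0.05

    def test_no_error_trials_excludes_all_classes(self):
        nr = flat_neuron(seed=4, with_errors=False)
        _, cp, excluded = choice_probability(nr)
        assert set(excluded) == {"c1", "c2", "c3", "c4"}
        assert np.all(np.isnan(cp))

    def test_decision_archetype_deviates_during_comparison(self):
        from spikecode.simulate import (SimulationSpec, default_archetype,
                                        simulate_neuron)
        rng = np.random.default_rng(21)
        nr = simulate_neuron(default_archetype("decision"),
                             SimulationSpec(seed=21), "dec0", rng)
        centers, cp, _ = choice_probability(nr)
        comparison = (centers >= 3.3) & (centers < 6.0)
        assert np.nanmax(np.abs(cp[comparison] - 0.5)) > 0.15
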