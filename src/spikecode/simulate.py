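"""Task-structured spike-train simulator with known ground truth.

The generator emulates a two-interval temporal-pattern discrimination
session: four classes built from grouped (G) and extended (E) 1-s pulse
patterns, a light-cued control task (LCT) with the same stimuli, hit/error
outcomes at a target performance, and neuron archetypes spanning
phase-locked sensory responses, categorical pattern/class/decision
responses, mixtures of the two, non-coding cells, and cells whose baseline
fluctuates with a controlled intrinsic timescale.

The simulator is an engineered test harness: it realises the response
taxonomy the analyses are meant to recover, not a biophysical model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (CLASS_DECISION, CLASS_P1, CLASS_P2, CLASSES, NeuronRecord,
                   StimulusPattern, TrialRecord)

#: inter-pulse frequency of the extended pattern (Hz)
PATTERN_FREQ_HZ = 4.34
E_PERIOD_MS = 1000.0 / PATTERN_FREQ_HZ  # ~230.4 ms


def make_pattern(kind: str, group_spacing_ms: float = E_PERIOD_MS / 2.0,
                 pulse_duration_ms: float = 20.0) -> StimulusPattern:
    """Build the grouped (G) or extended (E) five-pulse stimulus.

    E: onsets equally spaced at 1000/4.34 ~ 230.4 ms starting at 0.
    G: shares E's first and last (boundary) onsets; the middle three are
    center-grouped symmetrically about the stimulus midpoint with
    ``group_spacing_ms`` between them (default half the E period).
    """
    e_onsets = np.arange(5) * E_PERIOD_MS
    if kind == "E":
        onsets = e_onsets
    elif kind == "G":
        mid = e_onsets[2]  # 460.8 ms, midpoint of boundary pulses
        onsets = np.array([e_onsets[0], mid - group_spacing_ms, mid,
                           mid + group_spacing_ms, e_onsets[4]])
    else:
        raise ValueError(f"pattern kind must be 'G' or 'E', got {kind!r}")
    return StimulusPattern(kind=kind, pulse_onsets=tuple(onsets),
                           pulse_duration_ms=pulse_duration_ms)


@dataclass(frozen=True)
class NeuronArchetype:
    """Generative parameters of one simulated neuron.

    ``mix_weight`` blends the phase-locked sensory drive (1.0) with the
    categorical drive (0.0).  ``preferred`` names the pattern (G/E), class
    (c1..c4) or decision (match/nonmatch) the categorical term favours.
    ``error_fidelity`` scales the categorical/decision term on error trials
    (0 = the categorical signal is absent when the subject errs).
    """

    kind: str = "sensory"
    baseline_rate: float = 10.0
    pulse_gain: float = 120.0
    categorical_gain: float = 15.0
    preferred: str = "E"
    mix_weight: float = 1.0
    tau_ms: float = 150.0
    baseline_cv: float = 0.3
    error_fidelity: float = 0.0
    categorical_latency_s: float = 0.15

    KINDS = ("sensory", "categorical", "intermediate", "decision",
             "noncoding", "timescale_probe")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")
        if self.baseline_rate <= 0 and self.pulse_gain == 0 \
                and self.categorical_gain == 0:
            warnings.warn("degenerate rate: nonpositive baseline, zero gains")


def default_archetype(kind: str, rng: np.random.Generator | None = None) -> NeuronArchetype:
    """The study-condition parameterisation of each archetype kind."""
    presets = {
        "sensory": dict(mix_weight=1.0, pulse_gain=120.0, categorical_gain=0.0),
        "categorical": dict(mix_weight=0.0, pulse_gain=0.0, categorical_gain=15.0),
        "intermediate": dict(mix_weight=0.5, pulse_gain=60.0, categorical_gain=8.0),
        "decision": dict(mix_weight=0.0, pulse_gain=0.0, categorical_gain=15.0,
                         preferred="match"),
        "noncoding": dict(mix_weight=1.0, pulse_gain=0.0, categorical_gain=0.0),
        "timescale_probe": dict(mix_weight=1.0, pulse_gain=0.0,
                                categorical_gain=0.0, baseline_rate=20.0,
                                baseline_cv=0.5),
    }
    return NeuronArchetype(kind=kind, **presets[kind])


@dataclass
class SimulationSpec:
    """Session-level simulation parameters (the study conditions)."""

    n_neurons: int = 20
    proportions: dict[str, float] = field(default_factory=lambda: {
        "sensory": 0.25, "categorical": 0.25, "intermediate": 0.2,
        "decision": 0.1, "noncoding": 0.1, "timescale_probe": 0.1})
    trials_per_class: int = 15          # target hit trials per class
    performance_target: float = 0.84    # TPDT hit probability
    lct_fraction: float = 0.0           # fraction of neurons also run in LCT
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("archetype proportions must sum to 1")
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")


def _ou_path(n_steps: int, dt: float, tau_s: float,
             rng: np.random.Generator, n_paths: int = 1) -> np.ndarray:
    """Stationary unit-variance Ornstein-Uhlenbeck sample paths (n_paths, n_steps)."""
    a = np.exp(-dt / tau_s)
    noise_sd = np.sqrt(1.0 - a * a)
    x = np.empty((n_paths, n_steps))
    x[:, 0] = rng.standard_normal(n_paths)
    eps = rng.standard_normal((n_paths, n_steps - 1)) * noise_sd
    for i in range(1, n_steps):
        x[:, i] = x[:, i - 1] * a + eps[:, i - 1]
    return x


def _categorical_active(arch: NeuronArchetype, class_label: str, task: str,
                        outcome: str, reported: str) -> tuple[float, float, float]:
    """(gain multiplier, t_on, t_off) of the categorical/decision rate term."""
    if task == "LCT":
        return 0.0, 0.0, 0.0   # cognitive terms silenced in the guided task
    fidelity = 1.0 if outcome == "hit" else arch.error_fidelity
    lat = arch.categorical_latency_s
    if arch.kind == "decision" or arch.preferred in ("match", "nonmatch"):
        # decision cells follow the *reported* choice during/after comparison
        on = 1.0 if reported == arch.preferred else 0.0
        return on * fidelity, 3.0 + lat, 7.0
    if arch.preferred in CLASSES:
        on = 1.0 if class_label == arch.preferred else 0.0
        return on * fidelity, 3.0 + lat, 6.0
    # pattern-preferring (P1 identity) categorical term: active from P1
    # through the working-memory delay
    on = 1.0 if CLASS_P1[class_label] == arch.preferred else 0.0
    return on * fidelity, lat, 3.0


def trial_rate_profile(arch: NeuronArchetype, class_label: str, task: str,
                       outcome: str, t: np.ndarray,
                       patterns: dict[str, StimulusPattern] | None = None) -> np.ndarray:
    """Deterministic part of the trial rate (sp/s) on time grid ``t`` (s).

    rate(t) = baseline + mix * pulse drive + (1 - mix) * categorical term;
    the stochastic OU baseline modulation is added by :func:`simulate_trial`.
    """
    if patterns is None:
        patterns = {"G": make_pattern("G"), "E": make_pattern("E")}
    rate = np.full_like(t, arch.baseline_rate, dtype=float)
    # phase-locked sensory drive: 20-ms boxcar per pulse, both periods,
    # identical across task and outcome by construction
    if arch.mix_weight > 0 and arch.pulse_gain > 0:
        for onset_s, pat_key in ((0.0, CLASS_P1[class_label]),
                                 (3.0, CLASS_P2[class_label])):
            pat = patterns[pat_key]
            for po in pat.pulse_onsets:
                t0 = onset_s + po / 1000.0
                rate += np.where((t >= t0) & (t < t0 + pat.pulse_duration_ms / 1000.0),
                                 arch.mix_weight * arch.pulse_gain, 0.0)
    reported = CLASS_DECISION[class_label] if outcome == "hit" else (
        "match" if CLASS_DECISION[class_label] == "nonmatch" else "nonmatch")
    gain_mult, t_on, t_off = _categorical_active(arch, class_label, task,
                                                 outcome, reported)
    if arch.mix_weight < 1 and gain_mult > 0:
        rate += np.where((t >= t_on) & (t < t_off),
                         (1 - arch.mix_weight) * arch.categorical_gain * gain_mult,
                         0.0)
    return rate


def simulate_trial(arch: NeuronArchetype, class_label: str, task: str = "TPDT",
                   outcome: str = "hit", seed: int | np.random.Generator = 0,
                   trial_id: str = "t0", dt: float = 0.001) -> TrialRecord:
    """Inhomogeneous-Poisson spike train for one trial.

    Spikes are drawn at resolution ``dt`` from the rectified sum of the
    OU-modulated baseline and the archetype's deterministic rate profile.
    """
    if task == "LCT" and outcome != "hit":
        raise ValueError("LCT trials are always hits")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pd_time = -3.0 + rng.uniform(-0.5, 0.5)
    pu = 6.0
    ku = pu + rng.uniform(0.2, 0.4)
    pb = ku + rng.uniform(0.3, 0.5)
    events = {"pd": pd_time, "p1_on": 0.0, "p1_off": 1.0, "p2_on": 3.0,
              "p2_off": 4.0, "pu": pu, "ku": ku, "pb": pb}
    t = np.arange(pd_time, pb + 1.5 - dt, dt)
    rate = trial_rate_profile(arch, class_label, task, outcome, t)
    if arch.baseline_cv > 0 and arch.baseline_rate > 0:
        ou = _ou_path(t.size, dt, arch.tau_ms / 1000.0, rng)[0]
        rate = rate + arch.baseline_cv * arch.baseline_rate * ou
    rate = np.clip(rate, 0.0, None)
    counts = rng.poisson(rate * dt)
    idx = np.repeat(np.arange(t.size), counts)
    spikes = np.sort(t[idx] + rng.uniform(0, dt, idx.size))
    return TrialRecord(trial_id=trial_id, class_label=class_label, task=task,
                       outcome=outcome, event_times=events, spike_times=spikes)


def simulate_neuron(arch: NeuronArchetype, spec: SimulationSpec,
                    neuron_id: str, rng: np.random.Generator,
                    include_lct: bool = False) -> NeuronRecord:
    """All trials of one neuron (interleaved classes, outcome at target rate)."""
    trials = []
    n_total = int(round(spec.trials_per_class / spec.performance_target))
    k = 0
    for c in CLASSES:
        for _ in range(n_total):
            outcome = "hit" if rng.random() < spec.performance_target else "error"
            trials.append(simulate_trial(arch, c, "TPDT", outcome, rng,
                                         trial_id=f"T{k:04d}"))
            k += 1
    if include_lct:
        for c in CLASSES:
            for _ in range(spec.trials_per_class):
                trials.append(simulate_trial(arch, c, "LCT", "hit", rng,
                                             trial_id=f"T{k:04d}"))
                k += 1
    return NeuronRecord(neuron_id=neuron_id, trials=trials)


def simulate_population(spec: SimulationSpec) -> tuple[list[NeuronRecord], pd.DataFrame]:
    """Simulate a session; returns neurons plus a ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    kinds = list(spec.proportions)
    counts = np.floor(np.array([spec.proportions[k] for k in kinds])
                      * spec.n_neurons).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = np.array([spec.proportions[k] for k in kinds]) * spec.n_neurons - counts
    for i in np.argsort(-frac)[: spec.n_neurons - counts.sum()]:
        counts[i] += 1
    neurons, truth = [], []
    n_lct = int(round(spec.lct_fraction * spec.n_neurons))
    idx = 0
    for kind, n_k in zip(kinds, counts):
        for _ in range(n_k):
            arch = default_archetype(kind)
            nid = f"sim{idx:04d}"
            include_lct = idx < n_lct
            neurons.append(simulate_neuron(arch, spec, nid, rng, include_lct))
            truth.append({"neuron_id": nid, "archetype": kind,
                          "mix_weight": arch.mix_weight, "tau_ms": arch.tau_ms,
                          "preferred": arch.preferred, "has_lct": include_lct})
            idx += 1
    return neurons, pd.DataFrame(truth)


def simulate_timescale_counts(tau_ms: float, n_trials: int, bin_ms: float = 40.0,
                              step_ms: float = 20.0, duration_s: float = 1.0,
                              rate_hz: float = 20.0, modulation_cv: float = 0.5,
                              seed: int | np.random.Generator = 0,
                              dt: float = 0.002) -> tuple[np.ndarray, np.ndarray]:
    """OU-modulated Poisson spike counts in overlapping bins.

    Returns (bin_start_times_ms, counts (n_trials, n_bins)).  The across-trial
    lag correlation of the counts decays approximately as exp(-lag/tau_ms).
    """
    if tau_ms <= 0:
        raise ValueError("tau_ms must be positive")
    if tau_ms <= bin_ms / 10:
        warnings.warn("tau_ms below bin/10 is unresolvable at this binning")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(duration_s / dt))
    ou = _ou_path(n_steps, dt, tau_ms / 1000.0, rng, n_paths=n_trials)
    rate = np.clip(rate_hz * (1.0 + modulation_cv * ou), 0.0, None)
    spikes = rng.poisson(rate * dt)           # (n_trials, n_steps)
    csum = np.concatenate([np.zeros((n_trials, 1), int),
                           np.cumsum(spikes, axis=1)], axis=1)
    starts_ms = np.arange(0.0, duration_s * 1000.0 - bin_ms + 1e-9, step_ms)
    i0 = np.round(starts_ms / 1000.0 / dt).astype(int)
    i1 = np.round((starts_ms + bin_ms) / 1000.0 / dt).astype(int)
    counts = csum[:, i1] - csum[:, i0]
    return starts_ms, counts
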