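"""Trial-aligned spike-train containers, firing-rate estimation and session I/O.

The data model follows a two-interval temporal-pattern discrimination task:
each trial presents two 1-s vibrotactile pulse patterns (P1 at 0-1 s, P2 at
3-4 s, times relative to P1 onset), separated by a 2-s delay, with a 2-s
post-P2 delay before the probe-up (pu), key-up (ku) and push-button (pb)
events.  The four trial classes c1..c4 are the ordered pattern pairs
G-G, G-E, E-G, E-E (G = grouped, E = extended).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

CLASSES = ("c1", "c2", "c3", "c4")
TASKS = ("TPDT", "LCT")
OUTCOMES = ("hit", "error")
EVENT_NAMES = ("pd", "p1_on", "p1_off", "p2_on", "p2_off", "pu", "ku", "pb")

#: P1 pattern per class (c1=G-G, c2=G-E, c3=E-G, c4=E-E)
CLASS_P1 = {"c1": "G", "c2": "G", "c3": "E", "c4": "E"}
CLASS_P2 = {"c1": "G", "c2": "E", "c3": "G", "c4": "E"}
#: correct decision per class: match (P1 == P2) or nonmatch
CLASS_DECISION = {"c1": "match", "c2": "nonmatch", "c3": "nonmatch", "c4": "match"}

SPIKE_TIME_DECIMALS = 4  # 0.1 ms precision in files


class SessionFormatError(ValueError):
    """Raised when a session file violates the on-disk contract."""


@dataclass(frozen=True)
class StimulusPattern:
    """A 1-s pulse pattern: five 20-ms single-cycle pulses.

    ``pulse_onsets`` are in ms relative to stimulus onset.  The extended (E)
    pattern is periodic at 4.34 Hz between pulses; the grouped (G) pattern
    shares E's boundary pulses and center-groups the other three.
    """

    kind: Literal["G", "E"]
    pulse_onsets: tuple[float, ...]
    pulse_duration_ms: float = 20.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.pulse_onsets, dtype=float)
        if onsets.size != 5:
            raise ValueError(f"expected exactly 5 pulses, got {onsets.size}")
        if np.any(onsets < 0) or np.any(onsets >= 1000):
            raise ValueError("pulse onsets must lie in [0, 1000) ms")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if np.any(np.diff(onsets) < self.pulse_duration_ms):
            raise ValueError("pulse spacing overlaps the pulse duration")


@dataclass(frozen=True)
class TrialRecord:
    """One trial: metadata, event times (s, P1 onset = 0) and sorted spikes."""

    trial_id: str
    class_label: str
    task: str
    outcome: str
    event_times: dict[str, float]
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.task == "LCT" and self.outcome != "hit":
            raise ValueError("LCT trials are always hits")
        ev = self.event_times
        missing = [k for k in EVENT_NAMES if k not in ev]
        if missing:
            raise ValueError(f"missing event times: {missing}")
        if ev["p1_on"] != 0.0:
            raise ValueError("p1_on must be the 0 reference")
        order = [ev[k] for k in EVENT_NAMES]
        # pd < p1_on < p1_off < p2_on < p2_off < pu <= ku <= pb
        if not (order[0] < order[1] < order[2] < order[3] < order[4] < order[5]
                and order[5] <= order[6] <= order[7]):
            raise ValueError(f"event times out of order: {ev}")
        if ev["pu"] < 6.0:
            raise ValueError("pu must be >= 6 s")
        spikes = np.asarray(self.spike_times, dtype=float)
        if spikes.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if spikes.size and np.any(np.diff(spikes) < 0):
            raise ValueError("spike_times must be sorted")
        lo, hi = ev["pd"], ev["pb"] + 1.5
        if spikes.size and (spikes[0] < lo - 1e-9 or spikes[-1] > hi + 1e-9):
            raise ValueError("spike times outside [pd, pb + 1.5 s]")
        object.__setattr__(self, "spike_times", spikes)

    @property
    def p1_pattern(self) -> str:
        return CLASS_P1[self.class_label]

    @property
    def p2_pattern(self) -> str:
        return CLASS_P2[self.class_label]

    @property
    def decision_correct(self) -> str:
        """The correct match/nonmatch answer for this trial's class."""
        return CLASS_DECISION[self.class_label]

    @property
    def decision_reported(self) -> str:
        """The answer the subject actually reported (flipped on errors)."""
        correct = self.decision_correct
        if self.outcome == "hit":
            return correct
        return "match" if correct == "nonmatch" else "nonmatch"


@dataclass
class NeuronRecord:
    """All trials of one neuron plus identity metadata."""

    neuron_id: str
    trials: list[TrialRecord]
    area: str = "synthetic"
    monkey_id: str = "sim"
    session_id: str = "sim"

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("a NeuronRecord needs at least one trial")

    def select(self, *, task: str | None = None, outcome: str | None = None,
               class_label: str | None = None) -> list[TrialRecord]:
        out = self.trials
        if task is not None:
            out = [t for t in out if t.task == task]
        if outcome is not None:
            out = [t for t in out if t.outcome == outcome]
        if class_label is not None:
            out = [t for t in out if t.class_label == class_label]
        return out


@dataclass
class RateSeries:
    """A windowed firing-rate (or z-score) time series with provenance."""

    bin_centers: np.ndarray
    values: np.ndarray
    window_ms: float
    step_ms: float
    kernel: str = "square"
    is_zscored: bool = False

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("bin_centers and values must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rate values must be finite")
        if not self.is_zscored and np.any(self.values < -1e-12):
            raise ValueError("firing rates must be non-negative")


@dataclass
class PopulationTensor:
    """Per-neuron, per-class mean rates on a shared time grid.

    ``class_rates`` has shape (n_neurons, n_bins, 4) ordered c1..c4;
    ``grand_mean`` (n_neurons, n_bins) is the unweighted mean over classes.
    """

    neuron_ids: list[str]
    bin_centers: np.ndarray
    class_rates: np.ndarray
    window_ms: float = 200.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        self.class_rates = np.asarray(self.class_rates, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        n, t, c = self.class_rates.shape
        if c != 4 or n != len(self.neuron_ids) or t != self.bin_centers.size:
            raise ValueError("class_rates shape must be (n_neurons, n_bins, 4)")

    @property
    def grand_mean(self) -> np.ndarray:
        return self.class_rates.mean(axis=2)


def time_grid(t_start: float, t_end: float, step_ms: float) -> np.ndarray:
    """Bin centers on the half-open grid [t_start, t_end) at step_ms.

    The default analysis grid (-1 to 7.5 s, 50-ms steps) yields 170 bins.
    """
    step = step_ms / 1000.0
    n = int(np.floor((t_end - t_start) / step + 1e-9))
    return t_start + step * np.arange(n)


def _epanechnikov(u: np.ndarray, half_width: float) -> np.ndarray:
    out = 0.75 / half_width * (1.0 - (u / half_width) ** 2)
    return np.where(np.abs(u) <= half_width, out, 0.0)


def estimate_rate(trial: TrialRecord | np.ndarray, window_ms: float,
                  step_ms: float, kernel: str = "square",
                  t_start: float = -1.0, t_end: float = 7.5) -> RateSeries:
    """Windowed firing-rate estimate of one trial's spike train.

    Square kernel: spike count in the half-open window [t - w/2, t + w/2)
    divided by w.  Quadratic kernel: Epanechnikov window of total width
    ``window_ms`` with unit mass (used by the spectral pathway).
    """
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window_ms and step_ms must be positive")
    if t_start >= t_end:
        raise ValueError("empty time range")
    spikes = trial.spike_times if isinstance(trial, TrialRecord) else np.asarray(trial, float)
    centers = time_grid(t_start, t_end, step_ms)
    w = window_ms / 1000.0
    if kernel == "square":
        # vectorized half-open counts via searchsorted
        lo = np.searchsorted(spikes, centers - w / 2, side="left")
        hi = np.searchsorted(spikes, centers + w / 2, side="left")
        values = (hi - lo) / w
    elif kernel == "quadratic":
        if spikes.size:
            diffs = centers[:, None] - spikes[None, :]
            values = _epanechnikov(diffs, w / 2).sum(axis=1)
        else:
            values = np.zeros_like(centers)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return RateSeries(centers, values, window_ms, step_ms, kernel=kernel)


def trial_rate_matrix(trials: Sequence[TrialRecord], window_ms: float = 200.0,
                      step_ms: float = 50.0, t_start: float = -1.0,
                      t_end: float = 7.5) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-trial square-kernel rates into (n_trials, n_bins)."""
    centers = time_grid(t_start, t_end, step_ms)
    rates = np.empty((len(trials), centers.size))
    for i, tr in enumerate(trials):
        rates[i] = estimate_rate(tr, window_ms, step_ms, "square", t_start, t_end).values
    return centers, rates


def class_psth(neuron: NeuronRecord, hits_only: bool = True,
               window_ms: float = 200.0, step_ms: float = 50.0,
               t_start: float = -1.0, t_end: float = 7.5,
               task: str = "TPDT") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class mean rate r(t, c) and unweighted grand mean r(t).

    Returns (bin_centers, class_rates (n_bins, 4), grand_mean (n_bins,)).
    """
    centers = time_grid(t_start, t_end, step_ms)
    class_rates = np.empty((centers.size, 4))
    for j, c in enumerate(CLASSES):
        trials = neuron.select(task=task, class_label=c,
                               outcome="hit" if hits_only else None)
        if not trials:
            raise ValueError(f"neuron {neuron.neuron_id}: no "
                             f"{'hit ' if hits_only else ''}trials in class {c}")
        _, rates = trial_rate_matrix(trials, window_ms, step_ms, t_start, t_end)
        class_rates[:, j] = rates.mean(axis=0)
    return centers, class_rates, class_rates.mean(axis=1)


def population_tensor(neurons: Sequence[NeuronRecord], hits_only: bool = True,
                      window_ms: float = 200.0, step_ms: float = 50.0,
                      t_start: float = -1.0, t_end: float = 7.5,
                      task: str = "TPDT") -> PopulationTensor:
    """Pseudo-population of class PSTHs on a shared grid."""
    ids, mats = [], []
    centers = time_grid(t_start, t_end, step_ms)
    for nr in neurons:
        _, cr, _ = class_psth(nr, hits_only, window_ms, step_ms, t_start, t_end, task)
        ids.append(nr.neuron_id)
        mats.append(cr)
    return PopulationTensor(ids, centers, np.stack(mats), window_ms, step_ms)


# ---------------------------------------------------------------------------
# z-scoring


class ZeroVarianceNeuron(ValueError):
    """Neuron whose hit-trial rates have zero variance; cannot be z-scored."""


def zscore_reference(neuron: NeuronRecord, window_ms: float = 200.0,
                     step_ms: float = 50.0, t_start: float = -1.0,
                     t_end: float = 7.5, task: str = "TPDT") -> tuple[float, float]:
    """Scalar (mean, SD) of a neuron's hit-trial rates pooled over all bins."""
    hits = neuron.select(task=task, outcome="hit")
    if not hits:
        raise ValueError(f"neuron {neuron.neuron_id}: no hit trials")
    _, rates = trial_rate_matrix(hits, window_ms, step_ms, t_start, t_end)
    mean = float(rates.mean())
    sd = float(rates.std(ddof=0))
    if sd <= 0:
        raise ZeroVarianceNeuron(
            f"neuron {neuron.neuron_id} has zero rate SD over hit trials")
    return mean, sd


def zscore_rates(neuron: NeuronRecord, trials: Sequence[TrialRecord] | None = None,
                 window_ms: float = 200.0, step_ms: float = 50.0,
                 t_start: float = -1.0, t_end: float = 7.5,
                 task: str = "TPDT") -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-trial z-scored rates using the neuron's hit-trial reference.

    Returns (bin_centers, z (n_trials, n_bins), mean, sd).  The reference is
    one scalar mean and SD per neuron, pooled over all hit trials and all
    bins of the analysis interval.
    """
    mean, sd = zscore_reference(neuron, window_ms, step_ms, t_start, t_end, task)
    if trials is None:
        trials = neuron.select(task=task)
    centers, rates = trial_rate_matrix(trials, window_ms, step_ms, t_start, t_end)
    return centers, (rates - mean) / sd, mean, sd


def backtransform(z_values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Invert the z-score transform: rate = z * sd + mean.

    For population-mean traces, pass the population-average mean and SD.
    """
    return np.asarray(z_values, float) * sd + mean


# ---------------------------------------------------------------------------
# Session I/O (TSV trials + TSV or JSON-lines spikes)


def write_session(neurons: Sequence[NeuronRecord], path: str | Path,
                  spikes_format: str = "tsv") -> None:
    """Write a session directory: trials.tsv + spikes.tsv (or spikes.jsonl)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trial_rows = []
    for nr in neurons:
        for tr in nr.trials:
            row = {"neuron_id": nr.neuron_id, "trial_id": tr.trial_id,
                   "class": tr.class_label, "task": tr.task, "outcome": tr.outcome}
            row.update({k: tr.event_times[k] for k in EVENT_NAMES})
            trial_rows.append(row)
    pd.DataFrame(trial_rows).to_csv(path / "trials.tsv", sep="\t", index=False)
    if spikes_format == "tsv":
        with open(path / "spikes.tsv", "w") as fh:
            fh.write("neuron_id\ttrial_id\tspike_time_s\n")
            for nr in neurons:
                for tr in nr.trials:
                    for s in np.round(tr.spike_times, SPIKE_TIME_DECIMALS):
                        fh.write(f"{nr.neuron_id}\t{tr.trial_id}\t{s:.4f}\n")
    elif spikes_format == "jsonl":
        with open(path / "spikes.jsonl", "w") as fh:
            for nr in neurons:
                for tr in nr.trials:
                    rec = {"neuron_id": nr.neuron_id, "trial_id": tr.trial_id,
                           "spike_times_s":
                               [round(float(s), SPIKE_TIME_DECIMALS)
                                for s in tr.spike_times]}
                    fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown spikes format {spikes_format!r}")


def _read_spikes(path: Path) -> dict[tuple[str, str], list[float]]:
    spikes: dict[tuple[str, str], list[float]] = {}
    tsv, jsonl = path / "spikes.tsv", path / "spikes.jsonl"
    if tsv.exists():
        df = pd.read_csv(tsv, sep="\t", dtype={"neuron_id": str, "trial_id": str})
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                t = float(row.spike_time_s)
            except (TypeError, ValueError):
                raise SessionFormatError(f"{tsv}:{i}: bad spike time "
                                         f"{row.spike_time_s!r}") from None
            spikes.setdefault((row.neuron_id, row.trial_id), []).append(t)
    elif jsonl.exists():
        with open(jsonl) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    key = (str(rec["neuron_id"]), str(rec["trial_id"]))
                    spikes[key] = [float(s) for s in rec["spike_times_s"]]
                except (KeyError, ValueError, TypeError) as exc:
                    raise SessionFormatError(f"{jsonl}:{i}: {exc}") from None
    else:
        raise SessionFormatError(f"no spikes.tsv or spikes.jsonl in {path}")
    return spikes


def read_session(path: str | Path) -> list[NeuronRecord]:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    trials_path = path / "trials.tsv"
    if not trials_path.exists():
        raise SessionFormatError(f"missing {trials_path}")
    df = pd.read_csv(trials_path, sep="\t", dtype={"neuron_id": str, "trial_id": str})
    spikes = _read_spikes(path)
    neurons: dict[str, list[TrialRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        times = sorted(spikes.get((row.neuron_id, row.trial_id), []))
        if row._2 not in CLASSES:  # "class" is positional (reserved word)
            raise SessionFormatError(f"{trials_path}:{i}: unknown class {row._2!r}")
        if row.task not in TASKS:
            raise SessionFormatError(f"{trials_path}:{i}: unknown task {row.task!r}")
        if row.outcome not in OUTCOMES:
            raise SessionFormatError(f"{trials_path}:{i}: unknown outcome "
                                     f"{row.outcome!r}")
        try:
            tr = TrialRecord(
                trial_id=row.trial_id, class_label=row._2, task=row.task,
                outcome=row.outcome,
                event_times={k: float(getattr(row, k)) for k in EVENT_NAMES},
                spike_times=np.asarray(times))
        except ValueError as exc:
            raise SessionFormatError(f"{trials_path}:{i}: {exc}") from None
        neurons.setdefault(row.neuron_id, []).append(tr)
    return [NeuronRecord(neuron_id=nid, trials=trs) for nid, trs in neurons.items()]
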