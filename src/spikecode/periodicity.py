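"""Spike-train power spectra and periodicity information.

The extended (E) pattern is periodic at pf = 4.34 Hz between pulses while
the grouped (G) pattern is aperiodic, so a phase-locked neuron carries
pattern identity in the spectral power of its spike train near pf.  Each
trial's stimulus-period train is convolved with a 24-ms quadratic
(Epanechnikov) kernel sampled every 0.6 ms over a 1228.8-ms window (50 ms
before to 178.8 ms after the period), Fourier transformed with 2048
points, DC-removed and normalised so positive-frequency power sums to
100%.  The two frequency bins flanking pf are extracted and their summed
power is the trial response whose mutual information with pattern
identity (G vs E) defines I_Per.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import NeuronRecord, TrialRecord, CLASS_P1, CLASS_P2
from .information import InfoResult, mutual_information
from .simulate import PATTERN_FREQ_HZ

SAMPLE_STEP_MS = 0.6
N_FFT = 2048
WINDOW_PRE_MS = 50.0
KERNEL_WIDTH_MS = 24.0

#: window length: 2048 samples at 0.6 ms = 1228.8 ms
WINDOW_MS = N_FFT * SAMPLE_STEP_MS
#: frequency resolution derived from the FFT configuration (~0.8138 Hz)
FREQ_RESOLUTION_HZ = 1000.0 / WINDOW_MS


@dataclass
class SpectrumResult:
    """Normalised positive-frequency power spectrum of one trial period."""

    frequencies_hz: np.ndarray
    power_percent: np.ndarray
    pf_bin_freqs: tuple[float, float]
    pf_bin_powers: tuple[float, float]
    n_spikes: int

    @property
    def pf_power(self) -> float:
        """Summed power (%) of the two bins flanking the pattern frequency."""
        return float(sum(self.pf_bin_powers))


def pf_flanking_bins(pf_hz: float = PATTERN_FREQ_HZ) -> tuple[int, int]:
    """Indices (1-based into the positive-frequency axis) flanking pf."""
    lo = int(np.floor(pf_hz / FREQ_RESOLUTION_HZ))
    return lo, lo + 1


def spike_spectrum(trial: TrialRecord | np.ndarray,
                   period: str = "P1") -> SpectrumResult:
    """Normalised power spectrum of one trial's stimulus-period spike train.

    Accepts a TrialRecord (period "P1" or "P2" selects the window origin)
    or a bare array of spike times with origin 0.  A zero-spike window
    yields an all-zero spectrum with ``n_spikes == 0`` (callers exclude
    such trials from information estimates).
    """
    if isinstance(trial, TrialRecord):
        if period not in ("P1", "P2"):
            raise ValueError("period must be 'P1' or 'P2'")
        origin = 0.0 if period == "P1" else 3.0
        spikes = trial.spike_times
    else:
        origin = 0.0
        spikes = np.asarray(trial, float)
    t0 = origin - WINDOW_PRE_MS / 1000.0
    grid = t0 + SAMPLE_STEP_MS / 1000.0 * np.arange(N_FFT)
    half = KERNEL_WIDTH_MS / 2000.0
    in_win = spikes[(spikes >= t0 - half) & (spikes < grid[-1] + half)]
    freqs = FREQ_RESOLUTION_HZ * np.arange(1, N_FFT // 2 + 1)
    lo_i, hi_i = pf_flanking_bins()
    if in_win.size == 0:
        zeros = np.zeros(freqs.size)
        return SpectrumResult(freqs, zeros,
                              (freqs[lo_i - 1], freqs[hi_i - 1]), (0.0, 0.0), 0)
    diffs = grid[:, None] - in_win[None, :]
    kern = np.where(np.abs(diffs) <= half,
                    0.75 / half * (1.0 - (diffs / half) ** 2), 0.0)
    signal = kern.sum(axis=1)
    spec = np.fft.rfft(signal, n=N_FFT)
    power = np.abs(spec[1:]) ** 2          # DC removed
    total = power.sum()
    power_pct = 100.0 * power / total if total > 0 else power
    return SpectrumResult(
        frequencies_hz=freqs, power_percent=power_pct,
        pf_bin_freqs=(freqs[lo_i - 1], freqs[hi_i - 1]),
        pf_bin_powers=(float(power_pct[lo_i - 1]), float(power_pct[hi_i - 1])),
        n_spikes=int(in_win.size))


def periodicity_responses(neuron: NeuronRecord, period: str = "P1",
                          task: str = "TPDT",
                          combine: str = "sum") -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-hit-trial pf-power responses and pattern labels.

    ``combine`` = "sum" gives the scalar sum of the two flanking-bin
    powers; "pair" returns the (n_trials, 2) array of both powers.
    Zero-spike trials are excluded (their ids returned as the third item).
    """
    pat_of = CLASS_P1 if period == "P1" else CLASS_P2
    hits = neuron.select(task=task, outcome="hit")
    resp, labels, excluded = [], [], []
    for tr in hits:
        sr = spike_spectrum(tr, period)
        if sr.n_spikes == 0:
            excluded.append(tr.trial_id)
            continue
        resp.append(sr.pf_bin_powers if combine == "pair" else sr.pf_power)
        labels.append(pat_of[tr.class_label])
    return np.asarray(resp, float), np.asarray(labels), excluded


def periodicity_info(neuron: NeuronRecord, period: str = "P1",
                     task: str = "TPDT", n_perm: int = 1000,
                     alpha: float = 0.01, seed: int | np.random.Generator = 0,
                     combine: str = "sum", **mi_kwargs) -> InfoResult:
    """I_Per: mutual information of pf-adjacent spectral power with pattern.

    High for phase-locked (sensory) neurons, near zero for categorical
    neurons without phase-locking.
    """
    resp, labels, _ = periodicity_responses(neuron, period, task, combine=combine)
    if resp.size == 0:
        raise ValueError("no nonzero-spectrum hit trials")
    if combine == "pair":
        # joint discretization of the two flanking-bin powers
        from .information import discretize
        k = max(2, min(4, labels.size // 8))
        codes = discretize(resp[:, 0], k) * k + discretize(resp[:, 1], k)
        resp = codes.astype(float)
        mi_kwargs.setdefault("n_bins", k * k)
    return mutual_information(resp, labels, n_perm=n_perm, alpha=alpha,
                              seed=seed, window=f"{period} pf power", **mi_kwargs)
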