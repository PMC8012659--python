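"""Response/coding latencies, spike-count autocorrelation and timescale fit.

Response latency: the first of five consecutive sliding-window bins whose
stimulus-period rate distribution differs significantly (permutation ROC)
from the pre-stimulus basal rate.  Coding latency: the first of five
consecutive bins with a significant G-vs-E rate difference during P1.

Intrinsic timescale: spike counts in overlapping 40-ms bins (20-ms steps)
of the pre-stimulus second are correlated across trials at each lag; the
population-averaged autocorrelation is fit with

    Aut(t) = A [exp(-t / tau) + B]

by Levenberg-Marquardt nonlinear least squares; tau is the intrinsic
population timescale and B absorbs timescales longer than the window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .coding import _perm_auroc_stats
from .data import CLASS_P1, NeuronRecord, time_grid

logger = logging.getLogger(__name__)


@dataclass
class LatencyResult:
    neuron_id: str
    latency_ms: float | None
    kind: str                 # "response" or "coding"
    window_ms: float
    step_ms: float
    n_consecutive: int


@dataclass
class TimescaleFit:
    amplitude: float
    tau_ms: float
    offset: float
    lags_ms: np.ndarray
    aut: np.ndarray
    fitted: np.ndarray
    residual_norm: float


def _sliding_rates(trials, centers: np.ndarray, window_ms: float) -> np.ndarray:
    w = window_ms / 1000.0
    rates = np.empty((len(trials), centers.size))
    for i, tr in enumerate(trials):
        s = tr.spike_times
        a = np.searchsorted(s, centers - w / 2, "left")
        b = np.searchsorted(s, centers + w / 2, "left")
        rates[i] = (b - a) / w
    return rates


def _first_run(sig: np.ndarray, n_consec: int) -> int | None:
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= n_consec:
            return i - n_consec + 1
    return None


def response_latency(neuron: NeuronRecord, window_ms: float = 200.0,
                     step_ms: float = 1.0, n_consec: int = 5,
                     alpha: float = 0.05, n_perm: int = 1000,
                     seed: int | np.random.Generator = 0,
                     task: str = "TPDT") -> LatencyResult:
    """Latency of the stimulus-driven response during P1 (ms after onset).

    Sliding-window rates are compared against each trial's basal rate
    (the 200 ms before P1 onset) with a permutation ROC test; the latency
    is the first bin center opening a run of ``n_consec`` significant bins.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = neuron.select(task=task, outcome="hit")
    if not trials:
        raise ValueError("no hit trials")
    basal = np.array([_sliding_rates([t], np.array([-0.1]), 200.0)[0, 0]
                      for t in trials])
    centers = time_grid(0.0, 1.0 + 1e-9, step_ms)
    rates = _sliding_rates(trials, centers, window_ms)
    sig = np.zeros(centers.size, dtype=bool)
    for b in range(centers.size):
        obs, null = _perm_auroc_stats(basal, rates[:, b], n_perm, rng)
        p = (np.sum(null >= obs - 1e-12) + 1.0) / (n_perm + 1.0)
        sig[b] = p < alpha
    idx = _first_run(sig, n_consec)
    lat = None if idx is None else float(centers[idx] * 1000.0)
    return LatencyResult(neuron.neuron_id, lat, "response", window_ms,
                         step_ms, n_consec)


def coding_latency(neuron: NeuronRecord, window_ms: float = 200.0,
                   step_ms: float = 10.0, n_consec: int = 5,
                   alpha: float = 0.05, n_perm: int = 1000,
                   seed: int | np.random.Generator = 0,
                   task: str = "TPDT") -> LatencyResult:
    """Latency of significant G-vs-E pattern coding during P1 (ms)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = neuron.select(task=task, outcome="hit")
    g = [t for t in hits if CLASS_P1[t.class_label] == "G"]
    e = [t for t in hits if CLASS_P1[t.class_label] == "E"]
    if len(g) < 2 or len(e) < 2:
        raise ValueError("need P1 trials of both patterns")
    centers = time_grid(0.0, 1.0 + 1e-9, step_ms)
    rg = _sliding_rates(g, centers, window_ms)
    re = _sliding_rates(e, centers, window_ms)
    sig = np.zeros(centers.size, dtype=bool)
    for b in range(centers.size):
        obs, null = _perm_auroc_stats(rg[:, b], re[:, b], n_perm, rng)
        p = (np.sum(null >= obs - 1e-12) + 1.0) / (n_perm + 1.0)
        sig[b] = p < alpha
    idx = _first_run(sig, n_consec)
    lat = None if idx is None else float(centers[idx] * 1000.0)
    return LatencyResult(neuron.neuron_id, lat, "coding", window_ms,
                         step_ms, n_consec)


# ---------------------------------------------------------------------------
# Autocorrelation and timescale


def autocorrelation(counts: np.ndarray, bin_ms: float = 40.0,
                    step_ms: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial spike-count autocorrelation versus lag.

    ``counts`` is (n_trials, n_bins) from overlapping basal-period bins.
    For each positive lag, the Pearson correlation across trials is
    computed for every bin pair at that lag and averaged with equal
    weight; zero-variance bins are skipped (logged).  Lag 0 is excluded
    (it is 1 by construction).  Returns (lags_ms, aut).
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("counts must be (>=2 trials, >=2 bins)")
    n_bins = counts.shape[1]
    sd = counts.std(axis=0)
    ok = sd > 0
    if not ok.all():
        logger.info("autocorrelation: skipping %d zero-variance bins",
                    int((~ok).sum()))
    z = np.where(ok, 1.0, np.nan) * (counts - counts.mean(axis=0)) / \
        np.where(ok, sd, 1.0)
    lags = np.arange(1, n_bins)
    aut = np.full(lags.size, np.nan)
    n_pairs = np.zeros(lags.size, dtype=int)
    for li, lag in enumerate(lags):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.nanmean(z[:, :n_bins - lag] * z[:, lag:], axis=0)
        # nanmean over trials is exact Pearson (population normalisation)
        valid = ~np.isnan(corr)
        n_pairs[li] = int(valid.sum())
        if valid.any():
            aut[li] = float(corr[valid].mean())
    return lags * step_ms, aut


def population_autocorrelation(count_mats: Sequence[np.ndarray],
                               bin_ms: float = 40.0,
                               step_ms: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Average the per-neuron autocorrelation curves across the population."""
    curves = []
    lags = None
    for c in count_mats:
        lg, aut = autocorrelation(c, bin_ms, step_ms)
        lags = lg
        curves.append(aut)
    return lags, np.nanmean(np.stack(curves), axis=0)


def _decay(t, a, tau, b):
    return a * (np.exp(-t / tau) + b)


def fit_timescale(lags_ms: np.ndarray, aut: np.ndarray,
                  min_lag_ms: float = 40.0, max_lag_ms: float = 960.0,
                  n_restarts: int = 5, step_ms: float = 20.0,
                  window_ms: float = 1000.0, bin_ms: float = 40.0,
                  seed: int = 0) -> TimescaleFit:
    """Fit Aut(t) = A [exp(-t/tau) + B] on the population curve.

    Levenberg-Marquardt least squares; initialisation A = Aut(min lag),
    tau = 100 ms, B = Aut(max lag)/A, with jittered multi-start restarts
    on failure.  Lags shorter than the bin width are excluded by default:
    overlapping bins share spikes there, so the Poisson noise itself is
    correlated and inflates Aut above the rate-modulation decay.  Points
    are weighted by the square root of the number of bin pairs entering
    each lag (long lags average fewer pairs and are noisier).
    """
    lags_ms = np.asarray(lags_ms, float)
    aut = np.asarray(aut, float)
    mask = (lags_ms >= min_lag_ms) & (lags_ms <= max_lag_ms) & np.isfinite(aut)
    t, y = lags_ms[mask], aut[mask]
    if t.size < 4:
        raise ValueError("need >= 4 finite lags inside the fit range")
    n_bins = int(round((window_ms - bin_ms) / step_ms)) + 1
    n_pairs = np.maximum(n_bins - np.round(t / step_ms).astype(int), 1)
    sigma = 1.0 / np.sqrt(n_pairs)
    a0 = y[0] if y[0] > 0 else max(y.max(), 1e-3)
    b0 = y[-1] / a0 if a0 != 0 else 0.0
    rng = np.random.default_rng(seed)
    last_err = None
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            p0 = (a0, 100.0, b0)
        else:
            p0 = (a0 * rng.uniform(0.3, 3.0),
                  float(rng.uniform(30.0, 400.0)),
                  b0 + rng.uniform(-0.2, 0.2))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_decay, t, y, p0=p0, method="lm",
                                    sigma=sigma, maxfev=20000)
            if popt[1] <= 0:
                raise RuntimeError("nonpositive tau")
            if popt[1] > 10 * max_lag_ms:
                warnings.warn(
                    f"tau = {popt[1]:.0f} ms is far beyond the lag range; "
                    "the decay is unresolved at this trial count")
            fitted = _decay(t, *popt)
            return TimescaleFit(amplitude=float(popt[0]), tau_ms=float(popt[1]),
                                offset=float(popt[2]), lags_ms=t, aut=y,
                                fitted=fitted,
                                residual_norm=float(np.linalg.norm(y - fitted)))
        except (RuntimeError, ValueError) as exc:
            last_err = exc
    raise RuntimeError(f"timescale fit failed after {n_restarts + 1} starts: "
                       f"{last_err}")


def basal_count_matrix(neuron: NeuronRecord, bin_ms: float = 40.0,
                       step_ms: float = 20.0, t_start: float = -1.0,
                       t_end: float = 0.0, task: str | None = None) -> np.ndarray:
    """Overlapping-bin spike counts of the basal period, all trials pooled."""
    trials = neuron.trials if task is None else neuron.select(task=task)
    starts = np.arange(t_start, t_end - bin_ms / 1000.0 + 1e-9, step_ms / 1000.0)
    counts = np.empty((len(trials), starts.size))
    for i, tr in enumerate(trials):
        s = tr.spike_times
        a = np.searchsorted(s, starts, "left")
        b = np.searchsorted(s, starts + bin_ms / 1000.0, "left")
        counts[i] = b - a
    return counts
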