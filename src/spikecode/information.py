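"""Shannon mutual-information estimators for neural responses.

The core estimator discretizes a scalar response into equipopulated bins,
computes plug-in mutual information with a binary label (pattern identity,
decision or reward), subtracts the Panzeri-Treves sampling-bias term, and
assesses significance by label permutation.  On top of it sit the 1-s
spike-count pattern information (I_1s), time-resolved population
information from pooled z-scores (P1 / decision / reward targets), the
window-width information curve, the sensory/categorical neuron taxonomy at
the 0.25-bit threshold, and the task-comparison angle summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import (CLASS_P1, CLASS_P2, NeuronRecord, ZeroVarianceNeuron,
                   time_grid, trial_rate_matrix, zscore_rates)

LN2 = np.log(2.0)


@dataclass
class InfoResult:
    """A mutual-information value in bits with estimator provenance.

    ``bits`` is the bias-corrected value floored at zero; ``bits_raw``
    retains the (possibly slightly negative) corrected value and
    ``bits_plugin`` the uncorrected plug-in estimate.
    """

    bits: float
    bits_raw: float
    bits_plugin: float
    p_value: float
    n_trials: int
    n_bins: int
    correction: str
    significant: bool
    window: str = ""


def discretize(responses: np.ndarray, n_bins: int) -> np.ndarray:
    """Equipopulated (quantile) binning of a scalar response."""
    responses = np.asarray(responses, float)
    edges = np.quantile(responses, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, responses, side="right")


def _plugin_mi(resp_bins: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Plug-in MI (bits) and the joint count table."""
    rb = np.unique(resp_bins, return_inverse=True)[1]
    lb = np.unique(labels, return_inverse=True)[1]
    joint = np.zeros((rb.max() + 1, lb.max() + 1))
    np.add.at(joint, (rb, lb), 1.0)
    p = joint / joint.sum()
    pr = p.sum(axis=1, keepdims=True)
    ps = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (pr * ps))
    return float(np.nansum(term)), joint


def _pt_bias(joint: np.ndarray) -> float:
    """Panzeri-Treves first-order bias of plug-in MI, in bits.

    bias(I) = [sum_s (R_s - 1) - (R - 1)] / (2 N ln 2), with R the number
    of occupied response bins overall and R_s per stimulus.
    """
    n = joint.sum()
    r_total = np.count_nonzero(joint.sum(axis=1))
    r_per_s = np.count_nonzero(joint, axis=0)
    return (float(np.sum(r_per_s - 1)) - (r_total - 1)) / (2.0 * n * LN2)


def _corrected_mi(resp_bins: np.ndarray, labels: np.ndarray,
                  correction: str) -> tuple[float, float]:
    """(corrected, plug-in) MI in bits."""
    plug, joint = _plugin_mi(resp_bins, labels)
    if correction == "pt":
        return plug - _pt_bias(joint), plug
    if correction in (None, "none"):
        return plug, plug
    raise ValueError(f"unknown correction {correction!r}")


def mutual_information(responses: np.ndarray, labels: np.ndarray,
                       n_bins: int | None = None, correction: str = "pt",
                       n_perm: int = 1000, alpha: float = 0.01,
                       seed: int | np.random.Generator = 0,
                       shuffle_subtract: bool = False,
                       window: str = "") -> InfoResult:
    """Binned MI between a scalar response and a discrete label.

    Responses are discretized into ``n_bins`` equipopulated bins (default
    min(8, n_trials // 4)); the Panzeri-Treves bias term is subtracted;
    significance comes from ``n_perm`` label permutations with the add-one
    p-value estimator.  ``shuffle_subtract`` additionally subtracts the
    mean shuffled-label MI (an alternative bias control).
    """
    responses = np.asarray(responses, float)
    labels = np.asarray(labels)
    if responses.size != labels.size:
        raise ValueError("responses and labels must align")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 trials per label and >= 2 labels")
    n = responses.size
    if n_bins is None:
        n_bins = max(2, min(8, n // 4))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.ptp(responses) == 0:
        return InfoResult(0.0, 0.0, 0.0, 1.0, n, n_bins, correction, False, window)
    resp_bins = discretize(responses, n_bins)
    corrected, plug = _corrected_mi(resp_bins, labels, correction)
    null = np.empty(n_perm)
    lab = labels.copy()
    for i in range(n_perm):
        rng.shuffle(lab)
        null[i], _ = _corrected_mi(resp_bins, lab, correction)
    p = (np.sum(null >= corrected - 1e-12) + 1.0) / (n_perm + 1.0)
    if shuffle_subtract:
        corrected = corrected - float(null.mean())
    return InfoResult(bits=max(corrected, 0.0), bits_raw=float(corrected),
                      bits_plugin=float(plug), p_value=float(p), n_trials=n,
                      n_bins=n_bins, correction=correction,
                      significant=bool(p < alpha), window=window)


# ---------------------------------------------------------------------------
# 1-s categorical information


def _count_in(trial, lo: float, hi: float) -> int:
    s = trial.spike_times
    return int(np.searchsorted(s, hi, "left") - np.searchsorted(s, lo, "left"))


def info_1s(neuron: NeuronRecord, period: str = "P1", task: str = "TPDT",
            n_perm: int = 1000, alpha: float = 0.01,
            seed: int | np.random.Generator = 0, **mi_kwargs) -> InfoResult:
    """Pattern information of the full-stimulus (1 s) spike count.

    The response is the spike count over the whole P1 (0-1 s) or P2 (3-4 s)
    period of each hit trial; the label is the pattern identity (G or E).
    Near zero for phase-locked sensory neurons (both patterns have five
    pulses), high for categorical neurons.
    """
    if period not in ("P1", "P2"):
        raise ValueError("period must be 'P1' or 'P2'")
    lo, hi = (0.0, 1.0) if period == "P1" else (3.0, 4.0)
    pat_of = CLASS_P1 if period == "P1" else CLASS_P2
    hits = neuron.select(task=task, outcome="hit")
    counts = np.array([_count_in(t, lo, hi) for t in hits], float)
    labels = np.array([pat_of[t.class_label] for t in hits])
    return mutual_information(counts, labels, n_perm=n_perm, alpha=alpha,
                              seed=seed, window=f"{period} 1 s count",
                              **mi_kwargs)


# ---------------------------------------------------------------------------
# Time-resolved population information (pooled z-scores)


def population_info_time(neurons: Sequence[NeuronRecord], target: str = "P1",
                         trial_filter: str = "hits", window_ms: float = 200.0,
                         step_ms: float = 50.0, t_start: float = -1.0,
                         t_end: float = 7.5, n_perm: int = 200,
                         alpha: float = 0.01, n_boot: int = 0,
                         seed: int | np.random.Generator = 0,
                         task: str = "TPDT") -> dict:
    """I(t) of pooled population z-scores about P1 identity, decision or reward.

    Per bin, z-scored single-trial rates from all neurons are pooled into
    one response distribution per label.  For targets "P1" and "DEC" the
    label is the pattern / reported decision and ``trial_filter`` selects
    hits or errors; for "REW" the label is the outcome itself (hits vs
    errors).  Returns bin centers, corrected I(t), p-values and (optional)
    bootstrap 95% CIs over trials.
    """
    if target not in ("P1", "DEC", "REW"):
        raise ValueError("target must be P1, DEC or REW")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = time_grid(t_start, t_end, step_ms)
    pooled_z, pooled_lab = [], []
    skipped = []
    for nr in neurons:
        if target == "REW":
            trials = nr.select(task=task)
        else:
            outcome = {"hits": "hit", "errors": "error", "all": None}[trial_filter]
            trials = nr.select(task=task, outcome=outcome)
        if not trials:
            continue
        try:
            _, z, _, _ = zscore_rates(nr, trials, window_ms, step_ms,
                                      t_start, t_end, task)
        except ZeroVarianceNeuron:
            skipped.append(nr.neuron_id)
            continue
        if target == "P1":
            lab = [CLASS_P1[t.class_label] for t in trials]
        elif target == "DEC":
            lab = [t.decision_reported for t in trials]
        else:
            lab = [t.outcome for t in trials]
        pooled_z.append(z)
        pooled_lab.extend(lab)
    if not pooled_z:
        raise ValueError("no z-scorable neurons")
    z_all = np.concatenate(pooled_z, axis=0)       # (sum trials, n_bins)
    labels = np.array(pooled_lab)
    info = np.full(centers.size, np.nan)
    pvals = np.full(centers.size, np.nan)
    ci = np.full((centers.size, 2), np.nan)
    uniq, cnt = np.unique(labels, return_counts=True)
    if uniq.size < 2 or cnt.min() < 2:
        return {"bin_centers": centers, "bits": info, "p_values": pvals,
                "ci95": ci, "skipped": skipped}
    for b in range(centers.size):
        res = mutual_information(z_all[:, b], labels, n_perm=n_perm,
                                 alpha=alpha, seed=rng)
        info[b] = res.bits
        pvals[b] = res.p_value
        if n_boot:
            boots = np.empty(n_boot)
            for k in range(n_boot):
                idx = rng.integers(0, labels.size, labels.size)
                if np.unique(labels[idx]).size < 2:
                    boots[k] = np.nan
                    continue
                r, j = _plugin_mi(discretize(z_all[idx, b],
                                             max(2, min(8, labels.size // 4))),
                                  labels[idx])
                boots[k] = max(r - _pt_bias(j), 0.0)
            ci[b] = np.nanpercentile(boots, [2.5, 97.5])
    return {"bin_centers": centers, "bits": info, "p_values": pvals,
            "ci95": ci, "skipped": skipped}


# ---------------------------------------------------------------------------
# Window-width analysis


def info_vs_window(neuron: NeuronRecord, widths_ms: Sequence[float] = tuple(
        range(10, 1001, 10)), step_ms: float = 10.0, period: str = "P1",
        task: str = "TPDT", n_perm: int = 100,
        seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged pattern information as a function of window width.

    For each width, single-trial rates slide across the stimulus period and
    the per-bin pattern MI is averaged over time.  Phase-locked neurons
    peak at an interior width (coarse windows wash out phase structure);
    categorical neurons saturate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo = 0.0 if period == "P1" else 3.0
    pat_of = CLASS_P1 if period == "P1" else CLASS_P2
    hits = neuron.select(task=task, outcome="hit")
    labels = np.array([pat_of[t.class_label] for t in hits])
    widths = np.asarray(widths_ms, float)
    mean_info = np.empty(widths.size)
    for i, w in enumerate(widths):
        # windows fully inside the 1-s stimulus period
        t0, t1 = lo + w / 2000.0, lo + 1.0 - w / 2000.0 + 1e-9
        if t1 <= t0:
            t0 = t1 = lo + 0.5
        centers = time_grid(t0, t1 + 1e-9, step_ms)
        rates = np.empty((len(hits), centers.size))
        for j, tr in enumerate(hits):
            s = tr.spike_times
            a = np.searchsorted(s, centers - w / 2000.0, "left")
            b = np.searchsorted(s, centers + w / 2000.0, "left")
            rates[j] = (b - a) / (w / 1000.0)
        vals = [mutual_information(rates[:, b], labels, n_perm=n_perm,
                                   alpha=0.01, seed=rng).bits
                for b in range(centers.size)]
        mean_info[i] = float(np.mean(vals))
    return widths, mean_info


# ---------------------------------------------------------------------------
# Sensory / categorical taxonomy


@dataclass
class NeuronInfoProfile:
    """Per-neuron information summary and taxonomy label."""

    neuron_id: str
    i_per: float
    i_per_significant: bool
    i_1s_p1: float
    i_1s_p1_significant: bool
    i_1s_p2: float
    i_1s_p2_significant: bool
    label: str = "intermediate"
    threshold: float = 0.25


def classify_neurons(profiles: Sequence[NeuronInfoProfile],
                     threshold: float = 0.25) -> list[NeuronInfoProfile]:
    """Label neurons sensory / categorical by the information criterion.

    sensory: significant I_Per above threshold; categorical: significant
    I_1s(P1) above threshold.  On realistic data the two extremes are
    mutually exclusive; a neuron passing both is labelled "ambiguous" and
    flagged with a warning rather than silently resolved.
    """
    out = []
    for p in profiles:
        sens = p.i_per_significant and p.i_per > threshold
        cat = p.i_1s_p1_significant and p.i_1s_p1 > threshold
        if sens and cat:
            warnings.warn(f"neuron {p.neuron_id} satisfies both criteria")
            label = "ambiguous"
        elif sens:
            label = "sensory"
        elif cat:
            label = "categorical_P1"
        else:
            label = "intermediate"
        out.append(NeuronInfoProfile(
            neuron_id=p.neuron_id, i_per=p.i_per,
            i_per_significant=p.i_per_significant, i_1s_p1=p.i_1s_p1,
            i_1s_p1_significant=p.i_1s_p1_significant, i_1s_p2=p.i_1s_p2,
            i_1s_p2_significant=p.i_1s_p2_significant, label=label,
            threshold=threshold))
    return out


def task_angle(info_tpdt: np.ndarray, info_lct: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean angle (degrees) of per-neuron (TPDT, LCT) information pairs.

    theta = atan2(LCT, TPDT) per neuron; 45 deg means task-invariant
    information, above 45 deg means the LCT value dominates.  Both-zero
    pairs are excluded.  Returns (arithmetic mean angle, per-neuron angles).
    """
    info_tpdt = np.asarray(info_tpdt, float)
    info_lct = np.asarray(info_lct, float)
    if np.any(info_tpdt < 0) or np.any(info_lct < 0):
        raise ValueError("information values must be non-negative")
    keep = (info_tpdt > 0) | (info_lct > 0)
    angles = np.degrees(np.arctan2(info_lct[keep], info_tpdt[keep]))
    if angles.size == 0:
        raise ValueError("all pairs are (0, 0)")
    return float(angles.mean()), angles
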