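"""Single-neuron coding classification via pairwise AUROCs and binary words.

At each time bin, each of the six ordered class pairs is compared with the
area under the ROC curve between the two firing-rate distributions; a
permutation test on shuffled class labels decides statistical inequality
(digit 1) or equality (digit 0).  Digits are only assigned inside runs of
at least four consecutive bins with the same raw outcome (a multiple-
comparisons guard), yielding per-bin six-digit binary words.  Of the 64
possible words, exactly seven map to interpretable coding profiles: P1
identity, P2 identity, decision (match/nonmatch) and the four single-class
selectivities.  The same machinery computes choice probability, the
hit-versus-error ROC overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .data import (CLASSES, NeuronRecord, time_grid, trial_rate_matrix)

#: canonical ordering of the six class pairs (lexicographic)
PAIR_ORDER: tuple[tuple[str, str], ...] = tuple(combinations(CLASSES, 2))

UNASSIGNED = -1

PROFILES = ("P1", "P2", "class_c1", "class_c2", "class_c3", "class_c4",
            "decision")


def auroc(x: np.ndarray, y: np.ndarray) -> float:
    """P(random draw from y exceeds one from x), ties counted 1/2.

    Equivalent to the Mann-Whitney U statistic divided by n_x * n_y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("auroc requires nonempty samples")
    ranks = rankdata(np.concatenate([x, y]))
    u = ranks[x.size:].sum() - y.size * (y.size + 1) / 2.0
    return float(u / (x.size * y.size))


@dataclass(frozen=True)
class SignificanceResult:
    """AUROC with permutation p-value."""

    auroc: float
    p_value: float
    n_permutations: int
    significant: bool


def _perm_auroc_stats(x: np.ndarray, y: np.ndarray, n_perm: int,
                      rng: np.random.Generator) -> tuple[float, np.ndarray]:
    """Observed |AUROC - 0.5| and the shuffled-surrogate distribution."""
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    obs = abs(ranks[nx:].sum() - ny * (ny + 1) / 2.0 - nx * ny / 2.0) / (nx * ny)
    # permute which trials carry label y: shuffle the ranks row-wise
    mat = np.tile(ranks, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    u = mat[:, nx:].sum(axis=1) - ny * (ny + 1) / 2.0
    null = np.abs(u / (nx * ny) - 0.5)
    return float(obs), null


def permutation_test_auroc(x: np.ndarray, y: np.ndarray, n_perm: int = 1000,
                           alpha: float = 0.05,
                           seed: int | np.random.Generator = 0) -> SignificanceResult:
    """Two-sided permutation test of AUROC != 0.5 via label shuffling.

    The p-value uses the add-one estimator (b + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = auroc(x, y)
    obs, null = _perm_auroc_stats(x, y, n_perm, rng)
    p = (np.sum(null >= obs - 1e-12) + 1.0) / (n_perm + 1.0)
    return SignificanceResult(auroc=a, p_value=float(p), n_permutations=n_perm,
                              significant=bool(p < alpha and a != 0.5))


def stability_filter(raw: np.ndarray, min_run: int = 4) -> np.ndarray:
    """Keep digits only inside runs of >= min_run identical raw outcomes.

    ``raw`` is a 0/1 vector; bins outside qualifying runs become UNASSIGNED.
    """
    raw = np.asarray(raw, int)
    out = np.full(raw.shape, UNASSIGNED, dtype=int)
    if raw.size == 0:
        return out
    start = 0
    for i in range(1, raw.size + 1):
        if i == raw.size or raw[i] != raw[start]:
            if i - start >= min_run:
                out[start:i] = raw[start]
            start = i
    return out


@dataclass
class CodingWordSeries:
    """Per-bin six-digit words (UNASSIGNED = -1) and profile labels."""

    bin_centers: np.ndarray
    digits: np.ndarray          # (n_bins, 6) in PAIR_ORDER
    labels: list[str] = field(default_factory=list)   # per-bin profile

    def word_strings(self) -> list[str]:
        return ["".join("x" if d == UNASSIGNED else str(d) for d in row)
                for row in self.digits]


def digit_series(class_rates: dict[str, np.ndarray], alpha: float = 0.05,
                 n_perm: int = 1000, stability: int = 4,
                 seed: int | np.random.Generator = 0,
                 bin_centers: np.ndarray | None = None) -> CodingWordSeries:
    """Six-digit binary-word series from per-class rate matrices.

    ``class_rates[c]`` is (n_trials_c, n_bins).  For each pair and bin, the
    raw outcome is 1 when the permutation test rejects AUROC = 0.5 at
    ``alpha``; digits are assigned only inside runs of >= ``stability``
    identical raw outcomes.  Bins with fewer than 2 trials in a class are
    unassigned for that class's pairs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = next(iter(class_rates.values())).shape[1]
    if bin_centers is None:
        bin_centers = np.arange(n_bins, dtype=float)
    digits = np.full((n_bins, 6), UNASSIGNED, dtype=int)
    for j, (ca, cb) in enumerate(PAIR_ORDER):
        xa, xb = class_rates[ca], class_rates[cb]
        if xa.shape[0] < 2 or xb.shape[0] < 2:
            continue
        raw = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            res = permutation_test_auroc(xa[:, b], xb[:, b], n_perm=n_perm,
                                         alpha=alpha, seed=rng)
            raw[b] = int(res.significant)
        digits[:, j] = stability_filter(raw, min_run=stability)
    series = CodingWordSeries(bin_centers=np.asarray(bin_centers, float),
                              digits=digits)
    series.labels = [_label_word(tuple(row)) for row in digits]
    return series


# ---------------------------------------------------------------------------
# Binary-word library


def _pair_index(a: str, b: str) -> int:
    key = (a, b) if (a, b) in PAIR_ORDER else (b, a)
    return PAIR_ORDER.index(key)


def _profile_word(equal_pairs: Sequence[tuple[str, str]]) -> tuple[int, ...]:
    word = [1] * 6
    for a, b in equal_pairs:
        word[_pair_index(a, b)] = 0
    return tuple(word)


def enumerate_label_words() -> dict[tuple[int, ...], str]:
    """Map each of the 64 six-digit words to its profile, by brute force.

    Exactly seven words are labeled: responses equal within same-P1 pairs
    and different otherwise (P1 identity); same for P2; equal within
    same-outcome pairs (decision); and the four words where one class
    differs from all three mutually-equal others (class selectivity).
    The remaining 57 words are mixed/ambiguous and map to "noncoding".
    """
    rules: dict[tuple[int, ...], str] = {}
    rules[_profile_word([("c1", "c2"), ("c3", "c4")])] = "P1"
    rules[_profile_word([("c1", "c3"), ("c2", "c4")])] = "P2"
    rules[_profile_word([("c1", "c4"), ("c2", "c3")])] = "decision"
    for k in CLASSES:
        others = [c for c in CLASSES if c != k]
        rules[_profile_word(list(combinations(others, 2)))] = f"class_{k}"
    out: dict[tuple[int, ...], str] = {}
    for w in range(64):
        word = tuple((w >> (5 - i)) & 1 for i in range(6))
        out[word] = rules.get(word, "noncoding")
    return out


_WORD_MAP = enumerate_label_words()


def _label_word(word: tuple[int, ...]) -> str:
    if any(d == UNASSIGNED for d in word):
        return "unassigned"
    return _WORD_MAP[word]


def classify_profiles(series: CodingWordSeries, min_run: int = 4) -> dict:
    """Per-bin labels plus per-profile significant-coder masks.

    A neuron counts as coding a profile at a bin only within runs of
    >= ``min_run`` consecutive bins holding that same profile label.
    """
    labels = series.labels or [_label_word(tuple(r)) for r in series.digits]
    n = len(labels)
    coding = {p: np.zeros(n, dtype=bool) for p in PROFILES}
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            lab = labels[start]
            if lab in coding and i - start >= min_run:
                coding[lab][start:i] = True
            start = i
    return {"labels": labels, "coding": coding,
            "coder_flags": {p: bool(mask.any()) for p, mask in coding.items()}}


def neuron_coding_masks(neuron: NeuronRecord, alpha: float = 0.05,
                        n_perm: int = 1000, stability: int = 4,
                        window_ms: float = 200.0, step_ms: float = 50.0,
                        t_start: float = -1.0, t_end: float = 7.5,
                        task: str = "TPDT",
                        seed: int | np.random.Generator = 0) -> dict:
    """Full word pipeline for one neuron's hit trials."""
    class_rates = {}
    centers = time_grid(t_start, t_end, step_ms)
    for c in CLASSES:
        trials = neuron.select(task=task, outcome="hit", class_label=c)
        if len(trials) < 2:
            class_rates[c] = np.empty((len(trials), centers.size))
            continue
        _, rates = trial_rate_matrix(trials, window_ms, step_ms, t_start, t_end)
        class_rates[c] = rates
    series = digit_series(class_rates, alpha=alpha, n_perm=n_perm,
                          stability=stability, seed=seed, bin_centers=centers)
    out = classify_profiles(series, min_run=stability)
    out["series"] = series
    return out


def population_coding_fraction(neuron_results: Sequence[dict],
                               profile: str) -> np.ndarray:
    """Percentage of neurons coding ``profile`` per bin (0-100)."""
    if not neuron_results:
        raise ValueError("no neurons")
    masks = np.stack([r["coding"][profile] for r in neuron_results])
    return 100.0 * masks.mean(axis=0)


# ---------------------------------------------------------------------------
# Choice probability


def choice_probability(neuron: NeuronRecord, window_ms: float = 200.0,
                       step_ms: float = 50.0, t_start: float = 3.0,
                       t_end: float | None = None,
                       min_trials: int = 2) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """CP(t): hit-vs-error ROC overlap per stimulus pair, averaged over pairs.

    0.5 means full overlap of the hit and error rate distributions.  Classes
    without at least ``min_trials`` hits and errors are excluded (logged in
    the returned list).  Returns (bin_centers, cp (n_bins,), excluded).
    """
    if t_end is None:
        pbs = [t.event_times["pb"] for t in neuron.select(task="TPDT")]
        t_end = max(pbs) + 1.5
    centers = time_grid(t_start, t_end, step_ms)
    per_class, excluded = [], []
    for c in CLASSES:
        hits = neuron.select(task="TPDT", outcome="hit", class_label=c)
        errs = neuron.select(task="TPDT", outcome="error", class_label=c)
        if len(hits) < min_trials or len(errs) < min_trials:
            excluded.append(c)
            continue
        _, rh = trial_rate_matrix(hits, window_ms, step_ms, t_start, t_end)
        _, re = trial_rate_matrix(errs, window_ms, step_ms, t_start, t_end)
        cp_c = np.array([auroc(re[:, b], rh[:, b]) for b in range(centers.size)])
        per_class.append(cp_c)
    cp = (np.mean(per_class, axis=0) if per_class
          else np.full(centers.size, np.nan))
    return centers, cp, excluded
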