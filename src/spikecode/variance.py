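"""Instantaneous population coding-variance decomposition.

The population coding variance at each bin is the per-neuron-normalised
squared deviation of the four class-mean rates from their grand mean:

    Var_COD(t) = (1/N)(1/4) sum_i sum_c (r_i(t,c) - r_i(t))^2

Grouping the four classes into the two P1 identities, the two P2
identities, or the two decision outcomes gives the parameter variances
Var_P1, Var_P2, Var_DEC (each (1/N)(1/2) sum over the two group means).
Because the classes form a 2x2 factorial in (P1, P2) and the decision
grouping is its interaction contrast, the decomposition is exactly
additive: Var_COD = Var_P1 + Var_P2 + Var_DEC at every bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PopulationTensor

#: class-index pairs per grouping (classes ordered c1, c2, c3, c4)
GROUPINGS = {
    "P1": ((0, 1), (2, 3)),    # G-* vs E-*
    "P2": ((0, 2), (1, 3)),    # *-G vs *-E
    "DEC": ((0, 3), (1, 2)),   # match vs nonmatch
}


@dataclass
class VarianceSeries:
    """Time-resolved variance decomposition with its pre-stimulus floor."""

    bin_centers: np.ndarray
    var_cod: np.ndarray
    var_p1: np.ndarray
    var_p2: np.ndarray
    var_dec: np.ndarray
    basal: float


def coding_variance(pop: PopulationTensor) -> np.ndarray:
    """Var_COD(t): among-class rate variance, normalised per neuron."""
    r = pop.class_rates                       # (N, T, 4)
    dev = r - pop.grand_mean[:, :, None]
    return (dev ** 2).mean(axis=2).mean(axis=0)


def parameter_variance(pop: PopulationTensor, grouping: str) -> np.ndarray:
    """Var(t) for a two-group partition of the classes (P1, P2 or DEC)."""
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {sorted(GROUPINGS)}, "
                         f"got {grouping!r}")
    r = pop.class_rates
    gm = pop.grand_mean
    acc = np.zeros(gm.shape)
    for idx in GROUPINGS[grouping]:
        group_mean = r[:, :, idx].mean(axis=2)
        acc += (group_mean - gm) ** 2
    return (acc / 2.0).mean(axis=0)


def basal_variance(values: np.ndarray, bin_centers: np.ndarray,
                   window: tuple[float, float] = (-1.0, 0.0)) -> float:
    """Mean of a variance series over the pre-stimulus bins (noise floor)."""
    mask = (bin_centers >= window[0]) & (bin_centers < window[1])
    if not mask.any():
        raise ValueError("no bins inside the basal window")
    return float(values[mask].mean())


def variance_series(pop: PopulationTensor,
                    basal_window: tuple[float, float] = (-1.0, 0.0)) -> VarianceSeries:
    """Full decomposition plus the basal (pre-stimulus) Var_COD floor."""
    var_cod = coding_variance(pop)
    return VarianceSeries(
        bin_centers=pop.bin_centers,
        var_cod=var_cod,
        var_p1=parameter_variance(pop, "P1"),
        var_p2=parameter_variance(pop, "P2"),
        var_dec=parameter_variance(pop, "DEC"),
        basal=basal_variance(var_cod, pop.bin_centers, basal_window),
    )
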