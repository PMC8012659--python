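# Methods

This note documents the models, estimators and numerical choices behind
`spikecode`, in the order the pipeline applies them.

## Task timeline and data model

All times are in seconds relative to P1 onset. The canonical trial has
P1 at 0–1 s, a 2-s working-memory delay, P2 at 3–4 s, a 2-s post-P2
delay, probe-up (pu) at ≥6 s, then key-up and push-button; spikes span
probe-down (pd, ≈ −3 s) to 1.5 s after the button press. The four trial
classes are the ordered pattern pairs c1=G-G, c2=G-E, c3=E-G, c4=E-E.
Control-task (LCT) trials use identical stimuli and are always correct.

Firing rates use a square (boxcar) kernel: the rate at bin center *t* is
the spike count in the half-open window [t−w/2, t+w/2) divided by w,
with w = 200 ms and 50-ms steps by default. Bin centers lie on the
half-open grid [t_start, t_end), which makes the default −1 to 7.5-s
analysis range exactly 170 bins; windows at the grid edges draw on trial
data outside the range (which always exists on the task timeline).
Whether edge windows are instead truncated is isolated in
`data.time_grid`/`estimate_rate` and nowhere else.

z-scoring uses one scalar mean and SD per neuron, pooled over **all**
hit-trial bins of the analysis range; population mean z-traces are
mapped back to sp/s with the population-average mean and SD. A neuron
whose hit rates have zero variance cannot be normalised and is excluded
from pooled analyses (raised as `ZeroVarianceNeuron` and logged by
callers).

## ROC coding words

For each of the six class pairs and each bin, the area under the ROC
curve between the two rate distributions (equivalently the Mann–Whitney
U statistic over n·m, ties counted ½) is tested against 0.5 with a
two-sided permutation test (|AUROC−0.5| over 1000 label shuffles,
add-one p-value (b+1)/(n+1), α = 0.05). The per-bin outcome becomes a
digit (1 = different, 0 = equal) only inside runs of ≥4 consecutive bins
with the same raw outcome; otherwise the bin is unassigned — a
multiple-comparisons guard that can only remove false positives. Pair
order is fixed lexicographically: (c1,c2), (c1,c3), (c1,c4), (c2,c3),
(c2,c4), (c3,c4). Words are mapped to profiles by brute-force
enumeration of all 64 words against four rules (P1-equal pairs equal and
the rest different; same for P2; same for decision; one class different
from three mutually equal others); exactly 7 words are labeled. A neuron
counts as *coding* a profile only within runs of ≥4 consecutive bins
holding that profile — a second, independent filter. Comparisons need
≥2 trials per class; fewer leaves the pair's digits unassigned.

Choice probability is the same ROC applied to hit-vs-error rate
distributions per class over [P2 onset, button + 1.5 s]; classes with
fewer than two trials of either outcome are excluded and logged.

## Variance decomposition

Var_COD(t) = (1/N)(1/4) Σᵢ Σ_c (rⁱ(t,c) − rⁱ(t))², computed from
hit-trial class-mean PSTHs (the pseudo-population construction), and the
parameter variances use the two-group means of the P1 ({c1,c2}|{c3,c4}),
P2 ({c1,c3}|{c2,c4}) and decision ({c1,c4}|{c2,c3}) partitions with a
(1/N)(1/2) normalisation. Because the classes form a 2×2 factorial in
(P1, P2) whose interaction contrast is the decision grouping, the three
parameter variances are the orthogonal components of Var_COD and sum to
it exactly; the identity is enforced as a property test (1e−10 relative)
rather than assumed. The mean of Var_COD over the pre-P1 second is
reported with every series as the stochastic noise floor that any
coding-related excursion must exceed.

## Mutual information

Scalar responses are discretized into equipopulated (quantile) bins,
n_bins = min(8, ⌊n_trials/4⌋) by default; the plug-in information is
corrected by the first-order Panzeri–Treves bias term
[Σ_s(R_s−1) − (R−1)] / (2N ln2) with occupied-bin counts, and
significance comes from 1000 label permutations at α = 0.01.
Corrected values are floored at zero for reporting (`bits`); the raw
corrected value is retained (`bits_raw`) and is what calibration
statements about the *mean* null information refer to, since flooring
would bias that mean upward. A shuffle-subtraction control is available
behind a flag. Exact binning and bias-correction variants used upstream
of this package's design are not uniquely determined by the analysis
conventions it follows; both are configurable and echoed in
`InfoResult`.

- `I_1s`: spike count over the full 1-s stimulus period versus pattern
  identity (G/E).
- Population I(t): per bin, z-scored single-trial rates pooled across
  neurons form one response distribution per label (P1 identity,
  reported decision, or hit/error for the reward target), split by
  hits/errors where applicable; optional bootstrap 95% CIs over trials
  (1000 resamples by default in the API, fewer in tests).
- Window-width curve: time-averaged pattern information per sliding
  window width, 10–1000 ms.
- Taxonomy: sensory ⇔ significant I_Per > 0.25 bits; categorical ⇔
  significant I_1s > 0.25 bits. The thresholds are deliberately extreme
  so the two sets are empirically disjoint; a neuron passing both is
  labelled ambiguous and warned about, never silently resolved.
- Task comparison: θ = atan2(I_LCT, I_TPDT) per neuron, arithmetic mean
  over [0°, 90°] (the circular mean is indistinguishable on this
  domain); both-zero pairs are excluded.

## Periodicity

Each trial's stimulus-period train is convolved with a unit-mass
Epanechnikov (quadratic) kernel of 24-ms total width, sampled every
0.6 ms over 1228.8 ms (50 ms before to 178.8 ms after the period —
exactly 2048 samples), Fourier transformed, DC-removed, and normalised
so positive-frequency power sums to 100%. Duplicating every spike
leaves the normalised spectrum unchanged, so the measure reflects the
temporal arrangement of spikes, not their number. The frequency
resolution implied by this configuration is 1/1.2288 s ≈ 0.814 Hz; a
nominal 0.97-Hz bin width sometimes quoted for such configurations is
arithmetically inconsistent with 2048 points at 0.6 ms, and this
implementation derives the grid from the FFT length rather than forcing
either number. The two bins flanking the 4.34-Hz pattern frequency
(≈4.07 and 4.88 Hz here) are extracted; their **sum** is the scalar
trial response for I_Per (matching the single-variable form of the
information sum), with the two-dimensional variant behind the
`combine="pair"` flag. Zero-spike windows yield an all-zero spectrum
and are excluded from information estimates.

## Latencies

Response latency: 200-ms windows slide across P1 (1-ms steps by
default; tests use 10–20 ms), each compared against the per-trial basal
rate (the 200 ms before P1 onset) by permutation ROC at α = 0.05; the
latency is the first bin center opening ≥5 consecutive significant
bins. Coding latency: the same rule on the G-vs-E comparison with 10-ms
steps. Because adjacent windows overlap by ≥95%, the five "consecutive"
bins are strongly dependent and the run rule does **not** reach the α⁵
independent-bin bound: measured on flat Poisson neurons, the coding
latency false-positive rate is roughly 25% at 10-vs-10 trials while the
response latency's is near zero (the basal comparison pools twice the
trials and a chance basal/stimulus asymmetry must persist across the
whole run). Latency guarantees in the tests are therefore statistical
(bounded null rates, onset recovered within one window width), not
per-neuron absences.

## Intrinsic timescale

The basal second (−1 to 0 s) is divided into overlapping 40-ms bins at
20-ms steps; for each lag the across-trial Pearson correlation of spike
counts is averaged over all bin pairs at that lag (equal weight,
zero-variance bins skipped), per-neuron curves are averaged across the
population, and Aut(t) = A[exp(−t/τ) + B] is fit by Levenberg–Marquardt
least squares. Initialisation: A = Aut(min lag), τ = 100 ms,
B = Aut(max lag)/A, with five jittered restarts on failure. Two
numerical choices matter:

- **Lag 20 ms is excluded from the fit** (default fit range 40–960 ms).
  At a lag shorter than the bin width, overlapping bins share spikes, so
  the Poisson noise itself is correlated and Aut(20) sits far above the
  rate-modulation decay (0.56 vs 0.12 in an OU-modulated Poisson check);
  including it collapses τ by an order of magnitude. The minimum lag
  equals the bin width, i.e. the first non-overlapping separation.
- **Points are weighted by √(number of bin pairs)** entering each lag:
  long lags average fewer pairs and are proportionally noisier. With
  these choices, τ = 178 ms with 2000 trials is recovered with mean 180
  and SD 17 ms across seeds (versus SD 27 ms unweighted over 20–480 ms).

Fits are population-level only; single-neuron τ fits would need far more
trials per cell and are out of scope. A fitted τ beyond ten times the
lag range triggers a warning that the decay is unresolved (typical for
very small sessions).

## Simulator

The generator is an engineered test harness realising the response
taxonomy the analyses target; its parameters are conventions of this
package, not claims about any cortical area. Rate model per trial:

rate(t) = max(0, baseline·(1 + cv·OU_τ(t)) + λ·pulse_gain·Σ_p boxcar₍₂₀ₘₛ₎(t−t_p)
          + (1−λ)·categorical_gain·gate(t))

with OU_τ a unit-variance Ornstein–Uhlenbeck process (exact AR(1)
discretisation at 1 ms), λ the sensory↔categorical mix, and spikes drawn
as an inhomogeneous Poisson process. The E pattern places five pulses at
the 1000/4.34 ≈ 230.4-ms period; G shares E's boundary pulses with the
middle three center-grouped at half that spacing (the grouped geometry
is constrained only qualitatively by the task description; the symmetric
default is configurable). The categorical gate is archetype-specific:
pattern-preferring cells activate 150 ms after P1 onset through the
delay; class-selective cells during/after P2; decision cells follow the
*reported* choice from the comparison period on. Categorical and
decision terms are silenced in the LCT and multiplied by an error
fidelity (default 0) on error trials — so categorical information
vanishes on errors by construction, mirroring the empirical motif the
analyses are meant to detect. The sensory term is identical across
task and outcome by construction. Sessions draw ⌈15/0.84⌉ = 18 TPDT
trials per class with hit probability 0.84 (≈15 hits + 3 errors per
class) and all-hit LCT trials; defaults: baseline 10 sp/s, pulse gain
120 sp/s, categorical gain 15 sp/s, OU cv 0.3 at τ = 150 ms (timescale
probes: 20 sp/s, cv 0.5).

What the simulator does *not* emulate: correlated variability across
neurons, adaptation within pulse responses, non-Poisson spiking
statistics, drifting excitability across a session, or any biophysics.
Passing tests therefore demonstrate that the estimators recover the
constructs they define under clean generative conditions — not that
real recordings satisfy those conditions.

## Problem sizes in the test suite

The suite runs the full pipeline at reduced scale chosen as the smallest
sizes at which each statistical claim is stable: 12 neurons per archetype
for the taxonomy separation, 2000 trials for τ recovery, 200 replicates
for estimator calibration, 200–300 permutations where the test checks a
decision rather than a p-value's third digit. The API defaults remain at
the full analysis scale (1000 permutations, 1-ms latency steps).

## Known limitations

- The permutation and bootstrap loops are plain Python/numpy; a very
  large session (thousands of neurons) would want the per-bin tests
  vectorised across bins as well as permutations.
- The equipopulated binning makes I estimates invariant to monotone
  response transforms but discards within-bin structure; binless
  estimators are out of scope.
- Choice probability is computed per class and averaged; with the
  default error model only classes whose hit trials carry the decision
  term deviate from 0.5, so population CP magnitudes depend on the
  archetype mixture.
- The word classifier requires all six digits assigned before labelling
  a bin; sparse data therefore yields "unassigned" rather than a noisy
  label — by design, at the cost of coverage.
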