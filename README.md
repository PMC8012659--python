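# spikecode

Spike-train analysis of how cortical neurons encode *temporal* stimulus
patterns in a two-interval discrimination task. The package is aimed at
systems neuroscientists working with trial-aligned extracellular
recordings from pattern-discrimination experiments: a subject receives two
1-s vibrotactile pulse patterns (P1, then after a 2-s delay, P2), each
either **grouped** (G, three of five pulses center-grouped) or **extended**
(E, five pulses periodic at 4.34 Hz between pulses), and reports whether
they matched. The four pattern pairs define trial classes c1 (G-G), c2
(G-E), c3 (E-G) and c4 (E-E). A light-cued control task (LCT) uses the
same stimuli with the answer visually cued.

`spikecode` implements the complete single-neuron and population analysis
chain for such data, plus a ground-truth simulator so every stage is
testable without recordings:

- **ROC coding words** — at each time bin the six pairwise class
  comparisons are tested with the area under the ROC curve and a
  label-shuffling permutation test; the six equal(0)/different(1) digits
  (kept only across ≥4 consecutive stable bins) form a binary word. Of
  the 64 words, exactly 7 map to coding profiles: P1 identity
  `011110`, P2 identity `101101`, decision `110011`, and four
  class-selective words.
- **Variance decomposition** — the instantaneous population coding
  variance `Var_COD(t) = (1/N)(1/4) Σᵢ Σ_c (rⁱ(t,c) − rⁱ(t))²` splits
  exactly into P1, P2 and decision components (a 2×2 factorial identity).
- **Mutual information** — equipopulated-binned Shannon information with
  Panzeri–Treves bias correction and permutation significance:
  the 1-s spike-count pattern information `I_1s` and the spectral
  periodicity information `I_Per` (power near the 4.34-Hz pattern
  frequency from a 2048-point FFT at 0.6-ms resolution), which jointly
  separate phase-locked *sensory* neurons (`I_Per` > 0.25 bits) from
  *categorical* neurons (`I_1s` > 0.25 bits).
- **Dynamics** — response and coding latencies (five consecutive
  significant sliding bins), choice probability (hit-vs-error ROC), and
  the intrinsic population timescale τ from an exponential-plus-offset
  fit `Aut(t) = A[exp(−t/τ) + B]` to the basal-period spike-count
  autocorrelation.
- **Simulator** — inhomogeneous-Poisson neurons with OU-modulated
  baselines and archetype rate models (sensory, categorical,
  intermediate, decision, non-coding, timescale probes) on the full task
  timeline, with hit/error outcomes at a target performance.

## Worked example

Simulate one phase-locked and one categorical neuron and compute the two
information quantities that classify them:

```python
import numpy as np
from spikecode.simulate import SimulationSpec, default_archetype, simulate_neuron
from spikecode.periodicity import periodicity_info
from spikecode.information import info_1s

rng = np.random.default_rng(0)
spec = SimulationSpec(seed=0)
for kind in ("sensory", "categorical"):
    nr = simulate_neuron(default_archetype(kind), spec, kind, rng)
    iper = periodicity_info(nr, seed=1)
    i1s = info_1s(nr, seed=1)
    print(f"{kind:12s} I_Per = {iper.bits:.2f} bits (p={iper.p_value:.3f})  "
          f"I_1s,P1 = {i1s.bits:.2f} bits (p={i1s.p_value:.3f})")
```

```
sensory      I_Per = 0.49 bits (p=0.001)  I_1s,P1 = 0.04 bits (p=0.313)
categorical  I_Per = 0.03 bits (p=0.286)  I_1s,P1 = 0.83 bits (p=0.001)
```

The sensory neuron carries pattern identity in its spike-train
*periodicity* (high `I_Per`) but not in its total spike count — both
patterns have five pulses, so a faithfully phase-locked cell fires the
same number of spikes for G and E. The categorical neuron is the
converse: no phase-locking, but a pattern-selective rate offset that the
1-s count information picks up. The 0.25-bit line separates the two.

A shell workflow over a session directory (`trials.tsv` + `spikes.tsv`):

```sh
spikecode simulate --spec spec.yaml --out session/ --seed 1
spikecode code      --in session/ --out coding.tsv --seed 1
spikecode variance  --in session/ --out variance.tsv
spikecode classify  --in session/ --threshold 0.25 --out profiles.tsv
spikecode timescale --in session/ --out tau.json
spikecode report    --in session/ --out report/ --seed 1
```

Deposited recordings can be run through the same pipeline after
conversion to the TSV session format (columns documented in
`spikecode.data`).

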