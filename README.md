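# fbconn — filter-banked connectivity

Frequency-resolved estimation of time-varying functional network
connectivity (dynamic FNC) from component time series, for researchers who
analyse resting-state fMRI network time courses (e.g., ICA component time
series) and want connectivity dynamics *per frequency band* rather than the
single low-pass view that sliding-window correlation provides.

## The method

Sliding-window Pearson correlation (SWPC) between two series x(t), y(t)
can be rewritten as a convolution: define the per-sample normalized product

    w(t) = [x(t) − μ_x(t)] [y(t) − μ_y(t)] / [σ_x(t) σ_y(t)],

where μ and σ are windowed moments computed in a rectangular window of
length 2Δ+1 around each sample.  Convolving w(t) with that same rectangular
kernel (normalized by 1/(2Δ+1)) approximates SWPC — which exposes SWPC as a
*low-pass filter acting on the connectivity-domain signal w(t)*.  Whatever
the window size, all connectivity fluctuations faster than ≈ 1/(2Δ+1) are
discarded.

Filter-banked connectivity (FBC) replaces that implicit low-pass with a
bank of N zero-phase IIR band filters whose passbands tile [0, Nyquist]
contiguously:

    r_n(t) = h_n(t) * w(t),    n = 1 … N,

so r_n(t) estimates connectivity restricted to band n.  The default bank is
10 equal-width Chebyshev type-2 filters (≥ 30 dB stopband attenuation,
≤ 3 dB passband loss, minimal order, second-order sections, applied
forward–backward so the phase response is identically zero).  For TR = 2 s
this gives band 1 = 0.000–0.025 Hz … band 10 = 0.225–0.250 Hz.

Downstream, all subjects' banded trajectories are concatenated
(observations = subject × band × time, features = component pairs) and
clustered with k-means++ (squared Euclidean distance, best of 30 restarts;
default k = 8).  Each subject's *fraction rate* — the share of time points
assigned to each state, per band — gives every state a frequency profile,
and two groups can be compared state-by-state with Welch's t-test under
Benjamini–Hochberg FDR correction.

An oscillating-covariance simulator generates validation data: six
zero-mean unit-variance series whose pairwise correlation is
ρ_ij(t) = A_ij · cos(2π f_corr t), chained over two states, so the
connectivity has a known frequency and ±A ground-truth patterns.

## Worked example

Recover ground-truth connectivity states from a simulated scenario whose
two states oscillate at 0.01 and 0.05 cycles/sample — the second well above
the sliding-window passband (≈ 0.032 for the 31-sample window):

```python
import numpy as np
from fbconn import scenario_preset, run_toy_scenario

scen = scenario_preset("A", samples_per_state=5000, seed=1)
rep = run_toy_scenario(scen)
print("FBC matched corr :", np.round(rep["fbc"]["matched_corr"], 3))
print("SWPC matched corr:", np.round(rep["swpc"]["matched_corr"], 3))
print(np.round(rep["fbc"]["band_fraction"], 3))
```

prints

```
FBC matched corr : [0.991 0.96  0.937 0.873]
SWPC matched corr: [0.992 0.986 0.265 0.274]
[[0.182 0.109]
 [0.275 0.179]
 [0.249 0.355]
 [0.295 0.357]]
```

The four matched correlations score each estimator's clustered centroids
against the ground-truth patterns +A₁, −A₁, +A₂, −A₂.  Both methods recover
state 1 (in-band for the window), but only the filter bank recovers state 2
(0.94/0.87 vs 0.27/0.27): its oscillation was filtered away by the window.
The band-fraction rows show the frequency specificity — state-1 clusters
occupy the low band more than the high band (0.182 > 0.109, 0.275 > 0.179),
state-2 clusters the reverse.

The same pipeline runs on real data from the shell:

```
fbc design-bank --tr 2.0 --n-bands 10 --out bank.json
fbc run --config run.yaml            # estimate → filter → cluster → fractions → compare
fbc run-toy --scenario A --report toyA.json
```

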