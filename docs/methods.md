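# Methods

## Model and estimator

The package estimates time-varying functional network connectivity by
frequency tiling in the *connectivity domain*.  The connectivity-domain
raw signal for a pair of component time series is the per-sample
normalized product

w(t) = z_x(t)·z_y(t),  z(t) = (x(t) − μ(t)) / σ(t),

with μ(t) and σ(t) the windowed mean and standard deviation in a
rectangular window of length L = 2Δ+1 centred on t.  σ is the *population*
form (square root of the windowed mean squared deviation, divisor L): with
this convention the rectangular moving average of w is on the correlation
scale, and the exact per-window Pearson correlation — which we also
implement directly — is guaranteed to lie in [−1, 1].

Sliding-window Pearson correlation is (approximately) the convolution of
w(t) with the rectangular kernel; it is therefore a low-pass filter with
passband ≈ [0, 1/L] cycles/sample.  Filter-banked connectivity replaces
the kernel by N band filters tiling [0, Nyquist]; band n's output r_n(t)
estimates connectivity restricted to that band.  The two estimators agree
in the following precise sense, which we test: if the windowed moments in
w are replaced by *global* moments, the moving average of w equals the
Pearson correlation computed with those same global moments exactly; with
windowed moments the two forms agree to correlation ≥ 0.95 on pairs whose
true correlation varies smoothly.  (On pairs with *constant zero*
correlation both estimators are pure noise around zero and their mutual
correlation is attenuated; that regime says nothing about the
approximation and is deliberately not used as the agreement check.)

### Edge and degeneracy policy

All windowed quantities use valid-support truncation — no padding of the
activity series, so a trajectory sample at index t corresponds to activity
sample t+Δ and the trajectory is L−1 samples shorter than the recording.
A window with zero variance yields a missing value and a logged warning;
downstream clustering drops rows containing missing values and reports the
count, and band filtering refuses missing input outright (an IIR filter
would smear a NaN over the whole trajectory).  The windowed variance is
computed after centring each series by its global mean; the two-pass
formula otherwise cancels catastrophically and a constant series would not
be flagged as degenerate.

## Filter bank

Defaults: N = 10 equal-width bands over [0, Nyquist]; Chebyshev type 2;
stopband attenuation ≥ 30 dB; passband loss ≤ 3 dB; minimal order chosen
by `cheb2ord` (Butterworth and elliptic alternatives via their own order
selectors).  Band 1 is a low-pass, band N a high-pass, interior bands are
band-passes.  The published band edges leave stopband placement open, and
order selection needs both: stopband edges sit `transition_fraction`
(default 0.25) of the band width beyond each passband edge, clipped to
(0, Nyquist) — proportional transitions keep orders modest (5–6 per
prototype, i.e. 10–12 for band-passes).

Coefficients are stored and applied as second-order sections: stability of
high-order IIR cascades is the binding requirement, and transfer-function
polynomials of these orders are ill-conditioned.  Every designed filter is
validated at build time: all poles strictly inside the unit circle, and
realized magnitude response measured on an 8192-point grid meeting the
stopband/passband criteria within 0.05 dB (grid-discretisation slack).
Filtering is forward–backward (`sosfiltfilt`) with odd-reflection padding
of 3 × max(order, 8) samples per end, so the effective response is the
squared single-pass magnitude with identically zero phase.

Because each filter hits ≈ 3 dB at its passband edges, the squared
(two-pass) responses of adjacent bands each contribute ≈ 0.5 at a shared
edge and the band-sum reconstructs broadband input: measured relative L2
error ≈ 0.04 on white noise, asserted ≤ 0.1.  Banks built from explicit
edge lists may cover only part of the spectrum (used by the validation
scenarios, whose two bands cover [0, 0.075] of a 0.5-sample⁻¹ spectrum);
contiguity is always enforced, full coverage only for tiled banks.

## State analysis

Observations are (subject, band, time) rows with one feature per component
pair (upper triangle, i<j, row-major).  k-means++ with squared Euclidean
distance, best of `replicates` (default 30) random restarts by
within-cluster distance; defaults k = 8 for real-scale analyses, k = 4 for
the two-state validation scenarios (two states × two extreme patterns ±A).
Features are *not* scaled before clustering (raw filtered connectivity
values; scaling available as an option, default off).  Final states are
relabelled by descending overall occupancy for stable reporting.  Fraction
rates condition on (subject, band) — fractions over states sum to 1 per
subject-band — and the profile of a state's fraction rate across bands is
its frequency profile.

Centroid matching against reference patterns maximizes total Pearson
correlation via the Hungarian algorithm.  Exact ties arise in degenerate
constructions (an estimate set differing from the reference only by one
sign flip leaves many assignments with equal total); a 10⁻⁹ preference for
index-aligned matches makes the result deterministic without affecting any
non-degenerate optimum.

## Group comparison

Per-state two-sample comparison of fraction rates: Welch's
unequal-variance t-test by default (the distribution of occupancy
fractions is bounded and often skewed, so a Mann–Whitney U option is
provided and flagged to users).  Raw p-values are corrected with
Benjamini–Hochberg step-up; the family is the set of states (within band
for band-resolved comparisons).  When both groups are constant and equal
the statistic is defined as 0 with p = 1.

## Synthetic-data generator

The simulator draws X(t) ~ N(0, Σ(t)) independently per sample, with unit
diagonal and off-diagonals ρ_ij(t) = A_ij·cos(2π f_corr t); two states of
10,000 samples each (20,000 total) by default, six series, sampling
interval 1 s.  Σ(t) must be positive definite at every phase: each state
spec is validated on a dense grid of cosine values including both extremes
and rejected (not repaired — silent projection would change the ground
truth) if the smallest eigenvalue falls below 10⁻⁶.

The shipped amplitude matrices are chosen under that constraint: state 1
couples two blocks of three series (within-block +0.3, between −0.1;
Gershgorin radius 0.9 < 1) and state 2 rearranges the coupling into three
blocks of two (radius 0.7).  Stronger block amplitudes of the ±(0.6, 0.3)
kind are *not* admissible for an oscillating correlation — the block
eigenvalue 2·0.6+3·0.3 = 2.1 makes I − A indefinite at the trough phase —
which caps realistic effect sizes for this design at |λ(A)| < 1.

Scenario presets A–F differ in where the two connectivity frequencies sit
relative to the 2-band split (0.025 cycles/sample) and the window passband:

| scenario | f₁, f₂ (cycles/sample) | regime |
|---|---|---|
| A | 0.010, 0.050 | separate bands; state 2 above window passband |
| B | 0.005, 0.020 | both inside window passband |
| C | 0.040, 0.060 | both above window passband, same band |
| D | 0.010, 0.060 | separate bands, wider gap |
| E | 0.003, 0.010 | both well inside window passband |
| F | 0.050, 0.065 | both above window passband |

All presets use the 31-sample window (Δ = 15, passband ≈ 0.032).  An
11-sample window would widen the passband to ≈ 0.09, but at amplitude 0.3
the per-window sample Pearson estimator is then dominated by its own
sampling noise and fails to recover even in-band states — the classical
lower bound on window size for sample correlation — so "SWPC succeeds"
scenarios are realized by placing both frequencies inside the 31-sample
passband rather than by shortening the window.

What the generator does *not* emulate: hemodynamic convolution, fMRI noise
spectra and artefacts, inter-subject variability, and non-sinusoidal or
asymmetric connectivity oscillations.  Passing recovery tests therefore
demonstrates that the estimator separates and recovers band-limited
connectivity dynamics under the stated covariance model — not performance
on real fMRI.

## Problem sizes and numerical choices

The recovery suite runs each scenario at 5,000 samples per state over five
fixed seeds with 10 k-means restarts — sizes chosen so the whole suite
completes in well under a minute while leaving wide margins on the 0.8
recovery thresholds (measured means 0.83–0.95 for the banded estimator
out-of-band, 0.96–0.98 for windowed correlation in-band).  Tolerances:
windowed-moment oracle agreement 10⁻¹²; BH step-up vs enumeration 10⁻¹²;
realized filter specs within 0.05 dB of design; band-sum reconstruction
≤ 0.1 relative L2; symmetric-matrix vectorization tolerance 10⁻¹⁰.

## Known limitations

- Chebyshev-II stopbands guarantee 60 dB two-pass attenuation at DC, not a
  null: high-passed series retain an O(1/n) mean from edge transients.
  The Butterworth family provides an exact DC zero when that matters.
- Fraction-rate comparisons assume exchangeable subjects; no covariate
  adjustment (site, motion) is provided.
- Per-subject trajectories are filtered independently; filtering must not
  cross subject boundaries, so very short recordings lose proportionally
  more support to the window and to filter padding requirements.
- No dwell-time or transition statistics, and no alternative clusterings.
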