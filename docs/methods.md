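# Methods

`psgstats` implements a within-subject sleep-EEG analysis for trauma-film
designs: each participant sleeps once after an aversive film and once after a
neutral film; per-electrode sleep measures are computed for each night;
intra-individual change scores (trauma − neutral) are related to autonomic
reactivity during the film and to behavioural outcomes in the following week.
Because no public dataset accompanies this design, the package ships a
synthetic-data module that generates complete cohorts with recorded ground
truth; every statistical guarantee quoted below is demonstrated on that
generator, not on human data.

## Measurement chain

**Preprocessing.** Recordings (64 EEG channels + mastoids, 500 Hz) are
re-referenced to the mean of both mastoids, high-pass filtered at 0.1 Hz, and
bad channels are replaced by inverse-squared-distance weighted averages of
the remaining EEG channels. The filter is a 2nd-order Butterworth applied
forward–backward (zero phase); the paper's original processing does not pin
down the filter family or interpolation rule, so these are the package's own
commitments, chosen to be simple and exactly testable (spherical-spline
interpolation is deliberately out of scope).

**Spectra.** Within each maximal contiguous run of artifact-free scored
epochs of the requested stage set (N2+N3 or REM), 8.192-s windows are placed
at 50% overlap from the run start, so no window straddles a stage boundary
or an artifact-flagged 30-s epoch. Windows are Hann-tapered, Fourier
transformed, converted to power and averaged; the grid spacing is
fs/4096 = 0.1220703125 Hz, reported up to 30 Hz. Normalisation is
amplitude-correct (coherent-gain compensation, `2|X|²/(Σw)²`): a unit
sinusoid contributes 0.5 µV² at its bin regardless of the window. Band power
is the unweighted mean over bins whose *center* lies inside the closed band
interval — SWA 0.5–4 Hz, theta 4.25–8 Hz, spindle 12–16 Hz — so the
4.25-Hz theta edge excludes every SWA bin.

**Sleep cycles and SWA slope.** Cycles follow modified Feinberg rules: a
NREM period is an N2/N3 run of ≥ 15 min tolerating interruptions < 5 min,
terminated by a REM period of ≥ 5 min (no minimum for the first REM period).
The SWA slope of the first cycle is the OLS slope of per-30-s-epoch SWA
(mean over that epoch's six 8.192-s sub-windows) against epoch index. The
original study's slope formula lives in an unavailable supplement; the OLS
definition here is a declared stand-in, and the generator plants a known
within-cycle power ramp so the recovery error (< 20%) is testable.

**Spindles.** Per channel: zero-phase 12–16 Hz band-pass (4th-order
Butterworth), RMS envelope with a 200-ms sliding window, threshold at
mean + 1.5 SD of the envelope over all artifact-free N2/N3 samples of that
channel, supra-threshold runs merged across gaps < 100 ms, kept when their
duration lies in 0.5–3 s. Thresholds are per-channel (channel-wise amplitude
differences are absorbed into the criterion). Summary metrics per night:
event count, density per artifact-free N2+N3 minute, and "envelope" = mean
over events of the per-event envelope maximum (reported as missing, never
zero, when there are no events).

*Detector operating characteristics.* With events planted at 3× the
background envelope, this parameter set recovers roughly 80% of events with
~90% precision (±0.25-s onset tolerance). Three effects bound it: the
threshold is estimated from the envelope *including* the events, so at
realistic densities (~5/min, ~10% coverage) it self-inflates by ~30%; true
0.5–0.75-s events produce supra-threshold runs that fall under the 0.5-s
duration floor; and beating between the event carrier and in-band background
occasionally splits or delays the supra-threshold run. Recovery above 90/90
requires ~4× SNR under this parameter set. The constants are exposed in the
API, but the defaults are fixed and are not tuned per dataset.

## Inference

**Cluster-based permutation tests.** Channel-wise statistics are thresholded
at a sample-level α = 0.05; adjacent supra-threshold channels of common sign
(adjacency: distance rule on the montage, threshold auto-chosen for a mean
degree ≈ 6, or a 2-D Delaunay triangulation) form clusters scored by their
summed t-values. Cluster p-values come from the permutation distribution of
the maximum cluster-mass magnitude, which controls the familywise error over
the map.

* *Paired contrast*: per-channel paired t on trauma − neutral; the null
  flips each subject's difference sign (exchangeable under no condition
  effect). Zero-variance channels are dropped with a warning.
* *Correlation variant*: per-channel Spearman ρ between change scores and a
  behavioural vector, mapped to `t = ρ√((n−2)/(1−ρ²))` so both variants
  share one thresholding scale; the null permutes the behavioural vector.
  Average ranks handle ties, making the test invariant to monotone
  transforms of either variable. One-sided tests cluster only the
  hypothesised sign (increases in oscillatory activity → fewer intrusions /
  less negative affect: left tail; film heart-rate reactivity → stronger
  sleep response: right tail).

Monte-Carlo p-values use the `(1 + b)/(B + 1)` estimator (valid, minimum
p = 1/(B+1)). When the full permutation group is enumerated (`exact=True`,
sign flips up to n = 14, y-shuffles up to n = 8) the estimator switches to
`b/B` because the identity permutation is already a member of the group;
both paths are verified against brute-force enumeration oracles in the
tests.

**Cluster characterisation.** For each significant cluster, power is
averaged over the cluster's channels per subject and correlated with the
outcome (Spearman); a 95% percentile bootstrap over subjects (1000
iterations) gives the CI. The CI is suppressed below n = 4.

**Multiple testing.** Four sleep measures are tested per behavioural
outcome; the per-outcome families are corrected with Storey q-values.
π₀ = min(1, max(1, #{p > λ})/((1−λ)m)) with λ = 0.5 by default; the
numerator floor prevents a degenerate π₀ = 0 in families as small as m = 4
(with λ = 0 the procedure reduces exactly to Benjamini–Hochberg, which the
tests verify against statsmodels).

**Power analysis.** The a-priori sample size for a one-sided correlation
test uses the exact sampling density of the Pearson correlation under a
bivariate-normal alternative (Gaussian-hypergeometric form, integrated
numerically), not the Fisher-z approximation; the required n is the smallest
n ≥ 4 whose power reaches the target. This exact-distribution choice
reproduces the planning range n = 18 (ρ = 0.56) to n = 26 (ρ = 0.47) at
α = 0.05, power 0.80, and is cross-checked against a Monte-Carlo oracle.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
EEG morphology. Defaults describe the modelled study: 22 subjects, 64-channel
cap (sunflower-spiral layout plus mastoids), ~474-min nights, 90-min cycles
with stage targets N2 56% / N3 14% / REM 21%, intrusion counts with mean
2.24 over six days, and 12-min film heart-rate series with the trauma
elevation confined to minutes 7–9 (1-based).

* **Hypnograms** come from a cycle-scaffolded bout model: REM share grows
  and N3 mass decays geometrically (×0.55 per cycle) across the night; brief
  W/N1 bouts interrupt the NREM blocks; ~2% of epochs carry artifact flags.
* **EEG** is 1/f^χ background (χ = 1.3, 10 µV RMS, flat below 0.5 Hz) plus
  stage-gated oscillations: a ~1.22-Hz slow oscillation in N2/N3 whose
  epoch-wise band power follows `base + slope·j` within each cycle's NREM
  period and decays ×0.7 per cycle (gating covers N2 *and* N3 — an N3-only
  oscillation would make the planted slope unrecoverable by the slope
  definition above); a ~6.1-Hz REM oscillation scaled by a per-subject ×
  condition theta gain; and Poisson spindle bursts (uniform 12–16 Hz
  carrier, 0.5–2 s, flat-top envelope with 0.1-s raised-cosine ramps) placed
  entirely inside artifact-free N2/N3 and returned as exact ground truth.
  Component frequencies sit on the analysis grid so planted band powers are
  recovered without leakage corrections.
* **Behaviour** is tied to the per-subject sleep-effect latents through a
  Gaussian copula. For continuous outcomes the latent correlation is
  2·sin(πρ_s/6); for intrusion counts the Poisson discretisation's ties are
  handled explicitly: the population grade (mid-rank) correlation between
  the latent and the count is computed by numerical integration and inverted
  by root-finding, so the *sample* Spearman matches the planted target in
  expectation (verified to ±0.03 over 100 cohorts of n = 200). Several
  associations may share one outcome as long as their latent correlations
  are jointly feasible.
* **Two signal modes.** `signal_mode="eeg"` synthesises waveforms and is
  used to validate the full measurement chain; `signal_mode="maps"` draws
  the per-channel band-power and spindle-metric maps directly from the same
  generative parameters (log-normal measurement noise, Poisson counts),
  making many-seed simulations affordable. The tests confirm the two modes
  agree in the statistics that matter (rank ordering of planted effects).

What the generator does *not* emulate: K-complexes, eye movements, muscle
artifacts, volume conduction, spatially correlated noise, non-Gaussian
backgrounds. Passing tests therefore demonstrate the correctness and
calibration of the *pipeline*, not detector performance on real
polysomnography.

## Problem sizes used in the test-suite simulations

Waveform tests run on 4–8-channel caps and 45–90-min nights (the spectral
and detection arithmetic is identical at any scale); statistical
calibrations run at the study scale (n = 22, 64 channels) in map mode:
200 null datasets for type-I validity (permutations reduced to 500), 50
seeds for association recovery, full-group enumeration up to n = 7 for the
oracle comparisons. These sizes are the package's choices for routine runs;
all are parameters, not constants.

## Known limitations

* The spindle detector's 90/90 recovery target at 3× SNR is not met by the
  committed parameter set (see operating characteristics above); the
  acceptance test records this honestly rather than relaxing the detector.
* The EDF writer covers the classic 16-bit layout (one gain per channel,
  1-s records) — enough for round-tripping synthetic cohorts, not a general
  EDF+ implementation.
* Cycle segmentation rules (15-min NREM, 5-min REM, 5-min gap tolerance)
  are conventions; nights with unusual architecture may segment differently
  than a human scorer would.
* Listwise exclusion is applied per analysis when subjects miss data; no
  imputation is attempted.
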