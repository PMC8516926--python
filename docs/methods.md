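# Methods

`arousaldyn` implements an analysis chain linking phasic BOLD bursts in two
subcortical arousal nuclei — the noradrenergic locus coeruleus (LC) and the
cholinergic basal nucleus of Meynert (BNM) — to cortical travelling waves,
time-resolved network integration, and a mean-squared-displacement (MSD)
energy landscape of cortical BOLD dynamics. Every stage can be exercised on
synthetic cohorts with planted ground truth, which is how the package
validates itself.

## Signal conditioning

The raw LC and BNM region means are residualized against nuisance series
(fourth-ventricle CSF, a pontine control region) by ordinary least squares
with an intercept, band-pass filtered to 0.01–0.15 Hz, and z-scored. The
filter is a 4th-order Butterworth applied forward–backward
(`scipy.signal.sosfiltfilt`): the band edges are the analysis contract, and
zero-phase filtering is required because every downstream analysis is a lag
analysis. Nuisance regression precedes filtering. The analysis series are
the contrast τ_LC−BNM = z(τ_LC) − z(τ_BNM), its negation τ_BNM−LC, and the
sum τ_LC+BNM. Z-scoring before differencing makes the contrast independent
of ROI scaling; since all detection thresholds are in s.d. units the choice
does not move detections, only absolute amplitudes.

## Phasic event detection

A burst onset t0 must satisfy three criteria on the series being detected:
(1) its second temporal derivative (central difference; endpoints invalid)
is ≥ 2 s.d. above the mean acceleration; (2) at least one sample of the
series in the following 10 TR reaches ≥ 2 s.d. above the series mean;
(3) t0 avoids the first and last 20 TR. Both thresholds, the sustain
window and the boundary are parameters. Candidates are pruned to local
maxima of the raw acceleration. Because that peak set does not depend on
the thresholds, the detected sets are nested as thresholds rise, making
event counts provably monotone across the 0.5–2.5 s.d. sweep — a property
the more obvious "one event per run of consecutive qualifying samples"
rule does not have (runs can split at higher thresholds).

The sustained-elevation criterion is read as an existence condition: an
"all samples for 10 TR" reading finds almost nothing at 2 s.d. and is
incompatible with the intended ~2–3 events per 10-minute run.

## Travelling wave

For each parcel, the lag of the peak Pearson correlation between the
arousal contrast and the parcel series — computed only inside the 10 TR
windows after each detected burst, pooled across events — gives a
time-to-peak latency; a parabolic refinement of the three points around
the integer-lag peak yields sub-TR resolution, which matters because a
0.3 m/s wave spans under one TR across the whole cortex. Lags run from
−3 to +10 TR: the detected onset (an acceleration peak) trails the neural
onset by 1–2 TR, so genuinely causal responses can appear at small
negative lags relative to it, and clipping them at zero compresses the
latency map.

Two estimators are provided. `event_locked_time_to_peak` is per subject.
`cohort_time_to_peak` pools the event windows of all subjects before
taking the peak; this is the group estimator, because averaging
per-subject latencies biases the latency range toward zero (per-subject
peaks jitter against the lag floor) and inflates velocity by ~30% at
default noise levels.

Velocity is the inverse absolute slope of a Theil–Sen regression of
latency (s) on the anterior–posterior MNI coordinate y (mm), converted to
m/s. The robust slope resists parcels whose latency is off-wave.
`direction_sign = +1` means latency grows toward posterior cortex
(anterior→posterior propagation). A slope below 1e−6 s/mm flags the
velocity as undefined rather than reporting an astronomically fast wave.

## Time-resolved connectivity and modularity

Coupling is the multiplication of temporal derivatives (MTD): first
differences per parcel, each normalized by its own derivative s.d. over
the full run, multiplied pairwise and averaged in sliding windows
(default w = 20 TR). The normalization makes identical series couple at
~1; it is part of this package's MTD contract.

Community structure maximizes the signed modularity

    Q = (1/v⁺) Σ_ij (w⁺_ij − γ e⁺_ij) δ(M_i,M_j)
      − (1/(v⁺+v⁻)) Σ_ij (w⁻_ij − γ e⁻_ij) δ(M_i,M_j),

with per-layer strength-product nulls e_ij = s_i s_j / v and the
resolution parameter γ scaling both null terms (the standard placement;
the γ sweep requires γ somewhere, and scaling the null is the convention
that reduces to Newman–Girvan at γ = 1). The optimizer is a Louvain-style
greedy algorithm on the signed modularity matrix (node moves to the best
community, then community aggregation, until no gain); it is written
in-package because no installed library provides signed, γ-scaled
modularity, and it is tested against a brute-force double-sum oracle at
1e−12. Consensus clustering runs the heuristic `runs` times (default 500),
forms the co-assignment matrix, subtracts τ = 0.5 and reclusters
iteratively until all runs agree.

The participation coefficient PC_i = 1 − Σ_s (κ_is/κ_i)² is computed on
positive weights with the diagonal ignored; isolated nodes get 0. Mean PC
across parcels is the integration index; its lagged correlation with the
arousal contrast (windows aligned by their centres) and the one-sided
right-vs-left hemisphere permutation test operate on these PC time
courses.

## Energy landscape

From each reference onset t0, MSD(t, t0) is the mean over parcels of
(x[t0+t] − x[t0])² for lags 1…15 TR. Pooled samples per condition
(LC bursts, BNM bursts, joint bursts, block-resampled baseline) feed a
per-lag Gaussian KDE with fixed bandwidth h = 4 MSD units, evaluated on a
0–50 grid at step 0.5, and the energy is E = −ln P with T = Z = 1. The
kernel is an explicit normalized Gaussian: each per-lag density
integrates to one over the real line (the truncated display grid holds
less than unit mass). Cells whose density falls below a floor of
0.01/(n·h) — roughly a single kernel evaluated three bandwidths away —
are capped and flagged, and flagged cells are excluded from contrasts and
from the decomposition.

Subjects are standardized to a common reference amplitude before
displacement: z-scored per parcel, then scaled to σ = 4. Pure unit
variance would bound per-parcel displacement variance by 4 and leave the
canonical 0–50 grid essentially empty; σ = 4 keeps pooling scale-free
while placing typical resting displacements mid-grid, so tail effects
(flattening/deepening at MSD 20–50, averaged over lags 10–15) are
measurable. The grid step of 0.5 is insensitive with h = 4 (halving the
step changes the KDE by < 1e−3).

The joint landscape is decomposed as E_LC+BNM ≈ αE_LC + βE_BNM by
non-negative least squares over all jointly unflagged grid cells
(`scipy.optimize.nnls`); a sum-to-one renormalization is available but
not applied by default.

## Null models

Significance is always assessed by re-evaluating the statistic at random
non-event onsets: uniform draws over per-subject indices that respect the
20 TR boundary and stay ≥ 10 TR from every detected event (half the
21 TR analysis window — the minimal reading of "not substantially
overlapping"). Statistics are evaluated on contiguous windows around
these onsets, which is what preserves temporal autocorrelation under the
null. Pseudo-event sets match the observed event count. CIs are the
2.5th/97.5th percentiles over (default) 5000 resamples; calibration
checks use 500 resamples per CI, enough for ≥ 12 samples beyond each
tail, which empirically restores nominal ~95% coverage where 300 was
visibly narrow. The one-sided permutation test uses strict exceedance
with add-one smoothing, p = (1 + #{diff > observed})/(n_perm + 1), so a
perfectly separated contrast attains the 1/(n_perm+1) floor.

## Event-locked (FIR) analysis

For behavioural events (meditation button presses; TR taken from the
cohort manifest, 1.5 s for that dataset), the response of a signal
(arousal contrast, TR-to-TR MSD, mean PC) is the coefficient vector of an
OLS regression on 2L+1 lagged event indicators plus an intercept
(L = 5 by default). For isolated events this equals the event-locked
average minus the off-event baseline — asserted to 1e−10 in tests.
TR-to-TR MSD is exactly lag 1 of the MSD machinery with every time point
as reference. Null CIs re-fit the FIR at block-resampled pseudo-press
sets.

## Synthetic cohorts

The generator plants every effect the pipeline measures, at the scale of
the study design it emulates: 12 subjects, 1000 TR at TR = 0.586 s,
400 parcels, ~0.25 bursts/min per channel (plus joint bursts), a
0.13 m/s anterior→posterior wave, four modules with within/between
correlations 0.6/0.05 rising to 0.30 for 10 TR after LC-type bursts.

* **Noise** is synthesized in the frequency domain: random phases on the
  0.01–0.15 Hz rfft bins with power ∝ f^−2.5, zero elsewhere — band
  limits hold exactly, with no filter transients. The steep in-band slope
  encodes the design premise of acceleration-based burst detection: the
  background is slow drift, and sharp transients belong to bursts. A flat
  in-band spectrum (exponent 0 is available) puts so much curvature into
  the background that HRF-shaped bursts of any plausible amplitude are
  not acceleration-salient, and planted events become unrecoverable.
* **Bursts** follow a Poisson process thinned to ≥ 21 TR separation (so
  ±10 TR analysis windows never overlap) and enter the subcortical
  channels as canonical double-gamma HRFs (peak ~5 s, undershoot ~15 s).
  `burst_amplitude_sd` is calibrated so the *deterministic* conditioned
  response peaks at that many s.d. of the contrast (or sum) series — a
  fixed-point iteration against the same conditioning the detector uses,
  making the amplitude unit exactly the unit the thresholds are stated
  in. A fourth-ventricle-like nuisance is mixed into the LC channel
  (0.4 by default) to exercise residualization.
* **The wave** adds, per LC-type burst, an HRF to every parcel delayed by
  (distance along the wave axis)/velocity, evaluated at continuous
  (sub-TR) delays on a known 3-D coordinate grid spanning 140 mm
  anterior–posterior.
* **Integration** is modulated through a time-varying global-factor
  loading: between-module correlation rises from 0.05 to 0.30 for 10 TR
  after LC-type bursts, with per-window weights chosen to keep unit
  variance (feasible whenever between ≤ within ≤ 1, validated at
  construction).
* **Landscape effects** come from `post_event_variance_scale`: cortical
  fluctuations scaled by √s for 15 TR after LC-type bursts (s = 2 plants
  flattening, s = 0.5 deepening).

What the generator does **not** emulate: spatial haemodynamic smoothness,
motion and physiological artefacts, scanner drift, inter-subject
anatomical variability, non-Gaussian burst amplitude distributions, and
any coupling between the wave and the modular structure. Passing
parameter-recovery tests therefore shows the estimators are correct under
the stated generative assumptions — not that real data satisfy them.

## Numerical choices and degenerate inputs

Zero-variance series make the detector return an empty set with a
warning; zero-variance derivative channels propagate NaN couplings; a
latency map with |slope| < 1e−6 s/mm flags velocity as undefined; the
permutation test refuses empty groups; an exhausted null pool warns and
samples with replacement; consensus ties are resolved by seeded RNG order
and a fixed 0.5 co-assignment threshold; landscape cells under the
density floor are flagged rather than extrapolated. All randomness flows
from explicit integer seeds; per-subject seeds derive from the cohort
seed via `numpy.random.SeedSequence` and stay below 2³¹.

## Problem sizes used in validation

The acceptance-style suite runs the full default scale: one 12-subject
cohort for detection/NNLS/monotonicity, three cohorts for velocities
{0.05, 0.13, 0.3} m/s, twenty 4-subject cohorts for the directional
landscape sign test, three subjects × 500 Louvain runs for module
recovery, and 200 simulations × 500 resamples for CI coverage. The whole
suite completes in about a minute on one CPU.
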