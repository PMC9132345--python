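# Methods

This note documents the models, conventions, and numerical choices behind
`spiketypes`, and what the synthetic benchmark does and does not show.

## Data model

Spike times are stored in seconds relative to stimulus onset; a trial span
covers `[-prestim, duration + posttrial]` with a 200 ms prestimulus epoch by
default.  All windows are half-open `[t0, t1)`, which makes spike counts
exactly conserved under any partition of a trial.  On disk, times are
quantized to 1 µs (well below the ~41 µs sample period of a 24.414 kHz
recording), so a write/read cycle is an exact round trip.

## Spike-timing features

**ISI histograms** use 0.2 ms linear bins or 0.1-wide bins of the natural
log of the ISI in milliseconds.  The ln(ms) convention is pinned by two
Poisson anchors: a 50 spk/s train has its log-ISI mode at ln(20) ≈ 3 and a
1 spk/s train at ln(1000) ≈ 7 (the analytic mode of the log-transformed
exponential density is the log of its mean).  Binning is by integer index
with a ~10⁻⁶-bin epsilon so that ISIs that are exact bin-edge multiples
(common after on-disk quantization) land in the bin whose left edge they
equal.

**ISI peak** is the mode of the log-ISI histogram restricted to < 80 ms;
the truncation avoids secondary peaks created by the log transform and by
the trial repetition period.  Ties break toward the shorter ISI, which is
conservative in the direction of detecting bursts.  A minimum of 50
intervals is required for all ISI-shape features.

**logISIdrop** contrasts the smoothed log-ISI histogram's maximum over
1–5 ms with its mean over 10–16 ms (5 bins):
`(max − mean)/(max + mean)`.  Smoothing is Savitzky–Golay with a 5-bin
window and degree 3 applied to the full histogram; smoothed counts may go
negative, which can push the score slightly beyond [−1, 1].

**Autocorrelogram metric (ACM)** compares mean autocorrelogram height below
8 ms against 35–80 ms, `(R̄(0,8) − R̄(35,80))/(R̄(0,8) + R̄(35,80))`, with the
gap between the ranges avoiding a possible gamma-band peak.
Autocorrelograms count ordered pairs at positive lags in 0.2 ms bins,
within contiguous segments only (never across trial boundaries), self-pairs
excluded.  The bin means are simple means over the stated lag ranges.

**Intraburst frequency** is the inverse of the linear ISI-histogram peak
(so a 1.3 ms peak reads 769 Hz), and bursts are maximal runs of consecutive
ISIs within [0.5, 1.5]× the ISI peak, with length counted in spikes.  The
percentage of ISIs < 5 ms is also reported normalized by the Poisson
expectation `100·(1 − e^(−r·0.005))` with `r = 1/mean(ISI)` — the rate is
estimated from the mean ISI rather than from counts over a window so the
measure is window-free.  Regularity is `Var[ISIₙ/(ISIₙ + ISIₙ₊₁)]`, zero
for a perfectly periodic train.

**Hartigan's dip statistic** is implemented directly (no third-party dip
package is used): the iterative greatest-convex-minorant /
least-concave-majorant narrowing of the modal interval, operating on the
ECDF with duplicate values collapsed.  The implementation reproduces the
exact small-sample values (dip = 1/4 for a two-point sample; 1/(2n) floor
for unimodal data) and is calibrated by a seeded bootstrap under the
uniform null (≥ 2000 replicates), which is also how p-values are computed.
Because the observed statistic and the null are computed by the same code,
the p-value is internally consistent even where conventions at the modal
interval could differ by O(1/n) from other implementations.

## Waveform features

Snippets are zero-phase filtered (forward–reverse application of a
256th-order FIR).  A literal 1 Hz low edge is far below what 257 taps can
resolve at 24.4 kHz, so the filter is designed as a flat 10 kHz lowpass
with an exact spectral null at DC imposed by subtracting a Hann-shaped
kernel carrying the DC gain; in-band gain stays within 1% above a few
hundred hertz while constants are removed exactly.  Snippets shorter than
the 256-sample warm-up are rejected.

Isolated spikes (no neighbor within −5/+6 ms for averaging, −10/+6 ms for
spectra) are aligned on the largest absolute first difference of the
filtered snippet (lightly smoothed over 3 samples so broadband noise cannot
dominate the slope estimate; ties break earliest) and averaged; at least 5
snippets are required.  Alignment is quantized to whole samples, so when
the true slope maximum falls midway between samples, the average blurs by
up to one sample on steep slopes — the tests account for this explicitly.

`t_TTP` runs from the global trough to the next local maximum.
Half-amplitude duration is measured at 50% of trough depth relative to a
1 ms pre-spike baseline (ending 0.5 ms before the trough) on a 10×
cubic-spline interpolation.  `f50` is the high-side frequency where the
baseline-subtracted amplitude spectrum of a 5 ms Hann-windowed spike
segment falls to half its peak, the peak being searched above 400 Hz; the
5 ms segment length, Hann window and 4× zero-padding are this package's
choices (validated through the monotonicity of f50 in spike width and the
t_TTP ≈ 0.5 ms ↔ f50 ≈ 2 kHz correspondence), since only the isolation
windows are externally constrained.

## Unit classification

Criteria run sequentially: bursting first (all three of ISI peak < 10 ms,
ACM > 0.5, logISIdrop > 0.2; exactly two of three leaves the unit
unclassified), then the prestimulus check (prestimulus logISIdrop > 0.3
labels PBu; a nonbursting-but-PBu unit is "bursting ambiguous" and is not
considered for RS/FS), then RS/FS by two-of-three
(t_TTP ≷ 0.5 ms, f50 ≷ 2 kHz, spontaneous rate > 5 or < 3 spk/s).
Bursting units split into Bu1/Bu2 at 500 Hz intraburst frequency
(> 500 → Bu1), or alternatively by a 2-component GMM on intraburst
frequency, logISIdrop and latency.

The unsupervised route standardizes 8 features (ACM, ISI peak, logISIdrop,
%ISI < 5 ms, spontaneous rate, f50, max burst length, max firing rate),
log-transforming any with |skewness| > 2 (offset = half the minimum
positive value when zeros are present), projects onto 3 principal
components, and fits full-covariance Gaussian mixtures, taking the best of
20 seeded initializations by AIC at each candidate component count 1–7.
Model selection reports AIC, BIC and the mean held-out negative
log-likelihood over 50 half/half splits.  Prediction uses the 3-component
model and assigns a unit only when its posterior is at least twice each
other posterior.  Components map to types by their centroids in feature
space: highest ACM centroid → Bu, highest spontaneous-rate centroid among
the rest → FS, remainder → RS.  The |skewness| > 2 threshold and the
complete-case policy for the GMM stage are this package's operational
choices where only qualitative guidance exists.

## Response metrics

PSTHs are 1 ms-binned and convolved with a σ = 5 ms Gaussian, with
truncated-kernel renormalization at the edges so integrated counts are
conserved to < 0.1% for interior spikes.  The response window is
[onset + 10 ms, offset + 50 ms), extended to offset + 150 ms for
vocalizations.  Rate responsiveness requires the driven rate to exceed the
prestimulus mean plus 3 standard errors with the variance rescaled by
T_pre/T_resp (longer windows average down the variance); the instantaneous
test Bonferroni-corrects the Poisson tail probability of the maximum 5 ms
bin (λ̂ from the spontaneous rate; a floor of 0.5 expected counts avoids a
degenerate p when the prestimulus is silent).  Both tests are excitatory
only.

Vector strength excludes the first 50 ms of the response so onset bursts do
not masquerade as phase-locking; significance is Rayleigh 2NVS² strictly
greater than 13.8 (p < 0.001 under uniform phases; the comparison carries a
10⁻⁹ relative epsilon so a value mathematically equal to the criterion
never passes through float noise), and nonsignificant VS report as 0.
`f_max` interpolates the Rayleigh statistic in log₂ frequency (the tested
rates are octave-spaced) between the highest significant rate and the next,
to the 13.8 crossing.  tBMF is the VS-weighted geometric mean of the peak
reported VS and each significant immediate neighbor, requiring at least two
significant rates.  Onset latency — for which no standard recipe exists —
is the first post-onset time at which the smoothed PSTH exceeds the
spontaneous mean + 3 SD, minimized over responsive stimuli; it is a
documented stand-in used only as a descriptive feature.

## Correlation index

The shuffled autocorrelogram counts all-order spike-time differences
between distinct repetitions (within-trial pairs excluded, removing
refractory and intrinsic-burst structure).  The CI normalization is
`CI(ω) = N_c(ω)/(M(M−1) r² ω D)` with coincidences `|Δt| ≤ ω/2` counted as
ordered pairs, `r` estimated from the analyzed window itself
(spikes/(M·D)), and `D` the analysis-window duration.  The convention is
pinned by the requirement that a homogeneous Poisson responder has CI ≈ 1 —
verified by simulation — since several coincidence/normalizer pairings are
self-consistent.  The window grid is ω_k = 10^(k/10) ms over 0.05–5 ms, and
the unit-level CI averages the 5 grid windows flanking 0.5 ms.  No
edge-effect correction is applied (ω ≪ D makes it negligible).  CI_max is
the maximum over responsive vocalization stimuli.

## Victor–Purpura decoding

The distance is computed by the standard dynamic program (verified against
exhaustive matching enumeration on small trains).  Responses are cropped to
a segment equal to the shortest stimulus duration, centered on the peak of
a Gaussian kernel density estimate (σ = 20 ms — the bandwidth is this
package's choice) of the pooled response and clipped to the stimulus
window.  Classification is leave-one-out: the per-stimulus distance is the
z = −3 power mean over the other repetitions, with any zero distance
collapsing that average to 0 (the transformation's documented distortion,
applied literally); ties tally 1/k.  Performance is the transmitted
information of the confusion matrix.  The shuffle null (100 label
permutations) is evaluated at the unit's best q, reusing the distance
matrices; units with z > 3 are flagged for pooling.  The q grid is
{0, 1, 2, 4, …, 4096}/s (octave-spaced above 1).

## Population decoding

Responses to the vocalization list are binned in nonoverlapping windows
(10 ms default) over [0, shortest stimulus + 300 ms) — short stimuli
contribute poststimulus bins, equivalent to zero-padding.
Pseudopopulations sample units without replacement (compositions: Bu-only,
RS-only, or a mixture at the observed 110:54 ≈ 2:1 RS:Bu prevalence); each
unit independently contributes one randomly chosen left-out repetition per
stimulus as its test trial, and class templates average the remaining
repetitions.  The MCC decoder assigns the class template with the highest
Pearson correlation (zero-variance and tie cases resolve seeded-random);
the LDA decoder uses shrinkage-regularized pooled covariance with a uniform
prior, with training pseudo-trials formed by pairing each unit's k-th
non-left-out repetition.  `avg_time` collapses each unit to its mean over
bins (rate code); `avg_units` averages across units per bin (pooled
temporal code).  Accuracy is the diagonal mass fraction of the confusion
matrix pooled over 50 draws (the pattern tests use 25 draws).

## Synthetic benchmark

The generator emulates the statistical structure the analyses assume, not
any particular recording:

* Spiking is inhomogeneous Poisson by thinning with an 0.8 ms dead time
  (candidate intensity corrected by 1/(1 − λρ) so realized rates match
  their targets).  Bursting units are a two-stage process — burst *events*
  form a point process with a dead time long enough that bursts do not
  interleave, and each event expands with probability 0.85 into 2–4 spikes
  at the phenotype's intraburst interval (3% dispersion) — so burst timing
  is sporadic rather than oscillatory and intraburst frequency is an
  explicit parameter.  Spontaneous events continue through the prestimulus
  epochs, which is what makes the prestimulus burst score meaningful.
* Drive has a transient component proportional to a power of the rectified
  envelope derivative (rising-slope preference; it does not adapt) and a
  sustained component proportional to the envelope multiplied by an
  exponential adaptation profile.  Bu1 is pure slope drive (hence
  onset-dominated responses to flat stimuli and early-cycle phase-locking
  to SAM), Bu2 mixes both, RS/FS are envelope-driven.  Driven components
  carry a response latency (8–18 ms by type) and per-spike/per-event
  Gaussian jitter (1.2 ms for Bu1 up to 10–15 ms for RS) that sets each
  type's temporal precision.
* Vocalization stand-ins are sums of sharp-attack/exponential-decay events
  (optionally with a 30 Hz trill sub-modulation).  Each unit applies a
  per-stimulus gain (lognormal, sparser for more selective phenotypes) and
  a smooth random temporal weighting (~150 ms knots), so that which units a
  stimulus recruits and when they fire both carry information — without
  the weighting, population responses would be rank-1 in (unit × time) and
  the pooled-unit control could not degrade decoding.  A mean-one lognormal
  per-trial gain (σ = 0.35) models trial-to-trial response variability.
* Waveforms are calibrated biphasic templates (trough-to-peak 0.3–0.7 ms
  by type, spanning the 0.5 ms boundary; the 0.5 ms template's f50 falls
  near 2 kHz) with additive noise at a realistic single-unit SNR.

Default rates (RS 1 spk/s spontaneous / 60 spk/s driven; FS 12/55; Bu
event rates 1.6 spontaneous, 130 (Bu1) and 32 (Bu2) at full drive) are
chosen once so that each phenotype satisfies its own classification
criteria and so that driven responses have realistic spike counts; they
are documented here and not tuned per experiment.

**What passing tests show** — that the pipeline's definitions are mutually
consistent (generated types are recovered by the criteria and by the GMM,
phase-locking and precision orderings propagate through VS, CI, VP and
population decoding) and that all calibrated quantities (Rayleigh 13.8,
Poisson CI ≈ 1, log-ISI anchors) are correct.  **What they do not show** —
performance on real recordings: real units overlap between classes, drift,
and violate Poisson assumptions; electrode noise, sorting errors, and
non-stationarity are not modeled; synthetic class separations are
deliberately clean, so recovery rates here are upper bounds.

## Sizes and tolerances used by the checks

Closed-loop classification runs on a 40-unit session; the temporal-coding
patterns on a 38-unit session with the duration, SAM and vocalization
protocols; population decoding patterns use 25 pseudopopulation draws and
14–16 units per composition.  The Rayleigh null is checked with 10⁶ Monte
Carlo draws at N = 500 (±0.1); the log-ISI anchors with 10⁶ intervals
(±0.2, one histogram bin beyond the flat-top ambiguity of the mode); the
Victor–Purpura dynamic program against exhaustive enumeration on 10³ pairs
of ≤ 8-spike trains and the metric axioms on 10³ triples; the Poisson CI
on 100 simulations (within [0.9, 1.1]).
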