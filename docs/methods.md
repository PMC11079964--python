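# Methods

`wmcpp` reproduces, on synthetic data, the analysis chain used to
characterize a centro-parietal positivity (CPP) — the EEG decision signal
whose buildup rate tracks how quickly a decision is reached — when
participants sample a cued item from visual working memory.  Because the
package is built and validated without access to recorded EEG, a generative
model of the assumed signal structure is a first-class component: every
analysis stage is tested against the generator's known ground truth.

## Generative model (`wmcpp.synth`)

Each participant is a continuous multichannel recording at 1,000 Hz on a
schematic 10-10 montage (default 29 scalp sites + M1/M2 mastoids; a
61+2-channel variant is available).  Channel coordinates are a flat layout on
the unit disc, not a head-model projection; they only serve smooth spatial
weighting and topography exports.

**Decision times.** Trial decision times (cue onset to report onset) follow a
shifted lognormal, `DT = shift + LogNormal(mu, sigma)` with defaults
shift = 250 ms, mu = 6.102, sigma = 0.5, giving an analytic mean of
`250 + exp(mu + sigma^2/2) = 755.8 ms` — the cohort-mean decision time the
analysis is calibrated around — with realistic right skew.  Draws are *not*
clipped to the 200–2,000 ms analysis range, so the exclusion filter operates
on genuine out-of-range trials.  Draws at or before the accumulation onset
are redrawn (bounded retries).

**CPP component.** The core assumption is accumulation to a *fixed bound*: on
each trial the noiseless CPP at channel c is

    w_c * A * (t - t0) / (DT - t0)   for t0 <= t <= DT (time after cue),

reaching exactly `w_c * A` at the response sample, then decaying as
`exp(-(t - DT)/tau)` with tau = 300 ms.  The pre-decision slope is therefore
`A / (DT - t0)` — inversely proportional to decision time — which is the
structure the slope/binning analyses are designed to recover
(`expected_slope` exposes it as an analytic oracle).  Spatial weights `w_c`
are an isotropic Gaussian (width 0.4) centered between Pz and CPz.  The bound
is per condition: 10 uV by default; 12 vs 8 uV in the two-condition
(memory-load) cohort.

**Accumulation onset.** `t0 = 100 ms` after the cue.  The onset matters
because the a priori slope window (−500..−50 ms before the response) covers
the whole ramp only for slow decisions; for fast decisions part of the window
precedes the ramp and dilutes the measured slope.  With t0 = 100 ms the
noiseless *measured* slope is a monotonically decreasing function of decision
time across the range that quartile-bin means occupy (~450–1,400 ms), so the
generator's ground truth and the analysis' a priori window are mutually
consistent.  (With a late onset and a strong centro-parietal cue transient,
the measured slope becomes non-monotone at fast decision times — an
interaction worth knowing about when interpreting real data.)

**Cue-evoked transient.** A Gaussian bump (peak 150 ms post-cue, temporal SD
40 ms, amplitude 5 uV) with an *occipital* spatial profile (centered on Oz,
width 0.25) models the visual response to the fixation-cross color change.
Its overlap with the analysis cluster is deliberately modest (~0.3), as for a
low-level visual transient against a broad centro-parietal decision signal.

**Noise.** Channel noise is Gaussian with a summed power spectrum: pink (1/f
power above a 0.5 Hz amplitude floor; RMS 12 uV), white (6 uV), and an
alpha band (Gaussian around 10 Hz, SD 1 Hz; 4 uV).  Summing PSDs in a single
spectral-synthesis pass is statistically identical to adding independent
components.  Long recordings are synthesized as 2^16-sample blocks combined
by 50%-overlap-add with a sqrt-Hann window: variance is preserved exactly and
the PSD up to the (negligible) window kernel.  A slow common-mode drift
(1/f amplitude below 5 Hz, 5 uV RMS) is added identically to *all* channels,
including the mastoids, so mastoid-average rereferencing demonstrably removes
it.  Mastoids carry noise and drift but no neural components.

**Behavior.** Signed reproduction errors are drawn from a von Mises on the
orientation circle (180 deg period).  Concentrations were solved by
quadrature so the mean absolute error matches target values: kappa = 3.164
gives 14.14 deg (default), 3.619 gives 13.0, 4.728 gives 11.1 (two-condition
cohort).  The two-condition cohort ("selection" required vs "preselected",
P(selection) = 0.2) also shifts selection-trial decision times +250 ms.

**What the generator does not model:** ocular artifacts, electrode drift or
pops, realistic forward-model topographies, single-trial variability of the
bound or (by default) of the onset — `onset_jitter_ms` exists but defaults to
0 and no claim is made about matching real single-trial dynamics.  Passing
tests therefore show that the *pipeline* recovers the assumed structure, not
that real EEG has that structure.

## Preprocessing (`wmcpp.preprocess`)

Rereference to the mastoid average (references retained); downsample
1,000 → 250 Hz with a zero-phase symmetric FIR (cutoff 0.4 x target rate,
129 taps), evaluated polyphase at the kept samples with symmetric edge
padding; event samples are remapped by integer division and decision times
recomputed on the new grid (shift < 4 ms).  Epochs: −250..+1500 ms around the
cue, −1500..+500 ms around the response (windows chosen to contain every
analysis window plus smoothing margin; they are package choices, as is the
anti-alias filter).  Baselines: mean over −250..0 ms pre-cue (cue-locked) and
0..+250 ms post-response (response-locked), per trial and channel.  Smoothing:
Gaussian kernel, SD 30 ms, truncated at ±4 SD, renormalized, reflect-padded,
time axis only — slope estimates are unaffected by any constant baseline, and
smoothing is applied to trial-averaged or bin-averaged traces (binned ERPs
are smoothed *after* binning; a config switch exposes the alternative).

Trials with decision times strictly below 200 ms or strictly above 2,000 ms
are excluded (boundary values kept).  Visual artifact inspection is replaced
by a reproducible, condition-blind flag: robust z (median/MAD) of the log
broadband per-trial variance over the analysis channels, threshold 3.5.

## CPP analysis (`wmcpp.cpp`)

The a priori electrode cluster is Pz, CPz, POz, P1, P2 (unweighted mean).
Grand ERPs are two-level: trials averaged within participant, mean ± SEM
across participants (SEM denominator = number of participants).  Per
participant, trials are stably sorted by decision time (ties by trial id) and
partitioned into contiguous bins as equal as possible, remainders to the
earliest bins — 100 percentile bins for ERP images, 4 quartile bins for
slopes.  The pre-decision slope is the OLS coefficient of potential (uV) on
time (s) over the closed −500..−50 ms window; per participant, Pearson's r
between bin number (1..4) and slope quantifies the gradient, tested at the
group level with a one-sample t against zero.  A window sweep recomputes the
group t over a grid of slope windows (starts −1000..−200 ms, ends −400..0 ms,
50 ms steps, minimum width 100 ms); the a priori window is one grid cell.
Degenerate correlations (zero slope variance) propagate as missing, never as
zero.  Topography values are plain per-channel window means (no
interpolation): 300–600 ms post-cue, −300..0 ms pre-response, and
−600..−300 ms for the condition contrast.

## Inference (`wmcpp.inference`)

One-sample and paired t tests report t, df, two-sided p, mean, SEM and
Cohen's d = t/sqrt(n) (exact for these designs).  The cluster-based
permutation test evaluates participants x time data against zero (or paired
condition differences): pointwise one-sample t; contiguous runs exceeding the
two-sided parametric critical value at alpha = 0.05 (df = n−1) form clusters
scored by summed t; the null is the maximum |cluster mass| under
whole-participant sign flips (condition swaps reduce to sign flips of the
paired differences), with `p = (1 + #{null >= observed}) / (1 + n_perm)` so
p > 0 always.  Designs with 2^n <= 2^14 patterns are enumerated exhaustively
(exact p); an explicit enumeration oracle (`enumerate_cluster_null`, capped
at 2^20) backs the Monte-Carlo path in tests.  Zero pointwise variance is
floored at the smallest positive float, so perfectly consistent effects give
huge finite t identically in the observed and permuted statistics.
Permutations default to 10,000 (the cohort-scale drivers use 2,000, which
bounds attainable p at 5e-4 — ample for 0.05-level decisions at much lower
cost).

## Problem sizes and numerical choices

The shipped drivers and validation suite run the study-scale condition the
analyses assume: 25 participants x 620 simulated trials (~600
retained after exclusion), 1 kHz, 31 channels.  Continuous data are held in
float32 (microvolt signals; rounding ~1e-5 uV), epochs and all statistics in
float64.  Window masks use closed intervals with a 1e-9 ms guard; cluster
mass comparisons use a 1e-9 tolerance.  Type-I calibration of the cluster
test uses 500 null datasets (25 x 200 Gaussian) at 1,000 permutations.

## Known limitations

* The generator's single fixed onset and deterministic ramp understate real
  single-trial variability; recovered correlations (r ~ −0.9) are therefore
  cleaner than typically observed in vivo.
* The retention rate is near-total because no artifact classes are injected;
  only the reporting convention, not the rate, mirrors practice.
* Cluster inference is temporal only (the analysis restricts itself to an a
  priori channel cluster); no channel-adjacency clustering or TFCE.
* The schematic montage supports spatial weighting and ranking of channels,
  not quantitatively realistic scalp potentials.
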