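# Methods

`restingstop` re-implements, end to end and on fully synthetic data, an
analysis chain that links resting-state local functional connectivity to
stop-signal inhibition performance in middle-aged and elderly adults:
per-subject ReHo and fALFF maps, voxelwise correlation of those maps with
the stop-signal reaction time (SSRT) with and without age partialled out,
Monte-Carlo cluster-extent correction, and a max-r minimum-statistic
conjunction of the ReHo and fALFF correlation maps. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic data can and cannot establish.

## Stop-signal task and SSRT

The task is the classic stop-signal paradigm: five blocks of 140 trials,
40 of them stop trials, inter-stimulus intervals uniform on 1,300–4,800 ms.
On a stop trial an auditory stop signal follows the go stimulus at the
stop-signal delay (SSD), which is adapted by one of two interleaved
staircases (starts 150 and 350 ms, fixed 50-ms steps, clamped to
0–800 ms): a successful stop raises the SSD of that staircase, a failed
stop lowers it. Stop trials alternate strictly between the two staircases
(the alternation rule is a package choice; only "two interleaved
staircases" is given by the design).

Subjects are simulated under the horse-race model: an ex-Gaussian go
process (mu, sigma, tau; defaults 500/50/175 ms, mean go RT ≈ 675 ms) races
a constant-latency stop process (default SSRT 300 ms); the response is
emitted iff the go process finishes by SSD + SSRT and the trial is not an
omission (default omission rate 11.24%, choice-error rate 2.07%). A
constant stop latency makes recovery tests sharp, because the median-based
estimator targets a central latency; an estimator for a *distribution* of
stop latencies is out of scope.

SSRT is estimated as median go RT − median SSD, with medians over
responded go trials (omissions carry no RT and are excluded; wrong-key
responses carry an RT and are included) and over all stop-trial SSDs.
Two estimator properties are worth knowing:

- **Omissions bias the median method.** With omission rate p the staircase
  converges where F(SSD + SSRT) = 0.5/(1−p), so the estimate is low by
  the quantile gap q(0.5/(1−p)) − q(0.5) of the go distribution (≈ 25 ms
  at p = 0.11 for the default parameters). This is a property of the
  estimator under the real design, not a bug; recovery tests therefore
  use p = 0.
- **Cold-start transient and shared noise.** Both staircases usually start
  below the converged SSD, and the climb toward it takes longer for
  slower subjects, biasing the SSD median down proportionally to go RT;
  in addition the go-RT median's sampling noise enters the estimate with
  a positive sign. Together these make the *observed* go-RT median and
  the estimate correlate at r ≈ +0.1 across subjects even when go speed
  and stop latency are generated independently. Independence holds at the
  generative-parameter level (r ≈ 0.08 at n = 200 in our checks), which is
  what the test suite asserts. A single 200-stop-trial session estimates
  SSRT with ≈ 25 ms standard deviation, dominated by the staircase random
  walk.

## Synthetic cohort

A cohort row holds age (uniform on 40–77 years), race-model parameters,
and a latent true SSRT, Gaussian with mean 300 ms and SD 50 ms and a
configurable population correlation with age (default 0.22). Each
subject's *analyzed* SSRT comes from actually simulating their session,
so estimation noise propagates into the brain–behavior correlations as it
would in a real study.

Each subject also gets a 4D volume (default 24×24×24 voxels at 2 mm,
240 time points at TR 2 s, spherical in-brain mask; acceptance-scale runs
use 96 time points — see "Problem sizes" below). Background voxels are
independent unit-variance white noise; masked-out voxels are exactly
zero. Disjoint cubic effect regions implement known couplings through a
single construction: every voxel in a region is

    v = sqrt(rho) * c + sqrt(1 - rho) * p,
    c, p ~ (w + a * l) / sqrt(1 + a^2),

where w is white noise, l is unit-variance band-limited (0.01–0.08 Hz)
noise, c is shared across the region and p is private per voxel. The
shared-variance fraction rho drives ReHo (Kendall's W of the band-passed
series) and the low-frequency gain a drives fALFF, and the construction
keeps them orthogonal: the shared fraction is exactly rho for any a, and
the per-voxel spectrum depends only on a for any rho. This matters after
6-mm smoothing, which preserves the coherent (shared) component
unattenuated while suppressing incoherent components — with any
spectrally mismatched common signal, a synchrony region would leak into
fALFF (an earlier construction did exactly that, producing near-zero
coupling in dual-effect regions).

Couplings are affine in the standardized driver (true-SSRT z-score or age
z-score, clipped at ±2.5 SD), negative by default: rho = 0.45 − 0.22 z,
a = 1.0 − 0.4 z, clipped to [0, 0.9] and [0, 2.5]. These slopes were set
once so that region-level correlations with SSRT land in the
plausible-peak regime |r| ≈ 0.45–0.7 at n = 40. Region kinds: `synchrony`
(rho only), `amplitude` (a only), `both`, and `age_only` (both effects,
driven by age, with stronger couplings rho = 0.6 − 0.35 z, a = 1.4 − 0.7 z:
the region's purpose is to be unambiguously age-driven, and its marginal
SSRT correlation — the product of the region–age and age–SSRT
correlations, further attenuated by SSRT estimation noise — must still
clear the voxel threshold in the full-correlation maps for the
full-vs-partial contrast to be observable; the age-contrast test
accordingly also uses a strongly age-coupled cohort, population
corr(age, SSRT) = 0.75, while the default cohort keeps 0.22). The
recovery scene places 5³-voxel cubes ≥ 12 mm apart so smoothing cannot
bridge them.

What the generator does *not* emulate: head motion, physiological
(cardiac/respiratory) noise, scanner drift, anatomical structure, spatial
normalization error, or spatially varying smoothness. Passing tests show
that the statistics and their calibration behave correctly under the
stated noise model — not that the pipeline is robust to real-scanner
artifacts.

## Preprocessing

Order follows the analysis chain as published: 6-mm FWHM isotropic
Gaussian smoothing, then band-pass 0.01–0.08 Hz into ReHo, while fALFF
sees the smoothed, detrended, *unfiltered* series. The ReHo methods
literature often computes Kendall's W on unsmoothed data (pre-smoothing
inflates neighborhood concordance); `subject_maps(smooth_before_maps=False)`
provides that alternative (maps computed first, maps smoothed after), but
the published order is the default and no guess is made about intent.

The band-pass is an ideal frequency-domain filter: FFT, zero every bin
outside the passband (DC always removed), inverse FFT. Stop-band
rejection is exact on the FFT grid and the fALFF examples become
analytically checkable; a zero-phase 4th-order Butterworth is available
(`method="butter"`) for users who dislike ideal filters on real data.
Smoothing uses sigma = FWHM/(2·sqrt(2·ln 2)) per axis in voxel units,
zero-padded, without mask renormalization. Detrending removes each
voxel's least-squares line.

## ReHo and fALFF

ReHo assigns to each in-mask voxel Kendall's coefficient of concordance
over its 27-voxel neighborhood (7 and 19 also supported):

    W = (sum_i R_i^2 − n Rbar^2) / (K^2 (n^3 − n) / 12)

with ranks computed per series across time. Neighbors outside the mask
are dropped (K shrinks); voxels left with K < 2 are undefined and
logged. Ties get mid-ranks without the tie-correction factor (the
original ReHo convention); the fast map path uses ordinal argsort ranks,
equivalent on continuous data where ties have measure zero.

fALFF is the sum of FFT amplitudes (square root of power) over
0.01–0.08 Hz divided by the sum over 0.01–0.25 Hz, on the detrended,
unfiltered series. Bins are half-open [low, high) on the FFT grid; the
DC bin is always excluded (the stated bands start above it anyway, but
the rule also covers user-supplied bands). Zero-denominator voxels are
undefined and logged. Both maps are standardized (divided by the
within-mask mean) before correlation by default, following common
resting-state practice; `standardize=False` turns this off since the
published analysis does not say. One side effect of standardization worth
knowing: with strong effect regions in the mask, division by the mask
mean imparts a small *positive* SSRT correlation (|r| up to ~0.2) on
background voxels; it never survives the negative-sign threshold but is
visible in raw correlation maps.

## Brain–behavior correlation and thresholds

Voxelwise Pearson r between the subject vector of map values and SSRT;
the age-adjusted version uses the first-order partial-correlation
identity r_xy.z = (r_xy − r_xz r_yz)/sqrt((1−r_xz²)(1−r_yz²)), df = n−2
and n−3 respectively. Undefined voxels (zero variance, collinearity with
the covariate) propagate as NaN and can never survive thresholding.

The voxel threshold is the critical r from the t distribution,
r_crit = t_crit/sqrt(t_crit² + df), two-tailed by default even though
only negative correlations are reported (one-tailed available). At
α = 0.005 and df = 70 this gives 0.327 two-tailed (0.302 one-tailed);
the published threshold of 0.31 for that setting matches neither closed
form exactly, so the package always computes the threshold from
(α, df, tails) and records this discrepancy here rather than hard-coding
0.31.

## Cluster-extent correction

The minimum cluster extent k_min comes from a Monte-Carlo null: per
iteration, Gaussian white noise on the grid → Gaussian smoothing at the
analysis FWHM → standardization within the mask → two-tailed voxel
threshold (|z| ≥ z_{1−α/2}, matching the symmetric null even when one
sign is reported) → connected-component labeling → record the largest
cluster. k_min is the smallest k whose empirical exceedance
P(max ≥ k) ≤ corrected α; if even the full mask cannot reach it (e.g.
voxel α = 1) the result carries a None sentinel and nothing survives.
Defaults: voxel α = 0.005, corrected α = 0.05, 26-connectivity, 1,000
iterations, and the connectivity and seed are recorded in every output.
"p < 0.005 corrected" is read as voxel α = 0.005 with corrected α = 0.05
— the standard reading of that phrasing; both knobs are explicit.

Null smoothness is the analysis FWHM rather than being estimated from
residuals (no smoothness-estimation step is part of the chain). ReHo maps
carry extra intrinsic smoothness from neighborhood overlap, so k_min is,
if anything, slightly liberal for them; the null-cohort calibration test
measures the realized family-wise error directly (≤ 2× nominal over 100
cohorts) rather than assuming nominal behavior.

## Conjunction

Because the interest is in negative correlations, the minimum-statistic
conjunction is the voxelwise *maximum* of the two raw (unthresholded,
uncorrected) r maps: surviving a negative threshold then requires both
parents beyond it, so conjunction survivors are provably a subset of the
intersection of parent survivors at the same thresholds. The conjunction
map is thresholded at the same r_crit as its parents (the df ambiguity of
a max-of-r statistic is acknowledged; by the minimum-statistic argument
the threshold is conservative) and re-corrected with a freshly computed
extent threshold on the same mask and FWHM (whether the original analysis
reused or recomputed the extent is unstated; recomputation is the default
and the choice is logged). The partial-correlation conjunction uses the
two age-partialled parents only.

## Problem sizes and runtime choices

The default scene is 24³ voxels at 2 mm with 240 time points — small
enough for minutes-scale full-pipeline runs while keeping the stated
temporal parameters (TR 2 s, 240 retained samples). The heavy calibration
and recovery suites run 100 null cohorts and 2×20 effect cohorts at
n = 40 subjects on the 24³ grid with 96 time points; null calibration and
effect recovery are insensitive to series length, and 96 points keep the
full suite within a coffee break on one CPU. The Monte-Carlo extent
threshold for those suites is computed once per configuration (it is
deterministic given its own seed and shared mask/FWHM/α) rather than per
cohort. Per-subject volumes are generated in float32.

## Known limitations

- The synthetic affine is a toy MNI-like transform (isotropic 2 mm,
  origin at the grid center); reported "world mm" coordinates are only
  meaningful relative to it.
- The race model has no go/stop dependence, no SSD-dependent triggering
  failures, and a constant stop latency; SSRT variance across trials is
  not modeled (an optional extension point, not implemented).
- Cluster tables report coordinates and peak r only; no anatomical
  labeling.
- The Monte-Carlo null assumes stationary, isotropic smoothness equal to
  the applied kernel; real data violate this and would need residual
  smoothness estimation, which is deliberately out of scope.
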