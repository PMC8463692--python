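# Methods

This note documents the models, numerical choices and known limits of
`lfpspike`, in the spirit of a methods appendix: everything a user
needs to interpret what the pipeline computes and what passing tests do
and do not establish.

## Signal derivation

All filtering is forward–backward ("zero-phase") Butterworth: the two
passes square the magnitude response (|H(f)|² net) and cancel the
phase, so in-band components emerge with zero lag — essential when
features and targets must stay time-aligned on a common window grid.

* **LFP**: 4th-order low-pass at 100 Hz (10/50/300 Hz variants
  supported), then polyphase resampling to an exact 1 kHz grid. The
  100 Hz default keeps multi-unit spike-waveform energy (100–300 Hz)
  out of the LFP band.
* **ESA** (entire spiking activity): 1st-order high-pass at 300 Hz,
  full-wave rectification, 1st-order low-pass at 12 Hz, then the same
  resampling. ESA is a continuous, threshold-less measure of local
  population spiking; unlike SUA/MUA it involves no detection step and
  therefore no amplitude bias toward large neurons.

Filters are designed as second-order sections: transfer-function
coefficients are numerically fragile when the cutoff sits far below
Nyquist (a 2 Hz low-pass at 1 kHz loses ~8 decades of stop-band
attenuation in (b, a) form).

Edge transients are suppressed with odd-reflection padding spanning
three time constants of the lowest cutoff frequency (at least
3·(order+1) samples, capped at the signal length). A fixed short pad
is not enough: for the 12 Hz ESA smoother it leaves an edge undershoot
of tens of percent of signal RMS, whereas with time-constant-scaled
padding the ESA's negative undershoot stays within 5% of RMS. ESA
values are deliberately not clipped at zero.

Resampling uses `scipy.signal.resample_poly`, which handles the
non-integer 24.4 kHz → 1 kHz ratio (5/122) exactly; its linear-phase
FIR preserves the zero-lag contract, and the preceding low-pass
already provides anti-aliasing.

## Windowed features

One `WindowGrid` — 256 ms width, 50 ms hop (206 ms overlap), timestamps
at the window end (causal convention; alignment is what matters, the
convention itself is arbitrary) — serves every feature family:

* **LMP**: per-window arithmetic mean of the LFP (rectangular moving
  average).
* **Band powers**: Hann-tapered 256-point short-time spectrum at 1 kHz
  (3.906 Hz bin spacing), |X(f)|² averaged over bins with
  low ≤ f < high, DC excluded. **At this resolution delta, theta and
  alpha each contain exactly one bin** (3.9, 7.8, 11.7 Hz); beta has 4
  and gamma 18. An `nfft` argument enables zero-padding when finer
  band resolution is wanted; the default is the plain 256-point
  transform. Gamma's upper edge follows the LFP cutoff (100 or
  300 Hz).
* **Spike rates**: spike count in the half-open window [start, end)
  divided by 0.256 s; half-open intervals prevent double counting on
  shared edges. Units with session-wide rate not strictly above
  0.5 Hz are excluded, computed over the full session before any
  block split.
* **ESA feature**: the same moving average applied to the ESA signal.

Standardization (z-transform) uses per-column mean and population
standard deviation (ddof 0) estimated on training rows only;
zero-variance columns are guarded with σ := 1 so constants map to
zeros.

## Inference and evaluation

The decoder is multivariate multiple linear regression fitted by
ordinary least squares with an intercept. The implementation solves the
least-squares problem by factorization (`numpy.linalg.lstsq`) rather
than forming (XᵀX)⁻¹; agreement with the explicit normal equations is
enforced by tests, not by the code path. Rank-deficient designs (e.g. a
random channel subset drawing duplicated columns) return the
minimum-norm solution with a warning. No regularization is applied.

Evaluation uses 10 contiguous, non-overlapping blocks of near-equal
size (remainder rows go to the leading blocks). Fold f tests on block
f, reserves block (f+1) mod 10 as a validation set — unused by OLS but
kept for API parity with decoders that need one — and trains on the
remaining 8. Standardization parameters come from the training rows of
each fold only; a dedicated test verifies that modifying test-fold
samples leaves the fitted model bit-identical.

Metrics are Pearson's CC and RMSE per output and fold, computed on the
standardized target scale (which is why RMSE values sit in the
0.6–1.0 range: an uninformative predictor scores RMSE ≈ 1 there).
Aggregation pools all (output, fold) pairs; SEM is the ddof-1 standard
deviation of the pool over √count. Paired comparisons screen the
difference distribution with Shapiro–Wilk at α = 0.05 and branch to a
paired two-tailed t-test (normal-looking) or the Wilcoxon signed-rank
test (otherwise); α = 0.05 throughout.

## Array geometry

The electrode map models a 10 × 10 grid at 400 μm pitch with four
unconnected sites, 96 channels. The unconnected sites default to the
four corners — the standard wiring, and the only four-site choice
whose maximum connected-pair distance, 400·√130 = 4560.70 μm, rounds
to the conventional 4561 μm range endpoint. Channel numbering is
row-major over connected sites; only pairwise distances enter any
computation, so physical wire order is irrelevant. Distances are kept
as floats; the printed endpoint is compared after rounding to the
nearest integer micrometre (flooring would give 4560).

## Secondary analyses

* **Feature informativeness**, two routes: cross-validated mean CC of
  a decoder fit on each feature type separately (p = 96 columns), and
  mean |coefficient| per feature type from one decoder fit on all
  types combined (p = 576), averaged over inputs, outputs and folds.
* **Channel-count curve**: for p ∈ {1, 5, 10, …, 95}, sample p distinct
  channels without replacement, cross-validate, repeat 30 iterations;
  the 95% CI is the 2.5/97.5 percentile band over iterations (the
  percentile choice is a design decision; with 30 iterations a normal
  approximation would be similar). Each (p, iteration) pair has its
  own named substream, so curves are reproducible and p = 96 is
  deterministic. The "channels to 90% of maximum" summary linearly
  interpolates the mean-CC curve between grid points and rounds up —
  plateau counts reported in the field (e.g. 35) lie off the 5-channel
  grid, so some interpolation is implied.
* **Interchannel correlation**: the 96 × 96 Pearson matrix of LFP
  channels; the scalar summary is the mean of the upper-triangle
  off-diagonal entries.
* **Channel importance**: per (input channel, output) pair, either the
  cross-validated CC of a single-input decoder (`cc` metric) or the
  fold-averaged mean |coefficient| of the all-channel decoder (`coef`
  metric, averaged over folds rather than refit on the full session —
  a design choice; the two differ only by sampling noise). SUA scores
  from units sharing an output channel are averaged. Every row carries
  the interelectrode distance between input and output electrodes;
  the distance trend is the OLS slope of score on distance with its
  two-tailed t-test p-value. Heatmaps place scores on the 10 × 10 grid
  with unconnected sites flagged as NaN, distinct from a true 0.

## Synthetic recording generator

The generator is a stand-in, not a biophysical model: the study design
it supports uses real recordings, and no generative model of those
recordings exists. Every choice below is therefore labelled as
artifact plumbing whose sole purpose is to give the pipeline known
ground truth.

* A slow latent drive z(t): white noise low-passed at f_z = 2 Hz
  (4th-order, zero-phase) and standardized — a stand-in for the slow
  movement-related modulation that motivates the LMP feature.
* Per-channel LFP at 1 kHz: g_c·z(t) plus narrowband components
  (band-pass-filtered white noise; defaults: alpha 8–12 Hz at 0.35,
  beta 15–30 Hz at 0.25) plus pink noise (1/f-shaped, sd 0.3). The
  coupling g_c = exp(−d(c, hotspot)/λ) decays with distance from a
  hotspot channel (default: nearest the array centroid) with
  λ = 1200 μm, spanning g ≈ 0.12–1 across the array.
* Unit spike trains: inhomogeneous Poisson with rate
  r_u·max(0, 1 + β_u·z(t)), sampled by thinning on the 1 kHz grid.
  The rectified-linear link keeps the mean rate at r_u whenever
  clipping is rare, which makes expected counts checkable. Defaults:
  4 units per channel, r_u ~ U(5, 20) Hz, β_u ~ U(0.6, 1.0),
  amplitudes log-uniform on [0.5, 4].
* Raw trace: the 1 kHz LFP linearly interpolated to fs_raw (default
  30 kHz; the 100 Hz low-pass downstream makes interpolation artefacts
  negligible), plus a biphasic spike template per spike (difference of
  two Gaussians, ~1.2 ms span, exactly zero net area so spikes stay
  out of the LFP band), plus white noise (sd 0.5).
* Ground truth: SUA = the per-unit trains; MUA = union of trains of
  units whose amplitude exceeds a detection-equivalent cutoff
  (default 1.0, dropping roughly the smallest third of units —
  emulating threshold detection's bias); ESA has no event-level
  ground truth, being continuous by definition.
* All randomness flows from one root seed through named substreams
  (drive, unit parameters, spikes, LFP noise, raw noise), so each
  stage is independently reproducible and sessions are bit-identical
  under a fixed seed.

**Default conditions.** The `desk()` preset keeps the full 96-channel,
60 s session but generates at fs_raw = 4 kHz instead of 30 kHz — still
comfortably above twice the 300 Hz ESA high-pass — so the whole
pipeline runs in seconds; 30 kHz remains the plain default. Test
sessions use 8–96 channels and 20–60 s as stated per test.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real cortex: no task structure or trial events; a
single global drive rather than a population of partially shared
latent processes (real arrays show richer spatial correlation than one
exponential hotspot); no electrode drift, impedance variation or
artefacts; no cell-type diversity, refractoriness, bursting or
spike-waveform overlap; oscillatory bands uncoupled to spiking by
construction, so band-power features are uninformative here by design
rather than by measurement. Qualitative reproductions on this
generator (LMP most informative; ESA easier to infer than SUA;
importance decaying with distance) demonstrate that the pipeline
recovers planted structure, not that cortex behaves this way.

## Problem sizes

Desk-scale runs use 96 channels × 60 s at 4 kHz for the headline
quantities (~1200 windows, ~38 s end to end on one CPU including the
30-iteration subset curve), 24-channel × 48 s sessions for the
20-seed feature-informativeness checks, and 96-channel × 30 s sessions
for the 20-seed distance-trend checks.

## Known limitations

* Metrics are computed on standardized targets; RMSE is therefore
  scale-free and not comparable to spike-rate units.
* With the default 256-point spectrum the three narrow bands are
  single-bin estimates — noisy by construction; zero-padding sharpens
  the grid but not the underlying resolution.
* The minimum-norm fallback for rank-deficient designs makes
  coefficient-based importance scores of exactly collinear channels
  split arbitrarily (equally) between duplicates.
* `channels_to_fraction` assumes the subset curve is reasonably
  monotone; on non-monotone curves it reports the first interpolated
  crossing.
* HDF5 containers store float64 throughout; a 30 kHz, 96-channel,
  10-minute raw group is ~14 GB — desk-scale sessions are the intended
  use.
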