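# Methods

This note documents the processing model implemented by `happe`, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic test bed does and does not show.

## Processing model

Each EEG file passes through a fixed stage order:

1. **Filtering.** Zero-phase windowed-sinc FIR (Hamming window, ~1 Hz
   transition band), applied forward-backward. Every file gets a 1 Hz
   high-pass; files sampled at >= 500 Hz get a 1–249 Hz band-pass
   instead, bounding the bandwidth passed to the decomposition stages.
   The forward-backward pass squares the designed magnitude response,
   so the nominal cutoff gain is ~0.25 rather than 0.5.
2. **Channel-subset selection.** ICA of C channels is only considered
   stable with at least `30 * C**2` samples; `ica_sample_budget`
   implements the rule in exact integer arithmetic and the pipeline
   refuses to start a batch whose shortest file fails it. The subset
   must contain the 19 International 10–20 labels (18 canonical scalp
   positions without the Cz reference, plus Fpz; the set is
   configurable) because the component classifier reads its scalp maps
   from those rows.
3. **Line-noise removal.** Multitaper sinusoid regression in sliding
   4-s windows with a 1-s step: Slepian tapers with 2 Hz half-bandwidth
   (NW = 4, 7 tapers), a Thomson F-test for a deterministic sinusoid on
   a 0.05 Hz grid within ±2 Hz of the nominal mains frequency, and
   subtraction of the fitted sinusoid where the regression coefficient
   is significant at p < 0.01 after a Bonferroni correction for the
   ~16 resolvable frequencies in the scan band (without the correction
   the maximum over the scan grid makes false fits routine). Window
   contributions are cross-faded with sigmoidal edge weights whose
   steepness is the `smoothing_tau = 100` parameter. Harmonics are
   processed independently per listed frequency.
4. **Bad-channel rejection** (twice). Per channel, the average log10
   Welch power over 1–125 Hz (2-s Hamming windows, 50% overlap; band
   clipped to Nyquist − 1 when needed). The "normed joint probability"
   of these values is computed as the negative log of an empirical
   density: `log` of the distance to the 3rd-nearest neighbour plus a
   small (0.1-weighted) quadratic tail term from a robust
   (median/MAD) Gaussian fit. Statistics are z-scored and channels
   more than 3 SD out (one-sided, since improbable values always have
   *large* statistics) are flagged — provided they also deviate from
   the montage median by at least 0.25 decades of log power (~1.8x
   power). That material-deviation guard encodes a physical prior: a
   channel whose broadband power matches its neighbours is recording,
   whatever its rank statistics say; without it any smooth value
   distribution yields steady false flags at a fixed 3 SD cut. The
   evaluation runs twice because one gross outlier (a flat electrode)
   inflates the spread enough to mask a milder one; the second pass
   over the survivors catches it. Bad channels are excluded from all
   decomposition stages and interpolated near the end.
5. **Wavelet-enhanced ICA (W-ICA).** Extended-Infomax ICA, then every
   component is stationary-wavelet transformed (Coiflet-5,
   energy-normalized transform) to depth `L = round(log2(fs/16))`
   (250 Hz -> 4 levels, detail bands ~8–125 Hz), soft-thresholded with
   one global universal threshold per file,
   `T = median(|D1|)/0.6745 * sqrt(2 ln N)` computed from the pooled
   level-1 detail coefficients, and the reconstruction of the
   *surviving* coefficient mass is taken as the artifact time series
   and subtracted in channel space. All coefficient bands, including
   the approximation, are thresholded: blinks are <5 Hz events and
   live almost entirely in the approximation band at this depth, and
   thresholding everything also gives the exact limit behaviours
   (T -> infinity leaves the input untouched; T -> 0 moves the whole
   zero-mean signal into the artifact stream). No component is removed
   at this stage, so the full recording length survives.
6. **ICA with automated component rejection.** A second
   extended-Infomax decomposition, then each component is scored on
   six features: mean absolute skewness over 15-s windows (trailing
   partials >= 5 s included); mean log10 alpha-band (8–13 Hz) power;
   the exponent lambda of a `log P = a − lambda log f` fit sampled at
   2, 5, 8, 13, 30 and 75 Hz (capped at Nyquist − 5); the mean squared
   residual of that fit against the observed log spectrum in 8–15 Hz;
   the log range of the unit-norm scalp map; and the log norm of a
   minimum-norm inverse solution `j = L^T (L L^T + alpha I)^{-1} v` on
   a single-sphere head model (analytic series leadfield, 200 grid
   dipoles on a 0.8-radius shell, alpha = 1e-4 tr(LL^T)/19). A
   logistic head over standardized features yields an artifact
   probability; components with p > 0.5 (strict) are rejected. The
   retained variance is reported as
   `100 * (1 − var(pre − post)/var(pre))`, pooled over channels and
   samples.
7. **Optional segmentation.** Fixed windows from the file start (rest)
   or event-locked windows, then either (a) whole-segment rejection on
   a ±40 µV amplitude bound plus single-electrode and electrode-group
   joint probabilities (same density estimator as stage 4, 3 SD,
   two-sided; a segment-channel's activity is summarized by its RMS),
   all marks applied in one step, optionally restricted to an ROI
   channel set; or (b) per-segment channel repair: variance, median
   absolute gradient, amplitude range and deviation from the channel
   grand mean, z-scored across channels within the segment, |z| > 3
   plus a 2x material-deviation guard against the segment median,
   flagged channels spherical-spline interpolated within that segment
   only.
8. **Interpolation of bad channels.** Spherical splines on the unit
   sphere: Perrin-style kernel with stiffness m = 4 and the Legendre
   series truncated at order 7, regularization 1e-5. The
   unregularized path solves in an explicit real spherical-harmonic
   basis of the same truncated space, because the kernel Gram matrix
   (coefficients falling as n^-8) is numerically rank-deficient; that
   path reproduces any order-<= 7 harmonic field at held-out
   electrodes to ~1e-9.
9. **Re-referencing.** Average reference (subtract the instantaneous
   mean over retained channels) or a user-listed channel set.

The per-file quality report contains: file length, channels selected,
epochs retained after segment rejection, number and percentage of good
channels, interpolated channel ids (space-separated), number and
percentage of rejected components, percent variance retained after
component rejection, and median/mean/range/min/max artifact probability
of the kept components (computed before any segment handling). A
`flags` column mirrors warnings such as a majority of channels going
bad — an addition to the canonical column set.

## Extended Infomax

Natural-gradient learning on shuffled sample blocks
(`block = ceil(min(5 ln N, 0.3 N))`) of PCA-whitened data at full
effective rank (rank-deficient inputs are reduced with a warning, not
an error), with online kurtosis-sign re-estimation on a 6000-point
subsample every iteration so both subgaussian (mains) and supergaussian
(blink, muscle, rhythm) sources separate. Initial learning rate
`0.00065/ln K`, annealed by 0.98 whenever successive update directions
differ by more than 60 degrees; stop at a weight change below 1e-7 or
512 iterations. The weight matrix is initialized to a seeded random
orthogonal matrix and the block order reshuffles per iteration: ICA is
seed-dependent by nature, so the seed is a mandatory argument, stored
in the decomposition and in the intermediate JSON. In practice the
stochastic gradient floor means runs typically end at the iteration cap
with weight changes around 1e-3; source recovery is unaffected (Amari
index ~0.006 on the 10-source reference problem) and residual source
correlations sit near 3e-3, which is why the decorrelation test bound
is 1e-2 rather than 0.

## Synthetic test bed

`happe.synth` generates ground-truthed fixtures: a neural background of
40 dipolar 1/f sources (uniform radius 0.3–0.6 in a unit sphere,
analytic single-sphere leadfield), an occipital alpha rhythm, 1 µV
sensor noise, and additive artifacts — frontal biphasic blinks
(150 µV, ~0.25 Hz), temporal 20–100 Hz EMG bursts (35 µV), a mains
sinusoid (5 µV), slow drift (20 µV), flat and noisy channels. The clean
part plus the per-artifact matrices reconstruct the emitted data
exactly, and all randomness flows from one seed.

Two deliberate idealizations:

* **Background amplitude ~10 µV rms per channel.** Soft thresholding
  has an intrinsic artifact-capture ceiling (the threshold and the
  component scale are both fixed by ICA normalization), so blink
  removal quality depends on the artifact-to-background ratio. 10 µV
  is what the ±40 µV default segment threshold — with most segments
  retained after cleaning — implies for this population's cleaned EEG.
* **Per-channel background power partially equalized** (exponent 0.7
  row scaling). Sparse-dipole simulation otherwise leaves edge
  channels with genuinely outlying gains, which is a property of the
  simulation, not of the healthy-electrode condition the clean
  fixtures represent.

Consequently the tests show that planted faults of realistic size are
detected and removed under these conditions; they do not show
performance on recordings with strong regional power asymmetries,
pathological waveforms, or channel counts/durations outside the
generated range.

The component classifier's logistic weights are calibrated by
`scripts/calibrate_classifier.py` on a labelled synthetic component
corpus (six classes: alpha and broadband neural, blink, EMG, mains,
discontinuity; training seeds 7001–7010, 480 components) and shipped
as JSON; held-out evaluation across 50 unseen seeds gives sensitivity
1.00 and specificity 0.99. The weights file can be replaced by any
externally trained set with the same schema. These weights stand in
for a classifier trained on manually labelled recorded components,
which no public weight set reproduces; accuracy numbers on synthetic
components do not transfer to recorded EEG.

## File formats

Native intermediates are raw little-endian float64 channel-major
matrices with a JSON sidecar (rate, labels, events, history) — bit
exact. EDF export uses a 16-bit physical range of ±3276.7 µV (one LSB
= 0.1 µV), a single data record spanning the file, and is re-read
through `mne`; round trips agree to one quantization step. Montages are
"label x y z" text; builtin generic layouts place the 10–20 labels at
their standard arc positions and fill the remaining electrodes with a
deterministic spiral.

## Reference problem sizes

The test suite runs everything on scaled-down but structurally faithful
problems: 19–39 channels, 60-s recordings at 250 Hz, 10–20 seeds per
stochastic claim, and a 20-seed end-to-end recovery check at a reduced
ICA iteration cap (64). These sizes were chosen so the full suite
exercises every stage, including two full pipeline batches, in a few
minutes on one CPU.
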