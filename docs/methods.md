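# Methods

`stereoattn` re-implements, as a tested library, the analysis chain of a
stereoscopic-depth attention EEG experiment: two superimposed random-dot
kinematograms (RDKs) are frequency-tagged at 15 and 18 Hz and displaced to
depth planes in front of and behind fixation via binocular disparity;
observers are cued to attend one plane and respond to coherent-motion events
there.  The pipeline extracts steady-state visual evoked potential (SSVEP)
amplitude time courses around the attention cue, event-related potential
(ERP) window statistics around the motion events, and signal-detection
behavior, with a frequentist-plus-Bayesian inferential layer.  Because no
real recordings are distributed with the study, a forward generator with
known ground truth stands in for data; every quantitative guarantee of the
package is expressed as parameter recovery from that generator.

## Stimulus geometry

Visual angle is `2 atan(s / 2D)`.  Binocular disparity of a plane displaced
`dd` from a fixation plane at distance `D`, for interocular distance `a`, is
computed in two modes:

* `small_angle`: `a * dd / D^2` (radians), identical for crossed and
  uncrossed planes.  With the published values (`a = 2 x 31.9 mm`,
  `D = 120 cm`, `dd = 10 cm`) this gives 0.2539°, printed as 0.25°.
* `exact_vergence`: `|2 atan(a/2D_plane) - 2 atan(a/2D)|`, which
  distinguishes the crossed (0.277°) from the uncrossed (0.234°) plane.  The
  small-angle value approximates the average of the two; at `dd/D = 0.1` the
  crossed-side deviation is ~10%, so the approximation should be read as a
  symmetric-pair summary, not a per-plane value.

Flicker sequences use duty-cycle frame interpolation: each frame's intensity
is the fraction of the frame during which an ideal 50 %-duty square wave at
the tagging frequency is on.  Integer frame cycles (15 Hz at 240 Hz per eye)
give binary sequences; incommensurate ones (18 Hz) get fractional boundary
frames, which pins the spectral peak exactly to the tagging frequency and
conserves the 50 % duty cycle.

## Trial schedule

960 trials in 8 blocks; 480 with no coherent-motion event, 240 with one and
240 with two.  Events start no earlier than 200 ms after the cue and end
inside the 2000 ms post-cue window.  The published "at least 800 ms" delay
between events is interpreted as offset-to-onset, i.e. onset-to-onset
>= 1100 ms with 300 ms events (configurable).  Two-event trials draw each
event's plane independently with equal probability.  The coherent-dot count
defaults to 32 (the Methods value; a figure caption elsewhere says 20 — the
field is configurable).  Cue conditions are balanced exactly; onsets are
sampled uniformly subject to the constraints.  `validate_schedule` re-checks
every invariant independently of the construction.

## Synthetic EEG generator

Per subject the generator composes, at 512 Hz on 64 scalp channels
(10-10 positions from the standard idealized montage, unit sphere) plus
bipolar VEOG/HEOG:

* **1/f noise**, 10 µV RMS per channel, spectrum slope -1. Spatial
  correlation is imposed by a Gaussian mixing kernel (scale 0.5 rad on the
  sphere) with a 5 % spatially-white sensor-noise fraction. The correlated /
  white split matters because the surface Laplacian amplifies spatially white
  noise; volume-conducted physiological noise is smooth, and modelling it as
  such keeps the post-CSD signal-to-noise in the regime real recordings show
  (prominent tagging peaks over posterior channels).
* **Alpha rhythm**: 10 Hz occipital bursts with random phase and Rayleigh
  amplitude per trial (mean 3 µV) — non-phase-locked, so it averages out of
  evoked quantities but contributes realistically to spectra and to the
  channel-statistics scan.
* **Tagged responses**: sinusoids at 15 and 18 Hz (frequency-to-plane
  mapping configurable), source amplitude 5 µV at the topography peak, a
  broad posterior Gaussian topography (sigma 0.9 rad centered between Oz and
  POz — broad enough that all 22 cluster electrodes carry signal, which is
  the stated motivation for the large analysis cluster).  The amplitude
  envelope is 1.0 before the cue and ramps sigmoidally (onset 200 ms, rise
  ~120 ms) to a condition level; the default encodes the study's finding:
  both attended and ignored envelopes fall to 0.70 (a -30 % non-selective
  drop).  Phase resets at each trial start, as when the flicker stream
  restarts with the trial.
* **Transient components**: half-cosine bumps per coherent-motion event — a
  posterior negativity (peak 275 ms, width 200 ms, -3 µV attended / -1 µV
  ignored over PO7/PO8) and a centro-parietal positivity (peak 500 ms,
  width 300 ms, +3/+1 µV over CPz/Pz), i.e. attended-vs-ignored contrasts of
  -2 and +2 µV.
* **Ocular artifacts**: blinks (100-200 ms, 200-400 µV on VEOG, frontal
  projection) and saccades (40-80 µV steps on HEOG, small lateral-frontal
  projection), Poisson at 2 and 1 per minute so that rejected-epoch fractions
  land near the published per-participant averages (~8 %).  A truth table
  records every artifact's sample span.
* **Behavior**: hits with probability 0.9265 and false alarms with 0.04 (the
  published rates), reaction times 200 ms + log-normal (median 330 ms,
  sigma 0.30), clipped to the 200-1000 ms response window; cohort mean RT
  ~550 ms.
* **Inter-subject variability**: a log-normal common gain (sd 0.2) scales
  all evoked amplitudes per subject.

A single seed drives everything through `numpy.random.SeedSequence` fan-out;
identical seeds give bit-identical recordings.

What the generator does *not* emulate: realistic volume conduction (a head
model), heart/muscle artifacts, non-stationary noise, latency jitter of the
transient components, or any coupling between behavior and EEG beyond the
event bookkeeping.  Passing recovery tests therefore demonstrate that the
*analysis chain* is correct and calibrated, not that it is robust to every
property of real recordings.

## Preprocessing

Order is fixed: DC removal on continuous data; epoching (inclusive-start /
exclusive-end windows, anchor sample at t = 0, so a -1000..2000 ms epoch at
512 Hz holds 1536 samples); blink rejection; saccade rejection; the
channel-statistics scan with spline interpolation; average reference;
surface Laplacian.

* **Blink detection**: per-epoch VEOG peak-to-peak against
  `max(60 µV, median + 5 MAD)`, re-estimated once after removing first-pass
  flags.  This is a deliberately parameter-light stand-in for the original
  unpublished in-house adaptive procedure.
* **Saccade detection**: sliding 100-ms window means on HEOG; an epoch is
  flagged when consecutive window means differ by more than 30 µV.
* **Channel-statistics scan**: per epoch x channel, absolute maximum,
  standard deviation and maximum absolute first difference; a channel-epoch
  is contaminated when any statistic exceeds its pooled
  `median + 3 IQR` limit.  Epochs with more than 12 contaminated channels
  are discarded; remaining contaminated channels are spline-interpolated.
  This is a simplified variant of the published statistical-control
  procedure for dense-array data; the original's exact parameterization is
  not public.  Note one known property: channels with genuinely higher
  variance (e.g. alpha-rich occipital sites) sit in the upper tail of the
  pooled distributions and are flagged slightly more often.
* **Spherical splines** (interpolation and Laplacian): Legendre-series
  kernels with flexibility order m = 4, ridge 1e-5, 50 terms.  The CSD
  output is the negative surface Laplacian scaled by a nominal head radius
  of 0.085 m (µV/m²): a spherical harmonic of degree n maps onto
  `n(n+1)/r²` times itself, which the tests verify together with
  leave-one-out interpolation error < 5 % on smooth potentials.  The head
  radius affects scale only, never test statistics.

## SSVEP analysis

Cue-locked epochs (-1000..2000 ms) from event-free trials are averaged per
attentional condition (evoked), detrended, and passed through a
frequency-domain Gabor filter: the spectrum is multiplied by a Gaussian of
FWHM 2 Hz centered on the tagging frequency (negative frequencies zeroed)
and inverse-transformed; twice the magnitude of the analytic signal is the
amplitude envelope.  The time-frequency duality `FWHM_t = 4 ln2 / (pi
FWHM_f)` makes the temporal envelope half-width ±221 ms, which resolves the
"±1 Hz" spectral-width notation as a 2 Hz full width.  Envelopes are
expressed as percent change against the -600..-230 ms pre-cue baseline per
channel, averaged over the fixed 22-electrode posterior cluster (a top-k
spectral-amplitude strategy is also available), and collapsed across the
frequency-to-plane counterbalancing so each subject contributes one attended
and one ignored course.

Group inference: running FDR-corrected (Benjamini-Hochberg, q = 0.05) paired
t-tests of each condition against baseline and between conditions across
post-cue timepoints, excluding one temporal filter width (441 ms) at each
epoch edge where the envelope is unreliable; mean amplitudes in the
506-948 ms window go into a paired t-test with a default-prior (JZS, Cauchy
scale sqrt(2)/2) Bayes factor and Cousineau-Morey within-subject CIs.

## ERP analysis

Continuous data are low-passed at 11.5 Hz (Hamming windowed-sinc, -6 dB at
13.25 Hz, >50 dB by 15 Hz so the tagged oscillations cannot bias the
transients; applied as a single centered convolution, which is exactly
zero-phase).  Epochs of -100..700 ms are taken around coherent-motion events
with correct behavioral outcomes only (hits for attended events, correct
rejections for ignored), run through the same rejection / reference / CSD
chain, and baseline-corrected (-100..0 ms).  Channels are averaged within a
bilateral parieto-occipital cluster for the selection negativity (window
200-350 ms) and a centro-parietal cluster for the P3b (400-600 ms); the
per-subject window means enter paired frequentist and Bayesian t-tests.
Event epochs are extracted independently; with >= 1100 ms between onsets and
700 ms epochs they cannot overlap within a trial.

Because the analysis is in CSD units, recovery of injected effects is judged
against the ground-truth components forward-projected through the same
linear operators (filter, baseline, average reference, Laplacian, cluster
means) — `expected_window_contrasts` computes this analytically, including
cross-component filter smearing.

## Behavior

Presses within 200 ms (inclusive) to 1000 ms (exclusive) of an event are
matched to the earliest event whose window has not yet consumed a press;
attended matches are hits, ignored matches false alarms, unmatched presses
spurious (not false alarms — false alarms are defined as responses to
ignored events).  d' uses the log-linear extreme-rate correction
(+0.5 / +1; the alternative 1/(2N) clipping rule is selectable — the cited
correction's formula is not printed, and log-linear is the standard choice
for extreme rates).  The same- vs different-frequency control comparison
uses exact Wilcoxon signed-rank tests (n <= 25) and a rank-based Bayes
factor computed by applying the JZS Bayes factor to van der Waerden normal
scores of the differences — an approximation to the latent-normal Gibbs
approach of the literature, invariant under monotone transforms.

## Statistical core: numerical notes

The JZS Bayes factor is evaluated as a likelihood-ratio integral over the
variance-mixture representation of the Cauchy prior, in log space over
log g with the integrand's turnover point pinned as a quadrature breakpoint;
this is stable for arbitrarily large |t| (tolerance 1e-6, verified against
an independent effect-scale quadrature to 1e-4 and against pingouin).  At
`t(22) = 0.114` it returns BF10 = 0.220, matching the published value for
that comparison.  Wilcoxon uses the exact null distribution up to n = 25 and
the continuity-corrected normal approximation above.  All p-values are
two-sided.

## Validation study sizes

Chosen as the package's standard validation configuration:

* SSVEP recovery: 20 replicate cohorts of 23 subjects x 120 event-free
  trials (the full study had 480); grand-mean window change recovered within
  -30 ± 5 points, between-condition Bayes factors' median < 1.
* Sensitivity control: one cohort with attended +10 % / ignored -20 %
  envelopes; the between-condition window test must fire.
* ERP recovery: two cohorts of 23 subjects x 480 event trials (the full
  event-trial composition); attended-vs-ignored contrasts recovered in
  direction and within ±15 % of the forward-projected injection.  A single
  cohort's estimate scatters by ~9 % (1 SE), hence the two-cohort average.
* Calibration: 10,000 null t-tests (type-I error), 500 null running-FDR
  replicates (family-wise false-positive fraction <= q plus Monte-Carlo
  error).

## Known limitations

* The blink threshold rule and the channel-scan parameterization are
  reasoned stand-ins for unpublished procedures; results on real data will
  differ in the rejection bookkeeping.
* The rank-based Bayes factor is a normal-scores approximation, not the
  cited sampler; values can differ numerically from published ones.
* The spherical-spline Laplacian assumes a spherical head; no realistic
  geometry is attempted.
* Percent-change SSVEP courses carry a small positive envelope-noise
  (Rician) bias at low-SNR channels; at the generator's default SNR this
  biases the recovered -30 % modulation by about +3 points, which is inside
  the recovery band but visible in the acceptance numbers.
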