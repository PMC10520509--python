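# Methods notes

This note records the model assumptions, parameter choices and numerical
decisions behind `artonset`, in the spirit of a methods appendix. It
states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## The detection problem

EEG recorded during fMRI carries two structured artefacts. The
gradient-switch (GS) artefact is a broadband burst (a sum of sinusoids
from the gradient and RF waveforms) repeating *exactly* at the slice or
volume period — millivolts against microvolt EEG. The cardioballistic
(CB) artefact is produced by cardiac-related electrode and scalp motion
in the static field: quasi-periodic at the heart rate (RR intervals
600–1200 ms in healthy adults), strongest over frontotemporal sites, and
drifting in amplitude and shape over time. Average-artefact-subtraction
style correction needs one onset label per artefact occurrence; this
package computes those labels from the EEG itself.

Both detectors label the artefact *peak* rather than a leading edge.
Downstream correction only needs a consistent point per artefact cycle,
so any constant offset between the labelled point and a trigger-style
onset is irrelevant; the evaluation machinery makes this explicit by
removing the median signed offset before matching (configurable).

## GS detector

* **Expected structure.** Volume mode: count = `n_volumes`, spacing =
  `TR`; slice mode: count = `n_volumes·n_slices`, spacing =
  `TR/n_slices`. Fractional spacing (slice mode) is kept as a float and
  rounded only inside the periodicity comparison. Multiband sequences
  are handled by supplying the number of RF excitations per volume as
  the slice count — no special code path.
* **Threshold schedule.** The initial threshold (median across channels
  of the per-channel max |amplitude|) is lowered geometrically, factor
  0.9 per iteration, floored at 5% of the initial value, at most 50
  iterations per channel. Geometric decay reaches any burst amplitude in
  a bounded number of steps; the floor and cap bound the work on
  channels with no artefact. Once the peak count exceeds the count
  allowance the channel iteration stops early — lowering the threshold
  can only add peaks.
* **Peak picking** uses absolute amplitude (burst polarity varies by
  channel) with a minimum peak distance of half the expected spacing:
  large enough to suppress intra-burst maxima, small enough not to
  impose the periodicity that the check is supposed to *test*.
* **Acceptance rule.** Mode of inter-peak intervals within ±2 samples of
  the expected spacing, count within ±7 plus the dummy-scan allowance.
  The ±7 allowance is interpreted as *in addition to* dummy-scan
  artefacts, and both tolerances are exposed in `GsSearchConfig`.
* **Channel acceptance.** The unattended default (`accept_exact_count`)
  keeps scrolling (more decay iterations, further channels) until
  exactly the expected count plus dummy artefacts is labelled. A
  transiently passing threshold can clip a subset of bursts when burst
  peak heights straddle it within the noise; requiring the exact count
  rejects those states at no cost — if no exact-count candidate exists,
  the best periodicity-passing candidate is returned with a warning.
  `accept_first_pass` restores plain first-pass behaviour, and a custom
  callback can reproduce the interactive confirm/skip workflow.

## CB detector

* **High-pass.** 1 Hz cutoff, 1 Hz transition bandwidth, linear-phase
  FIR (Hamming design, `N ≈ 3.3·fs/transition` taps, odd), applied with
  centred convolution so the group delay cancels exactly. A literal
  five-tap FIR cannot realise a 1 Hz high-pass at 5 kHz; the cutoff and
  transition bandwidth are what determine behaviour, so the order is
  derived from them and exposed through the transition-bandwidth
  parameter.
* **Segmentation.** Non-overlapping 20 s segments; a trailing remainder
  is merged into the final segment so no data is unlabelled.
* **Template.** Reference = mean of two zero-meaned windows
  (peak ± RtoR/2, window length RtoR+1, kernel centre at
  `floor(len/2)`); refinement averages all candidate windows (local
  maxima at min distance RtoR − 10) with Pearson r ≥ 0.7 against the
  reference. The reference peaks re-enter the candidate set naturally
  (r ≈ 1), so they are not force-added twice. Fewer than two qualifying
  windows ⇒ the reference kernel is kept and flagged.
* **Matched filter.** Sliding inner product without time reversal,
  aligned so a kernel copy with its maximum at sample *p* scores
  maximally at *p*. (For the near-symmetric kernels involved, the
  distinction from convolution is immaterial; correlation gives the
  clean alignment contract.)
* **Score peaks.** Height ≥ mean + 2 SD of the segment's score series,
  spacing ≥ 4/5 kernel length (higher peak wins), plus a topographic
  prominence of ≥ 1 SD to suppress shoulder maxima — the prominence
  clause is this package's addition.
* **Segment boundaries.** Matched filtering runs on context-padded
  segments (pad = kernel length) and each onset is assigned to the
  segment containing it, so beats straddling a boundary are neither lost
  nor double-counted; a final cross-segment pass deduplicates any
  residual near-coincident pair, keeping the higher score.
* **Automatic peak provider.** The beat period is estimated per channel
  from the autocorrelation of the signal *envelope* (smoothed squared
  signal, 25 ms Gaussian) within 600–1600 ms lags. The envelope is used
  because RR jitter decorrelates the oscillatory artefact carrier at lag
  RR, while the envelope is phase-free. Channels must clear a normalised
  autocorrelation floor of 0.3 (evidence of periodicity); among those,
  the channel with the largest *unnormalised* peak — the most periodic
  artefact power — is selected, which reliably prefers the
  frontotemporal-type leads that carry the artefact best. The returned
  pair is the strongest pair of consecutive smoothed-signal peaks whose
  spacing best matches the period estimate and whose windows fit the
  segment. Peak localisation is noise-limited to a few milliseconds;
  this only shifts the template window, which the refinement and the
  matched filter absorb.

## Metrics

Greedy one-to-one nearest matching within an explicit tolerance
(defaults: ±100 ms for CB; half the burst period for GS), optionally
after median-offset removal (see above). "Specificity" is kept in its
literature sense TP/(TP+FP) — mathematically a positive predictive
value; the name and formula are preserved deliberately. Interval
kurtosis is the biased, non-excess Pearson estimator (normal ⇒ 3). The
reference kurtosis 4.0833 (outside-scanner ECG inter-beat intervals) is
a documented constant that callers pass explicitly. The physiological
range 600–1200 ms is applied with inclusive bounds. ECG R-peak
reference detection: 1 Hz high-pass, then local maxima ≥ 150 µV
(per-subject override possible, e.g. 400 µV) spaced ≥ 300 ms.

## Synthetic data

The generator emulates the structure the detectors rely on, not EEG
physiology at large:

* background = pink (1/f) noise (70% variance) + 10 Hz alpha (30%),
  per-channel SD 15 µV;
* GS bursts: per channel a fixed sum of three sinusoids (200–800 Hz,
  random phases) under a Hann envelope filling the whole period ("no
  break before the next acquisition"), tiled exactly — so per-channel
  peak positions are strictly periodic; peak amplitude 8 mV; the first
  5 bursts model dummy scans. Ground truth is the envelope centre per
  burst; channel peaks sit at a constant per-channel offset from it,
  which offset-corrected matching absorbs.
* CB: Gaussian-windowed 7 Hz wave (support ≈ 0.4·RR, unit peak at its
  centre sample) at each beat + 210 ms, amplitude 200 µV × per-beat
  jitter U[0.7, 1.3] × slow per-channel gain drift (±15% over the
  recording), frontotemporal-type channels weighted strongest;
* RR ~ N(900, 50) ms truncated by resampling to [600, 1200] ms — so the
  ground-truth physiological accuracy is exactly 100%, a clean anchor;
* ECG: Mexican-hat QRS wavelet (≈2 ms scale, 800 µV) at each R time over
  0.15/0.3 Hz baseline wander and 10 µV noise.

Default duration is 320 s: the 155 bursts of the default protocol need
310 s, plus a 2 s lead-in and a tail. Everything is a pure function of
the seed.

What the surrogates do **not** model: saturated or flat channels,
helium-pump and motion artefacts (beyond the test suite's injected
motion bursts), realistic head-volume conduction, heart-rate drift or
ectopic beats, and scanner clock drift. Passing tests therefore show the
algorithms implement their specifications and recover truth under
realistic amplitude/jitter regimes — not that performance on any
particular clinical recording will match.

CB validation runs on surrogates generated without the GS train
(`include_gs=False`): in a real pipeline the gradient artefact is
removed before CB detection, and an 8 mV burst train would otherwise
bury a 200 µV artefact. GS validation uses the full compound recording.

## Problem sizes and determinism

The validation batteries use 20 seeds per detector at the full study
conditions (320 s at 5000 Hz, 8 EEG channels + ECG); unit tests use
shorter recordings with identical structure (16–60 s). All randomness
flows from explicit seeds; detection itself is deterministic, and
repeated runs are byte-identical.

## Known limitations

* The GS detector assumes the artefact train is uninterrupted and the
  acquisition parameters are correct; sparse-burst protocols with long
  gaps between volumes are untested.
* The CB automatic provider needs at least one channel with visible
  cardiac-band periodicity per segment; segments failing that are
  skipped (reported, not silently dropped).
* Heart rates outside 37–100 bpm (lag window 600–1600 ms) defeat the
  automatic period estimate; the manual provider interface remains
  available for such data.
* EDF support is limited to homogeneous per-signal sampling rates; the
  writers (BrainVision INT_16 multiplexed, 16-bit EDF with 1 s records)
  cover what the simulator produces, not the full generality of either
  format.
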