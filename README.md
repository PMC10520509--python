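# artonset

Detection of **gradient-switch (GS)** and **cardioballistic (CB)** artefact
onsets in EEG recorded simultaneously with fMRI — directly from the EEG
itself, with as little as one usable channel and **no scanner volume
triggers or ECG recording**.

EEG acquired inside an MR scanner is contaminated by two dominant
artefacts: the gradient-switch artefact (bursts orders of magnitude above
brain activity, strictly periodic at the volume or slice acquisition
period TR) and the cardioballistic / ballistocardiogram artefact
(quasi-periodic at the heart rate, variable in shape and amplitude over
time and channels). Standard correction (average artefact subtraction,
optimal basis sets) needs the *onset* of every artefact occurrence.
Canonically those onsets come from recorded MR triggers (GS) or an ECG
channel (CB); when those side signals are missing or saturated, the
dataset is unusable. This package recovers the onsets from the EEG alone
and writes them in formats that standard correction software consumes.

## Methods

**GS onsets — iterative thresholding with periodicity constraints.**
From the acquisition parameters the expected artefact count `N` and
spacing `d` are known (volume mode: `N = n_volumes`, `d = TR`; slice
mode: `N = n_volumes · n_slices`, `d = TR / n_slices`). Starting from the
median over channels of the per-channel maximum |amplitude|, peaks above
the threshold are labelled per channel; a channel is accepted when

* `|mode(diff(peaks)) − d| ≤ 2` samples, and
* the peak count is within ±7 (plus dummy-scan artefacts) of `N`,

otherwise the threshold decays geometrically and eventually the next
channel is tried. Onsets from dummy scans are deleted from the front of
the accepted train.

**CB onsets — per-segment template matched filtering.** After a 1 Hz
linear-phase FIR high-pass, the recording is cut into 20 s segments.
Per segment, the peaks of two consecutive clear artefacts define the
beat spacing *RtoR*; each peak ± RtoR/2 is extracted, zero-meaned and
averaged into a reference template, which is then broadened with every
segment peak whose window correlates with it at Pearson *r* ≥ 0.7. The
refined template is slid across the segment (matched filter) and score
peaks at ≥ mean + 2 SD with spacing ≥ 4/5 of the template length are the
artefact onsets. An automatic peak provider (envelope-autocorrelation
period estimate + peak pair selection) replaces the manual labelling
step for unattended runs.

**Performance indices.** sensitivity `= 100·TP/(TP+FN)`, specificity
`= 100·TP/(TP+FP)` (positive predictive value, named as in the EEG-fMRI
validation literature), Pearson kurtosis of the inter-onset intervals
baselined against a reference kurtosis from outside-scanner ECG
inter-beat intervals (4.0833; 0 is optimal), and physiological accuracy
(the percentage of intervals inside 600–1200 ms).

A seeded synthetic generator (`artonset.synthetic`) produces
EEG-fMRI-like recordings — pink + alpha background, exactly periodic GS
bursts, cardiac-locked CB artefacts with truncated-normal RR intervals,
a QRS-like ECG channel — with ground-truth onset series, so the whole
pipeline is testable without any real recording.

## Worked example

```sh
# 52 s surrogate scan: 45 volumes + 5 dummy scans at TR 1000 ms, 5 kHz
artonset simulate --seed 0 --out demo/d --config sim.yaml
artonset gs-detect --vhdr demo/d/recording.vhdr --tr-ms 1000 --volumes 45 \
         --dummies 5 --out demo/gs.tsv
artonset evaluate --detected demo/gs.tsv --truth demo/d/gs_truth.tsv \
         --tol-ms 500 --out demo/gs_metrics.json
```

prints

```json
{
  "baselined_kurtosis": -1.4083353599458608,
  "kurtosis": 2.6749646400541396,
  "physio_accuracy_pct": 100.0,
  "sensitivity_pct": 100.0,
  "specificity_pct": 100.0
}
```

Every one of the 45 post-dummy gradient bursts was labelled
(sensitivity 100%) with no spurious detections (specificity 100%); the
kurtosis and physiological-accuracy fields describe the inter-onset
interval distribution and are the interesting part of the *CB* report
rather than the strictly periodic GS train. The cardiac pipeline on a
gradient-free surrogate (as after gradient-artefact correction):

```sh
artonset simulate --seed 3 --out demo/c --no-gs --duration-s 60
artonset cb-detect --vhdr demo/c/recording.vhdr --seg-len 20 --out demo/cb.tsv
artonset evaluate --detected demo/cb.tsv --truth demo/c/cb_truth.tsv \
         --tol-ms 100 --out demo/cb_metrics.json
```

again reports 100% sensitivity and specificity with physiological
accuracy 100% — every detected inter-beat interval lies inside
600–1200 ms, as the generator guarantees for the ground truth.

The library API mirrors the CLI: `gen_dataset`, `gs_detect`,
`cb_detect`, `evaluate` (see the docstrings in `artonset/`).

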