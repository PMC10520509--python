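"""Cardioballistic (CB) artefact onset detection by matched filtering.

The CB (ballistocardiogram) artefact arises from cardiac-related
electrode and scalp motion inside the static field.  It is quasi-periodic
at the heart rate, but its shape and amplitude drift over time and
differ across channels, so a single global template is inadequate.  The
procedure therefore works segment by segment:

1. High-pass the recording above 1 Hz (linear-phase FIR) to remove slow
   drifts.
2. Cut the chosen channel into non-overlapping segments (default 20 s;
   a trailing remainder is merged into the final segment).
3. Per segment, a *peak provider* nominates a channel and the peaks of
   two consecutive, clear CB artefacts.  Their spacing ("RtoR") sets the
   template window: each artefact ± RtoR/2 is extracted, zero-meaned,
   and the two are averaged into a reference template.
4. The template is refined: all segment peaks with minimum distance
   RtoR − 10 samples are candidate artefacts; windows correlating with
   the reference at Pearson r ≥ 0.7 are averaged into the final
   template.
5. The template is slid across the segment (matched filter); score
   peaks at least two standard deviations above the score mean, spaced
   at least 4/5 of the template length apart, are the artefact onsets.
6. Segment-local onsets are concatenated; boundary duplicates are
   removed keeping the higher-scoring detection.

The interactive provider of the original workflow (the user clicks two
peaks) is replaced for unattended runs by :func:`auto_peak_provider`,
which estimates the beat period from the envelope autocorrelation and
picks the pair automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .containers import EEGRecording, OnsetSeries
from .errors import NoPeriodicityFoundError, ParameterError, ValidationError
from .filters import highpass

__all__ = [
    "Segment",
    "ArtefactTemplate",
    "CbConfig",
    "segment_recording",
    "build_reference",
    "refine_template",
    "matched_filter",
    "detect_cb_onsets_in_segment",
    "auto_peak_provider",
    "cb_detect",
]


@dataclass
class Segment:
    """One channel's data within one time window of the recording."""

    channel_data: np.ndarray
    start_sample: int
    channel_label: str
    fs: float

    def __post_init__(self):
        self.channel_data = np.asarray(self.channel_data, dtype=float)
        if self.channel_data.ndim != 1 or self.channel_data.size < 2:
            raise ValidationError("segment must be a 1-D signal of length >= 2")
        if self.start_sample < 0:
            raise ValidationError("start_sample must be >= 0")

    def __len__(self) -> int:
        return int(self.channel_data.size)


@dataclass
class ArtefactTemplate:
    """Zero-mean CB template and the RtoR spacing used to build it."""

    kernel: np.ndarray
    rtor_samples: int
    n_contributing: int
    peak_offset: int
    fallback: bool = False

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float)
        peak = np.abs(self.kernel).max()
        if peak > 0 and abs(self.kernel.mean()) > 1e-9 * peak:
            raise ValidationError("template kernel must be zero-mean")
        if self.rtor_samples < 10:
            raise ValidationError("RtoR spacing implausibly small (< 10 samples)")
        if self.n_contributing < 2:
            raise ValidationError("template needs >= 2 contributing artefacts")

    def __len__(self) -> int:
        return int(self.kernel.size)


@dataclass
class CbConfig:
    """Tunables of the CB detection pipeline.

    The defaults encode the published procedure: 1 Hz high-pass, 20 s
    segments, r >= 0.7 template inclusion, RtoR − 10 candidate spacing,
    score threshold mean + 2 SD, inter-peak spacing 4/5 of the template
    length.  ``autocorr_min`` and the lag bounds govern the automatic
    peak provider only.
    """

    hp_cutoff_hz: float = 1.0
    hp_transition_bw_hz: float = 1.0
    seg_len_s: float = 20.0
    min_corr: float = 0.7
    rtor_slack_samples: int = 10
    prominence_sd: float = 2.0
    spacing_frac: float = 0.8
    autocorr_min: float = 0.3
    rr_lag_bounds_ms: Tuple[float, float] = (600.0, 1600.0)
    peak_smooth_ms: float = 3.0

    def __post_init__(self):
        if not 0 < self.min_corr < 1:
            raise ParameterError("min_corr must be in (0, 1)")
        if not 0 < self.spacing_frac <= 1:
            raise ParameterError("spacing_frac must be in (0, 1]")
        if self.seg_len_s <= 0:
            raise ParameterError("segment length must be positive")


def segment_bounds(n_samples: int, fs: float, seg_len_s: float) -> List[Tuple[int, int]]:
    """Non-overlapping, exhaustive (start, stop) windows.

    A trailing remainder shorter than ``seg_len_s`` is merged into the
    final window so no data is left unlabelled.
    """
    seg_len = int(round(seg_len_s * fs))
    if seg_len < 2:
        raise ParameterError("segment length below 2 samples")
    n_full = n_samples // seg_len
    if n_full == 0:
        return [(0, n_samples)]
    bounds = [(i * seg_len, (i + 1) * seg_len) for i in range(n_full)]
    if n_full * seg_len < n_samples:  # merge remainder into last window
        bounds[-1] = (bounds[-1][0], n_samples)
    return bounds


def segment_recording(rec: EEGRecording, seg_len_s: float) -> List[List[Segment]]:
    """Cut a recording into per-window channel segment sets.

    Returns one list of :class:`Segment` (one per channel, recording
    order) per time window.
    """
    out = []
    for s0, s1 in segment_bounds(rec.n_samples, rec.fs, seg_len_s):
        out.append(
            [
                Segment(rec.data[i, s0:s1], s0, lab, rec.fs)
                for i, lab in enumerate(rec.channel_labels)
            ]
        )
    return out


def _window_bounds(peak: int, rtor: int) -> Tuple[int, int]:
    """Window of length rtor + 1 with the peak at index (rtor + 1) // 2."""
    c = (rtor + 1) // 2
    return peak - c, peak - c + rtor + 1


def build_reference(seg: Segment, peak1: int, peak2: int) -> ArtefactTemplate:
    """Average two manually (or automatically) labelled artefacts into a
    reference template.

    Each artefact is extracted as peak ± RtoR/2 (window length
    RtoR + 1), zero-meaned, and the two windows are averaged.
    """
    if not peak1 < peak2:
        raise ValidationError("peak1 must precede peak2")
    rtor = int(peak2 - peak1)
    windows = []
    for name, p in (("peak1", peak1), ("peak2", peak2)):
        a, b = _window_bounds(int(p), rtor)
        if a < 0 or b > len(seg):
            raise ValidationError(
                f"window around {name} (sample {p}) falls outside the segment"
            )
        w = seg.channel_data[a:b]
        windows.append(w - w.mean())
    kernel = np.mean(windows, axis=0)
    kernel = kernel - kernel.mean()
    return ArtefactTemplate(
        kernel=kernel,
        rtor_samples=rtor,
        n_contributing=2,
        peak_offset=int(np.argmax(kernel)),
    )


def refine_template(seg: Segment, ref: ArtefactTemplate, cfg: Optional[CbConfig] = None
                    ) -> ArtefactTemplate:
    """Broaden the reference template with every artefact it resembles.

    Candidate peaks are local maxima with minimum distance
    RtoR − ``rtor_slack_samples``.  Each candidate with a fully in-bounds
    window is zero-meaned and correlated (Pearson) with the reference
    kernel; windows with r ≥ ``min_corr`` are averaged, always including
    the two reference windows.  If no candidate qualifies the reference
    kernel is returned unchanged with ``fallback=True``.
    """
    cfg = cfg or CbConfig()
    rtor = ref.rtor_samples
    min_dist = max(1, rtor - cfg.rtor_slack_samples)
    cand, _ = signal.find_peaks(seg.channel_data, distance=min_dist)
    accepted: List[np.ndarray] = []
    n_ok = 0
    for q in cand:
        a, b = _window_bounds(int(q), rtor)
        if a < 0 or b > len(seg):
            continue
        w = seg.channel_data[a:b]
        w = w - w.mean()
        denom = np.linalg.norm(w) * np.linalg.norm(ref.kernel)
        if denom == 0:
            continue
        r = float(np.dot(w, ref.kernel) / denom)
        if r >= cfg.min_corr:
            accepted.append(w)
            n_ok += 1
    if n_ok < 2:  # a mean over < 2 windows is no template; keep the reference
        out = ArtefactTemplate(
            kernel=ref.kernel.copy(),
            rtor_samples=rtor,
            n_contributing=ref.n_contributing,
            peak_offset=ref.peak_offset,
            fallback=True,
        )
        return out
    kernel = np.mean(accepted, axis=0)
    kernel = kernel - kernel.mean()
    return ArtefactTemplate(
        kernel=kernel,
        rtor_samples=rtor,
        n_contributing=n_ok,
        peak_offset=int(np.argmax(kernel)),
    )


def matched_filter(seg: Segment, tmpl) -> np.ndarray:
    """Slide the zero-mean template across the segment.

    The score at sample ``p`` is the inner product of the kernel with
    the data window whose *kernel peak position* lands on ``p``; hence
    when the segment contains an exact copy of the kernel with its
    maximum at ``p``, the score attains its maximum at ``p``.  Output
    length equals the segment length; positions whose window overhangs
    the segment get score 0.

    ``tmpl`` is an :class:`ArtefactTemplate` or a bare 1-D kernel array
    (peak offset then taken at its argmax).
    """
    if isinstance(tmpl, ArtefactTemplate):
        kernel, peak_offset = tmpl.kernel, tmpl.peak_offset
    else:
        kernel = np.asarray(tmpl, dtype=float)
        peak_offset = int(np.argmax(kernel))
    n, m = len(seg), kernel.size
    if m >= n:
        raise ValidationError("kernel must be shorter than the segment")
    valid = signal.correlate(seg.channel_data, kernel, mode="valid")
    score = np.zeros(n)
    score[peak_offset : peak_offset + valid.size] = valid
    return score


def detect_cb_onsets_in_segment(score: np.ndarray, tmpl: ArtefactTemplate,
                                cfg: Optional[CbConfig] = None,
                                fs: float = 1.0) -> OnsetSeries:
    """Pick artefact onsets from a matched-filter score series.

    Peaks must reach mean + ``prominence_sd``·SD of the score, show a
    topographic prominence of at least one SD, and be spaced at least
    ``spacing_frac`` of the kernel length apart (the higher peak wins a
    spacing conflict).
    """
    cfg = cfg or CbConfig()
    score = np.asarray(score, dtype=float)
    mu, sd = float(score.mean()), float(score.std())
    height = mu + cfg.prominence_sd * sd
    distance = max(1.0, cfg.spacing_frac * len(tmpl))
    peaks, _ = signal.find_peaks(
        score, height=height, distance=distance, prominence=sd if sd > 0 else None
    )
    return OnsetSeries(peaks.astype(np.int64), fs, "CB")


def _envelope(x: np.ndarray, fs: float, smooth_ms: float = 25.0) -> np.ndarray:
    """Smoothed instantaneous power — a phase-free activity envelope."""
    sigma = max(1.0, smooth_ms * fs / 1000.0)
    return gaussian_filter1d(np.square(x - x.mean()), sigma)


def _autocorr_strength(x: np.ndarray, fs: float,
                       lag_bounds_ms: Tuple[float, float]) -> Tuple[float, float, int]:
    """Envelope-autocorrelation peak in the cardiac lag window.

    Returns the normalised peak (0–1, the periodicity *evidence*), the
    unnormalised peak (the periodic artefact *power*, used to rank
    channels), and the lag in samples.
    """
    env = _envelope(x, fs)
    env = env - env.mean()
    n = env.size
    lo = int(round(lag_bounds_ms[0] * fs / 1000.0))
    hi = min(int(round(lag_bounds_ms[1] * fs / 1000.0)), n - 2)
    if hi <= lo:
        return 0.0, 0.0, 0
    ac = signal.correlate(env, env, mode="full", method="fft")[n - 1 :]
    if ac[0] <= 0:
        return 0.0, 0.0, 0
    window = ac[lo : hi + 1]
    lag = lo + int(np.argmax(window))
    return float(ac[lag] / ac[0]), float(ac[lag]), lag


def auto_peak_provider(segments: Sequence[Segment], cfg: Optional[CbConfig] = None
                       ) -> Tuple[str, int, int]:
    """Non-interactive stand-in for manual peak labelling.

    Estimates the beat period per channel from the envelope
    autocorrelation within the physiological lag window, selects the
    channel with the strongest periodicity, and returns the peaks of two
    consecutive clear artefacts whose spacing matches that period.
    """
    cfg = cfg or CbConfig()
    if not segments:
        raise ParameterError("need at least one channel segment")
    best = None  # qualifying channel with the most periodic artefact power
    best_norm = 0.0
    for seg in segments:
        norm, power, lag = _autocorr_strength(seg.channel_data, seg.fs,
                                              cfg.rr_lag_bounds_ms)
        best_norm = max(best_norm, norm)
        if norm < cfg.autocorr_min or lag == 0:
            continue
        if best is None or power > best[0]:
            best = (power, lag, seg)
    if best is None:
        raise NoPeriodicityFoundError(
            f"no channel shows cardiac-band periodicity (best autocorrelation "
            f"{best_norm:.3f} < {cfg.autocorr_min})"
        )
    _, lag, seg = best
    # light smoothing so sample noise does not dislodge the peak sample
    sigma = max(1.0, cfg.peak_smooth_ms * seg.fs / 1000.0)
    smooth = gaussian_filter1d(seg.channel_data, sigma)
    cand, _ = signal.find_peaks(smooth, distance=max(1, int(0.7 * lag)))
    if cand.size < 2:
        raise NoPeriodicityFoundError("fewer than two candidate artefact peaks")
    heights = smooth[cand]
    pairs = []
    margin = int(np.ceil(0.55 * lag))
    for i in range(cand.size - 1):
        spacing = cand[i + 1] - cand[i]
        if not (0.75 * lag <= spacing <= 1.3 * lag):
            continue
        if cand[i] < margin or cand[i + 1] > len(seg) - margin:
            continue  # reference windows would overhang the segment
        pairs.append((min(heights[i], heights[i + 1]), spacing, int(cand[i]), int(cand[i + 1])))
    if not pairs:
        raise NoPeriodicityFoundError("no consecutive peak pair matches the beat period")
    # among clearly strong pairs prefer spacing closest to the estimated
    # period (stabilises RtoR), ties broken toward the earlier pair
    h_best = max(p[0] for p in pairs)
    strong = [p for p in pairs if p[0] >= 0.6 * h_best]
    strong.sort(key=lambda p: (abs(p[1] - lag), p[2]))
    _, _, p1, p2 = strong[0]
    return seg.channel_label, p1, p2


PeakProvider = Callable[[Sequence[Segment], CbConfig], Tuple[str, int, int]]


def cb_detect(rec: EEGRecording, cfg: Optional[CbConfig] = None,
              peak_provider: Optional[PeakProvider] = None,
              exclude_labels: Sequence[str] = ("ECG",),
              ) -> Tuple[OnsetSeries, List[Dict]]:
    """Detect cardioballistic artefact onsets across a whole recording.

    Channels named in ``exclude_labels`` (the ECG electrode by default)
    do not take part: the method is meant to work from the EEG itself.
    Matched filtering uses context-padded segments so beats straddling a
    segment boundary are not lost; each onset is assigned to the segment
    containing it and boundary duplicates keep the higher score.

    Returns the concatenated onset series and one report dict per
    segment (channel used, template size, warnings).
    """
    cfg = cfg or CbConfig()
    peak_provider = peak_provider or auto_peak_provider
    keep = [l for l in rec.channel_labels if l not in exclude_labels]
    if not keep:
        raise ParameterError("no channels left after exclusion")
    work = highpass(rec.pick(keep), cfg.hp_cutoff_hz, cfg.hp_transition_bw_hz)
    n = work.n_samples
    bounds = segment_bounds(n, work.fs, cfg.seg_len_s)

    all_onsets: List[int] = []
    all_scores: List[float] = []
    all_spacing: List[int] = []
    reports: List[Dict] = []
    for s0, s1 in bounds:
        report: Dict = {"start": s0, "stop": s1, "warnings": []}
        reports.append(report)
        segs = [
            Segment(work.data[i, s0:s1], s0, lab, work.fs)
            for i, lab in enumerate(work.channel_labels)
        ]
        try:
            label, p1, p2 = peak_provider(segs, cfg)
            seg = segs[work.channel_labels.index(label)]
            ref = build_reference(seg, p1, p2)
            tmpl = refine_template(seg, ref, cfg)
        except (NoPeriodicityFoundError, ValidationError) as exc:
            report["warnings"].append(f"segment skipped: {exc}")
            continue
        if tmpl.fallback:
            report["warnings"].append("template refinement fell back to the reference")
        pad = len(tmpl)
        a, b = max(0, s0 - pad), min(n, s1 + pad)
        padded = Segment(work.channel(label)[a:b], a, label, work.fs)
        score = matched_filter(padded, tmpl)
        local = detect_cb_onsets_in_segment(score, tmpl, cfg, work.fs)
        spacing = int(np.ceil(cfg.spacing_frac * len(tmpl)))
        for q in local.onsets:
            g = int(q) + a
            if s0 <= g < s1:
                all_onsets.append(g)
                all_scores.append(float(score[q]))
                all_spacing.append(spacing)
        report.update(
            channel=label,
            rtor_samples=tmpl.rtor_samples,
            n_contributing=tmpl.n_contributing,
            n_onsets=int(np.sum((np.asarray(local.onsets) + a >= s0)
                                & (np.asarray(local.onsets) + a < s1))),
        )

    # deduplicate across segment boundaries: of two detections closer
    # than the spacing rule allows, the higher-scoring one survives
    onsets = np.asarray(all_onsets, dtype=np.int64)
    scores = np.asarray(all_scores, dtype=float)
    spacings = np.asarray(all_spacing, dtype=np.int64)
    keep_mask = np.ones(onsets.size, dtype=bool)
    for i in range(1, onsets.size):
        j = i - 1
        while j >= 0 and not keep_mask[j]:
            j -= 1
        if j < 0:
            continue
        if onsets[i] - onsets[j] < min(spacings[i], spacings[j]):
            if scores[i] >= scores[j]:
                keep_mask[j] = False
            else:
                keep_mask[i] = False
    series = OnsetSeries(onsets[keep_mask], work.fs, "CB")
    return series, reports
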