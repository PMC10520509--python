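"""Gradient-switch (GS) artefact onset detection.

The MR gradient train contaminates simultaneously recorded EEG with
bursts one to three orders of magnitude larger than brain activity,
repeating exactly at the volume (or slice) acquisition period.  Because
amplitude and periodicity are both known a priori, the onsets can be
found directly in the EEG without any scanner trigger channel:

1. Compute an initial amplitude threshold as the median over channels of
   each channel's maximum absolute amplitude.
2. For each channel in recording order, label all peaks above the
   threshold (absolute amplitude; burst polarity varies by channel) with
   a minimum inter-peak distance of half the expected artefact period.
3. Accept the channel if the mode of the inter-peak intervals is within
   two samples of the expected artefact duration and the number of peaks
   is within ±7 (plus dummy-scan artefacts) of the expected count;
   otherwise lower the threshold geometrically and retry, moving to the
   next channel once the threshold floor or iteration cap is reached.
4. Delete the first onsets attributable to dummy scans.

The expected count is the number of volumes (volume mode) or
volumes × slices (slice mode); the expected duration is TR, or
TR / n_slices in slice mode.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple

import numpy as np
from scipy import signal

from .containers import AcquisitionParams, DetectionReport, EEGRecording, OnsetSeries
from .errors import NoArtefactChannelError, ParameterError, ValidationError

__all__ = [
    "ExpectedArtifacts",
    "GsSearchConfig",
    "expected_artifact_params",
    "initial_threshold",
    "find_peaks_above",
    "periodicity_check",
    "remove_dummy_onsets",
    "gs_detect",
    "accept_first_pass",
    "accept_exact_count",
]


@dataclass
class ExpectedArtifacts:
    """Expected GS artefact count and spacing derived from acquisition
    parameters.  ``duration_samples`` may be fractional in slice mode."""

    n_expected: int
    duration_samples: float
    n_dummy_onsets: int = 0

    def __post_init__(self):
        if self.n_expected < 1:
            raise ParameterError("expected artefact count must be >= 1")
        if not self.duration_samples > 0:
            raise ParameterError("artefact duration must be positive")


@dataclass
class GsSearchConfig:
    """Tunables of the iterative threshold search.

    ``interval_tol_samples`` and ``count_tol`` are the periodicity and
    count tolerances of the acceptance rule (two samples and ±7).  The
    threshold schedule (geometric decay by ``threshold_decay`` down to
    ``threshold_floor_frac`` of the initial value, at most ``max_iters``
    steps) and the minimum peak distance (``min_peak_distance_frac`` of
    the artefact duration) are implementation choices; see the methods
    note.
    """

    interval_tol_samples: int = 2
    count_tol: int = 7
    threshold_decay: float = 0.9
    threshold_floor_frac: float = 0.05
    max_iters: int = 50
    min_peak_distance_frac: float = 0.5

    def __post_init__(self):
        if not 0 < self.threshold_decay < 1:
            raise ParameterError("threshold_decay must be in (0, 1)")
        if self.interval_tol_samples < 0 or self.count_tol < 0:
            raise ParameterError("tolerances must be >= 0")


def expected_artifact_params(acq: AcquisitionParams, fs: float) -> ExpectedArtifacts:
    """Translate MR acquisition parameters into expected artefact
    count/spacing at the EEG sampling rate."""
    if acq.mode == "volume":
        return ExpectedArtifacts(
            n_expected=acq.n_volumes,
            duration_samples=acq.tr_ms * fs / 1000.0,
            n_dummy_onsets=acq.n_dummy,
        )
    # slice mode: one artefact per slice excitation
    return ExpectedArtifacts(
        n_expected=acq.n_volumes * acq.n_slices,
        duration_samples=(acq.tr_ms / acq.n_slices) * fs / 1000.0,
        n_dummy_onsets=acq.n_dummy * acq.n_slices,
    )


def initial_threshold(rec: EEGRecording) -> float:
    """Median over channels of the per-channel maximum absolute
    amplitude (µV) — the starting threshold of the search."""
    maxima = np.abs(rec.data).max(axis=1)
    return float(np.median(maxima))


def find_peaks_above(channel: np.ndarray, threshold: float,
                     min_distance: int, fs: float = 1.0) -> OnsetSeries:
    """Local maxima of ``|channel|`` strictly above ``threshold``.

    When two qualifying peaks are closer than ``min_distance`` samples
    the higher one survives (greedy, highest first); equal-height ties
    are resolved toward the earlier index.
    """
    if min_distance < 1:
        raise ParameterError("min_distance must be >= 1")
    x = np.abs(np.asarray(channel, dtype=float))
    cand, _ = signal.find_peaks(x)
    cand = cand[x[cand] > threshold]
    if cand.size == 0:
        return OnsetSeries(np.empty(0, dtype=np.int64), fs, "GS")
    # greedy selection: sort by (-height, index), keep peaks at least
    # min_distance from every already-kept peak
    order = np.lexsort((cand, -x[cand]))
    kept: list[int] = []
    for idx in cand[order]:
        pos = bisect_left(kept, idx)
        if pos > 0 and idx - kept[pos - 1] < min_distance:
            continue
        if pos < len(kept) and kept[pos] - idx < min_distance:
            continue
        insort(kept, int(idx))
    return OnsetSeries(np.asarray(kept, dtype=np.int64), fs, "GS")


def periodicity_check(series: OnsetSeries, exp: ExpectedArtifacts,
                      cfg: Optional[GsSearchConfig] = None) -> Tuple[bool, Dict]:
    """Test whether a peak train matches the expected GS periodicity.

    Passes iff the mode of the inter-peak intervals is within
    ``interval_tol_samples`` of the (rounded) expected duration AND the
    peak count is within ``count_tol`` plus the dummy-scan allowance of
    the expected count.
    """
    cfg = cfg or GsSearchConfig()
    diag: Dict = {
        "n_peaks": len(series),
        "mode_interval": None,
        "expected_interval": int(round(exp.duration_samples)),
        "expected_count": exp.n_expected,
        "count_allowance": cfg.count_tol + exp.n_dummy_onsets,
    }
    if len(series) < 2:
        diag["reason"] = "insufficient peaks"
        return False, diag
    diffs = np.diff(series.onsets)
    values, counts = np.unique(diffs, return_counts=True)
    mode_interval = int(values[np.argmax(counts)])  # ties -> smallest interval
    diag["mode_interval"] = mode_interval
    interval_ok = abs(mode_interval - round(exp.duration_samples)) <= cfg.interval_tol_samples
    count_ok = abs(len(series) - exp.n_expected) <= cfg.count_tol + exp.n_dummy_onsets
    diag["interval_ok"] = bool(interval_ok)
    diag["count_ok"] = bool(count_ok)
    return bool(interval_ok and count_ok), diag


def remove_dummy_onsets(series: OnsetSeries, exp: ExpectedArtifacts) -> OnsetSeries:
    """Delete the leading onsets produced by dummy scans."""
    if len(series) < exp.n_dummy_onsets:
        raise ValidationError(
            f"cannot remove {exp.n_dummy_onsets} dummy onsets from "
            f"{len(series)} detected onsets"
        )
    out = OnsetSeries(series.onsets[exp.n_dummy_onsets:], series.fs, series.label)
    if len(out) != exp.n_expected:
        import warnings

        warnings.warn(
            f"retained {len(out)} GS onsets but expected {exp.n_expected}",
            stacklevel=2,
        )
    return out


def accept_first_pass(channel_label: str, onsets: OnsetSeries,
                      exp: ExpectedArtifacts) -> bool:
    """Acceptor that takes the first channel passing the periodicity
    check, regardless of the exact peak count."""
    return True


def accept_exact_count(channel_label: str, onsets: OnsetSeries,
                       exp: ExpectedArtifacts) -> bool:
    """Acceptor that keeps scrolling until exactly the expected number
    of artefacts plus dummy-scan artefacts is labelled.

    This mirrors the recommended unattended practice: continue until
    only the expected count (plus dummies) is detected, which rejects
    thresholds that clip a subset of bursts or pick up scanner
    calibration transients.
    """
    return len(onsets) == exp.n_expected + exp.n_dummy_onsets


Acceptor = Callable[[str, OnsetSeries, ExpectedArtifacts], bool]


def gs_detect(rec: EEGRecording, acq: AcquisitionParams,
              cfg: Optional[GsSearchConfig] = None,
              acceptor: Optional[Acceptor] = None,
              ) -> Tuple[OnsetSeries, DetectionReport]:
    """Detect gradient-switch artefact onsets in a recording.

    Iterates channels in recording order; per channel the threshold
    starts at :func:`initial_threshold` and decays geometrically until
    the periodicity check passes and the acceptor approves, the floor is
    reached, or ``max_iters`` is exhausted.  Dummy-scan onsets are
    removed from the accepted train.

    The default acceptor is :func:`accept_exact_count`; if no candidate
    ever satisfies it, the best periodicity-passing candidate (count
    closest to expected, earliest channel) is returned with
    ``report.accepted = False``.  If no channel ever passes the
    periodicity check, :class:`NoArtefactChannelError` is raised with
    the best diagnostics per channel.
    """
    cfg = cfg or GsSearchConfig()
    acceptor = acceptor or accept_exact_count
    exp = expected_artifact_params(acq, rec.fs)
    thr0 = initial_threshold(rec)
    floor = cfg.threshold_floor_frac * thr0
    min_dist = max(1, int(round(cfg.min_peak_distance_frac * exp.duration_samples)))
    count_limit = exp.n_expected + exp.n_dummy_onsets + cfg.count_tol

    best_per_channel: Dict[str, Dict] = {}
    fallback = None  # (count_gap, channel_order, onsets, report)

    for ch_idx, label in enumerate(rec.channel_labels):
        x = rec.data[ch_idx]
        thr = thr0
        trace = []
        best_diag = None
        for it in range(cfg.max_iters):
            trace.append((it, thr))
            peaks = find_peaks_above(x, thr, min_dist, rec.fs)
            ok, diag = periodicity_check(peaks, exp, cfg)
            if best_diag is None or diag["n_peaks"] > best_diag["n_peaks"]:
                best_diag = diag
            if ok:
                report = DetectionReport(
                    chosen_channel=label,
                    threshold_trace=list(trace),
                    n_peaks_found=len(peaks),
                    mode_interval_samples=diag["mode_interval"] or 0,
                    accepted=False,
                )
                if acceptor(label, peaks, exp):
                    report.accepted = True
                    onsets = remove_dummy_onsets(peaks, exp)
                    if len(onsets) != exp.n_expected:
                        report.warnings.append(
                            f"retained {len(onsets)} onsets, expected {exp.n_expected}"
                        )
                    return onsets, report
                gap = abs(len(peaks) - (exp.n_expected + exp.n_dummy_onsets))
                if fallback is None or (gap, ch_idx) < (fallback[0], fallback[1]):
                    fallback = (gap, ch_idx, peaks, report)
            # lowering the threshold can only add peaks: once the count
            # exceeds the allowance there is nothing left to find here
            if len(peaks) > count_limit:
                break
            thr *= cfg.threshold_decay
            if thr < floor:
                break
        best_per_channel[label] = best_diag or {"reason": "no iterations"}

    if fallback is not None:
        _, _, peaks, report = fallback
        report.warnings.append(
            "acceptor never satisfied; returning best periodicity-passing candidate"
        )
        onsets = remove_dummy_onsets(peaks, exp)
        return onsets, report

    raise NoArtefactChannelError(
        "no channel produced a peak train matching the expected GS periodicity",
        diagnostics=best_per_channel,
    )
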