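"""Core data containers shared by the detectors, metrics and generator.

Conventions
-----------
* Amplitudes are microvolts (µV) everywhere inside the package; readers
  convert at ingest.  The detection thresholds of the method (e.g. the
  150 µV R-peak floor) are specified in µV, so µV is the natural unit.
* Onset positions are 0-based sample indices.  The 1-based convention of
  BrainVision marker files is applied only at that file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ParameterError, ValidationError


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitude samples in µV.
    fs : float
        Sampling rate in Hz (> 0).
    channel_labels : list of str
        Unique channel names, one per row of ``data``.
    t0 : int
        Offset of the first sample relative to the original recording
        start, in samples (used when slicing recordings).
    """

    data: np.ndarray
    fs: float
    channel_labels: List[str]
    t0: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (n_channels, n_samples)")
        n_ch, n_samp = self.data.shape
        if n_ch < 1 or n_samp < 1:
            raise ValidationError("recording must have >= 1 channel and >= 1 sample")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != n_ch:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {n_ch} channels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise ValidationError("channel labels must be unique")
        bad = ~np.isfinite(self.data).all(axis=1)
        if bad.any():
            names = [l for l, b in zip(self.channel_labels, bad) if b]
            raise ValidationError(
                f"non-finite samples in channel(s): {', '.join(names)}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal of the named channel."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None
        return self.data[idx]

    def pick(self, labels: Sequence[str]) -> "EEGRecording":
        """Sub-recording containing only ``labels`` (order preserved)."""
        idx = [self.channel_labels.index(l) for l in labels]
        return EEGRecording(self.data[idx], self.fs, list(labels), self.t0)


@dataclass
class OnsetSeries:
    """Strictly increasing 0-based sample indices of detected artefacts.

    ``label`` tags the artefact class: ``"GS"`` (gradient switch),
    ``"CB"`` (cardioballistic) or ``"R"`` (ECG R-peak).
    """

    onsets: np.ndarray
    fs: float
    label: str = "GS"

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=np.int64).ravel()
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        if self.onsets.size and (np.diff(self.onsets) <= 0).any():
            raise ValidationError("onsets must be strictly increasing")
        if self.onsets.size and self.onsets[0] < 0:
            raise ValidationError("onsets must be non-negative")

    def __len__(self) -> int:
        return int(self.onsets.size)

    def __iter__(self):
        return iter(self.onsets.tolist())

    @property
    def times_s(self) -> np.ndarray:
        """Onset times in seconds."""
        return self.onsets / self.fs

    def intervals_ms(self) -> np.ndarray:
        """First differences of the onsets, in milliseconds."""
        return np.diff(self.onsets) * 1000.0 / self.fs

    def shifted(self, offset: int) -> "OnsetSeries":
        return OnsetSeries(self.onsets + int(offset), self.fs, self.label)


@dataclass
class AcquisitionParams:
    """MR acquisition parameters driving gradient-switch expectations.

    ``mode`` selects whether one artefact per volume ("volume") or one per
    slice ("slice") is expected.  For multiband sequences the caller
    supplies the number of radio-frequency excitations used to sample all
    slices as ``n_slices``.
    """

    tr_ms: float
    n_volumes: int
    n_slices: int = 1
    n_dummy: int = 0
    mode: str = "volume"

    def __post_init__(self):
        if not self.tr_ms > 0:
            raise ParameterError("TR must be positive")
        if self.n_volumes < 1:
            raise ParameterError("need at least one volume")
        if self.n_slices < 1:
            raise ParameterError("need at least one slice")
        if self.n_dummy < 0:
            raise ParameterError("dummy count cannot be negative")
        if self.mode not in ("volume", "slice"):
            raise ParameterError(f"mode must be 'volume' or 'slice', got {self.mode!r}")


@dataclass
class DetectionReport:
    """Audit trail of a gradient-switch detection run.

    ``threshold_trace`` holds (iteration, threshold µV) pairs for the
    chosen channel and is monotonically non-increasing in threshold.
    """

    chosen_channel: str = ""
    threshold_trace: List[Tuple[int, float]] = field(default_factory=list)
    n_peaks_found: int = 0
    mode_interval_samples: int = 0
    accepted: bool = False
    warnings: List[str] = field(default_factory=list)
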