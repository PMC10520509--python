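"""Zero-net-delay FIR filtering helpers.

The cardioballistic pipeline and the ECG R-peak reference both start by
high-pass filtering above 1 Hz to strip slow drifts.  We realise this as
a linear-phase (symmetric, odd-length) FIR designed with a Hamming
window from the requested transition bandwidth, applied with centred
("same") convolution so the group delay cancels exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EEGRecording
from .errors import ParameterError

__all__ = ["design_highpass", "highpass_array", "highpass"]


def design_highpass(cutoff_hz: float, fs: float, transition_bw_hz: float = 1.0) -> np.ndarray:
    """Design a linear-phase high-pass FIR.

    The number of taps follows the Hamming-window rule
    ``N ≈ 3.3 · fs / transition_bw`` (rounded up to odd, so the filter is
    type I and has an integer group delay).
    """
    if not 0 < cutoff_hz < fs / 2:
        raise ParameterError(f"cutoff {cutoff_hz} Hz outside (0, fs/2)")
    if transition_bw_hz <= 0:
        raise ParameterError("transition bandwidth must be positive")
    numtaps = int(np.ceil(3.3 * fs / transition_bw_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, cutoff_hz, window="hamming", pass_zero=False, fs=fs)


def highpass_array(x: np.ndarray, fs: float, cutoff_hz: float = 1.0,
                   transition_bw_hz: float = 1.0) -> np.ndarray:
    """High-pass filter along the last axis with zero net delay.

    Edges are where the symmetric kernel overhangs the data; the first
    and last ``(numtaps - 1) // 2`` samples are attenuated accordingly
    and should be trimmed by callers that care.
    """
    taps = design_highpass(cutoff_hz, fs, transition_bw_hz)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ParameterError("signal too short to filter")
    was_1d = x.ndim == 1
    x2 = np.atleast_2d(x)
    out = np.empty_like(x2)
    for i in range(x2.shape[0]):
        out[i] = signal.oaconvolve(x2[i], taps, mode="same")
    return out[0] if was_1d else out


def highpass(rec: EEGRecording, cutoff_hz: float = 1.0,
             transition_bw_hz: float = 1.0) -> EEGRecording:
    """Return a high-pass filtered copy of a recording (µV in, µV out)."""
    taps = design_highpass(cutoff_hz, rec.fs, transition_bw_hz)
    if rec.n_samples < 3:
        raise ParameterError("recording too short to filter")
    out = np.empty_like(rec.data)
    for i in range(rec.n_channels):
        out[i] = signal.oaconvolve(rec.data[i], taps, mode="same")
    return EEGRecording(out, rec.fs, rec.channel_labels, rec.t0)
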