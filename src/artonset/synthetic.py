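"""Seeded generator of EEG-fMRI-like recordings with ground truth.

No public recording with scanner triggers and ECG is available, so every
detector and metric in this package is exercised against synthetic
surrogates that emulate the salient structure of EEG acquired during
fMRI:

* background EEG: pink (1/f) noise plus a 10 Hz alpha component,
  per-channel SD ``background_sd_uv``;
* gradient-switch bursts: per channel a fixed sum of three sinusoids
  (200–800 Hz, random phases) under a Hann envelope, tiled at exactly
  the volume (or slice) period, peak amplitude ``gs_amplitude_mv`` —
  orders of magnitude above the EEG, as in real recordings; the first
  ``n_dummy`` bursts model dummy scans;
* cardioballistic artefacts: a Gaussian-windowed low-frequency wave
  placed at each cardiac beat plus a fixed conduction-style delay, with
  per-beat amplitude jitter, slow per-channel gain drift, and
  frontotemporal-dominant channel weighting;
* ECG: a sharp QRS-like wavelet at each R time over slow baseline
  wander and measurement noise.

RR intervals are drawn from a normal distribution truncated to the
physiological range, so the ground-truth physiological accuracy is
100% by construction.  Everything is a pure function of the
configuration (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal.windows import hann

from .containers import EEGRecording, OnsetSeries
from .errors import ParameterError

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "gen_background_eeg",
    "gen_gs_train",
    "gen_cardiac_train",
    "gen_cb_waveform",
    "gen_ecg",
    "gen_dataset",
]

_TEN_TEN = ["F7", "F8", "T7", "T8", "C3", "C4", "O1", "O2",
            "F3", "F4", "P3", "P4", "Fz", "Cz", "Pz", "Oz"]


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic recording.

    Acquisition values mirror a typical 3 T resting-state protocol
    (5000 Hz EEG, TR 2000 ms, 150 volumes, 36 slices, 5 dummy scans);
    ``duration_s`` leaves room for the dummy bursts plus a short
    artefact-free lead-in and tail.  ``ecg_delay_ms`` is the canonical
    cardiac-cycle-to-artefact delay assumption (210 ms).
    """

    fs: float = 5000.0
    duration_s: float = 320.0
    n_channels: int = 8
    tr_ms: float = 2000.0
    n_volumes: int = 150
    n_slices: int = 36
    n_dummy: int = 5
    mode: str = "volume"
    gs_amplitude_mv: float = 8.0
    gs_start_s: float = 2.0
    rr_mean_ms: float = 900.0
    rr_sd_ms: float = 50.0
    rr_bounds_ms: Tuple[float, float] = (600.0, 1200.0)
    cb_amplitude_uv: float = 200.0
    cb_drift_frac: float = 0.3
    ecg_r_amplitude_uv: float = 800.0
    ecg_delay_ms: float = 210.0
    background_sd_uv: float = 15.0
    include_gs: bool = True
    include_cb: bool = True
    include_ecg: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.duration_s < 0 or self.n_channels < 1:
            raise ParameterError("fs, duration and channel count must be positive")
        if not self.rr_bounds_ms[0] < self.rr_bounds_ms[1]:
            raise ParameterError("rr_bounds_ms must be ordered")
        if self.cb_drift_frac < 0 or self.cb_drift_frac >= 1:
            raise ParameterError("cb_drift_frac must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def channel_labels(self) -> List[str]:
        labs = list(_TEN_TEN[: self.n_channels])
        while len(labs) < self.n_channels:
            labs.append(f"EEG{len(labs) + 1}")
        return labs


@dataclass
class SyntheticDataset:
    """A synthetic recording with its ground-truth onset series."""

    recording: EEGRecording
    gs_truth: OnsetSeries
    cb_truth: OnsetSeries
    r_truth: OnsetSeries
    config: SimConfig
    gs_dummy_onsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def gen_background_eeg(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Pink-noise + alpha background, per-channel SD = background_sd_uv."""
    n = cfg.n_samples
    if n == 0:
        return np.zeros((cfg.n_channels, 0))
    out = np.empty((cfg.n_channels, n))
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # 1/f power spectrum
    t = np.arange(n) / cfg.fs
    for c in range(cfg.n_channels):
        white = rng.standard_normal(n)
        pink = np.fft.irfft(np.fft.rfft(white) * shaping, n)
        sd = pink.std()
        pink = pink / sd if sd > 0 else pink
        alpha = np.sqrt(2.0) * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        # 70% of the variance from pink noise, 30% from alpha
        mix = np.sqrt(0.7) * pink + np.sqrt(0.3) * alpha
        out[c] = cfg.background_sd_uv * mix / mix.std()
    return out


def _gs_period_samples(cfg: SimConfig) -> float:
    if cfg.mode == "volume":
        return cfg.tr_ms * cfg.fs / 1000.0
    if cfg.mode == "slice":
        return cfg.tr_ms / cfg.n_slices * cfg.fs / 1000.0
    raise ParameterError(f"unknown acquisition mode {cfg.mode!r}")


def gen_gs_train(cfg: SimConfig, rng: np.random.Generator
                 ) -> Tuple[np.ndarray, OnsetSeries, np.ndarray]:
    """Gradient-switch burst train.

    Returns the per-channel waveform addend, the ground-truth onset
    series of the non-dummy bursts (per-burst envelope-peak samples),
    and the dummy-burst onset samples.  Burst waveforms repeat exactly,
    so per-channel peak positions are strictly periodic.
    """
    n = cfg.n_samples
    period = _gs_period_samples(cfg)
    if cfg.mode == "volume":
        n_bursts = cfg.n_dummy + cfg.n_volumes
    else:
        n_bursts = (cfg.n_dummy + cfg.n_volumes) * cfg.n_slices
    start = int(round(cfg.gs_start_s * cfg.fs))
    if start + n_bursts * period > n:
        raise ParameterError(
            f"{n_bursts} bursts of {period:.1f} samples do not fit in "
            f"{n - start} samples after the lead-in"
        )
    amp = cfg.gs_amplitude_mv * 1000.0  # µV
    freqs = rng.uniform(200.0, 800.0, size=(cfg.n_channels, 3))
    amps = rng.uniform(0.5, 1.0, size=(cfg.n_channels, 3))
    phases = rng.uniform(0, 2 * np.pi, size=(cfg.n_channels, 3))
    gains = rng.uniform(0.6, 1.0, size=cfg.n_channels)
    gains = gains / gains.max()  # strongest channel reaches amp exactly
    addend = np.zeros((cfg.n_channels, n))
    centers = np.empty(n_bursts, dtype=np.int64)
    for k in range(n_bursts):
        s = start + int(round(k * period))
        e = start + int(round((k + 1) * period))
        centers[k] = s + (e - s) // 2
        L = e - s
        tloc = np.arange(L) / cfg.fs
        env = hann(L, sym=True)
        for c in range(cfg.n_channels):
            w = env * sum(
                amps[c, i] * np.cos(2 * np.pi * freqs[c, i] * tloc + phases[c, i])
                for i in range(3)
            )
            peak = np.abs(w).max()
            if peak > 0:
                w = w / peak
            addend[c, s:e] += gains[c] * amp * w
    dummy = centers[: cfg.n_dummy if cfg.mode == "volume" else cfg.n_dummy * cfg.n_slices]
    truth = centers[dummy.size:]
    return addend, OnsetSeries(truth, cfg.fs, "GS"), dummy.copy()


def gen_cardiac_train(cfg: SimConfig, rng: np.random.Generator
                      ) -> Tuple[OnsetSeries, OnsetSeries]:
    """Cardiac beat times and the cardioballistic artefact times.

    RR intervals are normal(rr_mean, rr_sd) truncated by resampling to
    ``rr_bounds_ms``; the artefact follows each R peak by
    ``ecg_delay_ms``.  A one-second margin is kept at both ends of the
    recording so every artefact waveform fits entirely inside it.
    """
    n = cfg.n_samples
    delay = int(round(cfg.ecg_delay_ms * cfg.fs / 1000.0))
    margin = int(round(1.0 * cfg.fs))
    r_times: List[int] = []
    t = float(margin)
    while t + delay + margin <= n:
        r_times.append(int(round(t)))
        rr = rng.normal(cfg.rr_mean_ms, cfg.rr_sd_ms)
        while not (cfg.rr_bounds_ms[0] <= rr <= cfg.rr_bounds_ms[1]):
            rr = rng.normal(cfg.rr_mean_ms, cfg.rr_sd_ms)
        t += rr * cfg.fs / 1000.0
    r = np.asarray(r_times, dtype=np.int64)
    return (
        OnsetSeries(r, cfg.fs, "R"),
        OnsetSeries(r + delay, cfg.fs, "CB"),
    )


def cb_template(cfg: SimConfig) -> np.ndarray:
    """Canonical cardioballistic waveform: a Gaussian-windowed 7 Hz
    wave with unit peak exactly at its centre sample."""
    width = int(round(0.4 * cfg.rr_mean_ms * cfg.fs / 1000.0)) | 1
    half = width // 2
    tloc = np.arange(-half, half + 1)
    sigma = width / 8.0
    return np.cos(2 * np.pi * 7.0 * tloc / cfg.fs) * np.exp(-(tloc ** 2) / (2 * sigma ** 2))


def gen_cb_waveform(cfg: SimConfig, cb_truth: OnsetSeries,
                    rng: np.random.Generator) -> np.ndarray:
    """Place the CB template at each artefact time with per-beat
    amplitude jitter, slow per-channel gain drift, and frontotemporal-
    dominant channel weighting."""
    n = cfg.n_samples
    kern = cb_template(cfg)
    half = kern.size // 2
    gains = np.empty(cfg.n_channels)
    gains[:] = rng.uniform(0.3, 0.6, size=cfg.n_channels)
    gains[0] = 1.0  # frontotemporal-like leads carry the artefact best
    if cfg.n_channels > 1:
        gains[1] = 0.9
    if cfg.n_channels > 2:
        gains[2] = 0.75
    if cfg.n_channels > 3:
        gains[3] = 0.7
    drift_phase = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
    beat_amp = rng.uniform(1.0 - cfg.cb_drift_frac, 1.0 + cfg.cb_drift_frac,
                           size=len(cb_truth))
    addend = np.zeros((cfg.n_channels, n))
    duration = max(n / cfg.fs, 1.0)
    for k, p in enumerate(cb_truth.onsets):
        a, b = p - half, p + half + 1
        ka, kb = 0, kern.size
        if a < 0:
            ka, a = -a, 0
        if b > n:
            kb, b = kern.size - (b - n), n
        tk = p / cfg.fs
        for c in range(cfg.n_channels):
            slow = 1.0 + 0.15 * np.sin(2 * np.pi * tk / duration + drift_phase[c])
            addend[c, a:b] += (
                cfg.cb_amplitude_uv * gains[c] * slow * beat_amp[k] * kern[ka:kb]
            )
    return addend


def gen_ecg(cfg: SimConfig, r_truth: OnsetSeries, rng: np.random.Generator) -> np.ndarray:
    """QRS-like wavelet train over baseline wander and noise (µV)."""
    n = cfg.n_samples
    # Mexican-hat wavelet: sharp positive R peak flanked by shallow
    # negative lobes, peak value 1 at the centre sample
    a = max(2.0, 0.002 * cfg.fs)  # ~2 ms main-lobe scale
    half = int(round(8 * a))
    tloc = np.arange(-half, half + 1)
    qrs = (1 - (tloc / a) ** 2) * np.exp(-(tloc ** 2) / (2 * a ** 2))
    qrs = qrs / qrs.max()
    ecg = np.zeros(n)
    for p in r_truth.onsets:
        lo, hi = p - half, p + half + 1
        ka, kb = 0, qrs.size
        if lo < 0:
            ka, lo = -lo, 0
        if hi > n:
            kb, hi = qrs.size - (hi - n), n
        ecg[lo:hi] += cfg.ecg_r_amplitude_uv * qrs[ka:kb]
    t = np.arange(n) / cfg.fs
    wander = 150.0 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    wander += 100.0 * np.sin(2 * np.pi * 0.15 * t + rng.uniform(0, 2 * np.pi))
    noise = 10.0 * rng.standard_normal(n)
    return ecg + wander + noise


def gen_dataset(cfg: Optional[SimConfig] = None, **overrides) -> SyntheticDataset:
    """Compose a full synthetic dataset from a configuration.

    Background, gradient train, cardiac train, CB waveform and ECG are
    drawn in a fixed order from one seeded generator, so the dataset is
    a pure function of the configuration.
    """
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    data = gen_background_eeg(cfg, rng)
    if cfg.include_gs:
        gs_add, gs_truth, gs_dummy = gen_gs_train(cfg, rng)
        data = data + gs_add
    else:
        gs_truth = OnsetSeries(np.empty(0, dtype=np.int64), cfg.fs, "GS")
        gs_dummy = np.empty(0, dtype=np.int64)
    r_truth, cb_truth = gen_cardiac_train(cfg, rng)
    if cfg.include_cb:
        data = data + gen_cb_waveform(cfg, cb_truth, rng)
    labels = cfg.channel_labels()
    if cfg.include_ecg:
        ecg = gen_ecg(cfg, r_truth, rng)
        data = np.vstack([data, ecg[None, :]])
        labels = labels + ["ECG"]
    rec = EEGRecording(data, cfg.fs, labels)
    return SyntheticDataset(
        recording=rec,
        gs_truth=gs_truth,
        cb_truth=cb_truth,
        r_truth=r_truth,
        config=cfg,
        gs_dummy_onsets=gs_dummy,
    )
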