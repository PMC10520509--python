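"""Readers and writers for EEG recordings and onset marker files.

Recordings are read through :mod:`mne` (BrainVision and EDF/EDF+) and
converted to µV at ingest.  Minimal writers for both formats are provided
so that synthetic recordings can be materialised on disk; they cover only
what this package itself produces (INT_16 multiplexed BrainVision,
16-bit EDF with one-second records), not the full generality of either
standard.

Onset series travel as either a tab-separated table
(``sample_index  time_s  label``, 0-based) or a BrainVision ``.vmrk``
marker file (1-based positions, type ``Response``).
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .containers import EEGRecording, OnsetSeries
from .errors import FormatError, UnsupportedLayoutError, ValidationError

__all__ = [
    "read_brainvision",
    "read_edf",
    "write_brainvision",
    "write_edf",
    "write_onsets",
    "read_onsets",
]

_MNE_KW = dict(preload=True, verbose="error")


def _read_with_mne(raw) -> EEGRecording:
    data_uv = raw.get_data() * 1e6  # mne works in volts internally
    return EEGRecording(data_uv, float(raw.info["sfreq"]), list(raw.ch_names))


def read_brainvision(vhdr_path) -> EEGRecording:
    """Read a BrainVision ``.vhdr``/``.vmrk``/``.eeg`` triplet.

    Integer counts are scaled by the per-channel resolution declared in
    the header (e.g. 0.5 µV/bit), so the returned data is in µV.
    """
    vhdr_path = Path(vhdr_path)
    if not vhdr_path.is_file():
        raise FileNotFoundError(f"header file not found: {vhdr_path}")
    header = vhdr_path.read_text(encoding="utf-8", errors="replace")
    for key in ("DataFile", "MarkerFile"):
        m = re.search(rf"^{key}=(.+)$", header, re.MULTILINE)
        if m:
            companion = vhdr_path.parent / m.group(1).strip()
            if not companion.is_file():
                raise FileNotFoundError(
                    f"{key} referenced by {vhdr_path.name} is missing: {companion}"
                )
    m = re.search(r"^BinaryFormat=(\S+)", header, re.MULTILINE)
    if m and m.group(1) not in ("INT_16", "IEEE_FLOAT_32"):
        raise FormatError(f"unsupported BrainVision binary format: {m.group(1)}")
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, **_MNE_KW)
    return _read_with_mne(raw)


def read_edf(path) -> EEGRecording:
    """Read an EDF/EDF+ file; physical values are converted to µV.

    All signals must share one sampling rate; EDF files mixing rates
    across channels raise :class:`UnsupportedLayoutError`.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"EDF file not found: {path}")
    _check_edf_homogeneous(path)
    import mne

    raw = mne.io.read_raw_edf(path, **_MNE_KW)
    return _read_with_mne(raw)


def _check_edf_homogeneous(path: Path) -> None:
    """Reject EDF files whose signals have different samples-per-record."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise FormatError(f"truncated EDF header in {path}")
        try:
            n_sig = int(hdr[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"malformed EDF header in {path}") from exc
        sig_hdr = fh.read(256 * n_sig)
    # per-signal samples-per-record live in the 8-byte fields at offset
    # 216 * n_sig within the signal header block
    off = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * n_sig
    spr = []
    labels = []
    for i in range(n_sig):
        labels.append(sig_hdr[16 * i : 16 * (i + 1)].decode("ascii").strip())
        spr.append(int(sig_hdr[off + 8 * i : off + 8 * (i + 1)].decode("ascii")))
    # EDF+ annotation channels carry no sample data we use
    rates = {s for s, l in zip(spr, labels) if l != "EDF Annotations"}
    if len(rates) > 1:
        raise UnsupportedLayoutError(
            f"EDF signals have heterogeneous sampling rates: {sorted(rates)}"
        )


def write_brainvision(rec: EEGRecording, vhdr_path, resolution_uv: float = 0.5) -> None:
    """Write ``rec`` as an INT_16 multiplexed BrainVision triplet.

    ``resolution_uv`` is the quantisation step (µV per bit); the default
    matches common MR-compatible amplifier settings.  Values outside the
    int16 range at this resolution raise :class:`ValidationError`.
    """
    vhdr_path = Path(vhdr_path)
    stem = vhdr_path.stem
    eeg_path = vhdr_path.with_suffix(".eeg")
    vmrk_path = vhdr_path.with_suffix(".vmrk")
    counts = np.round(rec.data / resolution_uv)
    if np.abs(counts).max(initial=0) > 32767:
        raise ValidationError(
            f"amplitude exceeds int16 range at resolution {resolution_uv} µV/bit"
        )
    counts = counts.astype("<i2")
    with open(eeg_path, "wb") as fh:
        fh.write(counts.T.reshape(-1).tobytes())  # multiplexed sample-major
    sampling_interval_us = 1e6 / rec.fs
    si = (
        f"{sampling_interval_us:.0f}"
        if abs(sampling_interval_us - round(sampling_interval_us)) < 1e-9
        else f"{sampling_interval_us!r}"
    )
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by artonset",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={si}",
        "",
        "[Binary Infos]",
        "BinaryFormat=INT_16",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,{resolution_uv:g},µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk_path.write_text(
        "\n".join(
            [
                "Brain Vision Data Exchange Marker File, Version 1.0",
                "",
                "[Common Infos]",
                "Codepage=UTF-8",
                f"DataFile={stem}.eeg",
                "",
                "[Marker Infos]",
                "Mk1=New Segment,,1,1,0,00000000000000000000",
            ]
        )
        + "\n",
        encoding="utf-8",
    )


def write_edf(path, rec: EEGRecording, dims: Sequence[str] | None = None) -> None:
    """Write ``rec`` as a 16-bit EDF file with one-second data records.

    The sampling rate must be a positive integer and the recording is
    zero-padded to a whole number of seconds.  ``dims`` optionally gives
    a physical dimension per channel (default ``uV``).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs < 1:
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    n_rec = -(-n_samp // fs)  # ceil
    data = np.zeros((n_ch, n_rec * fs))
    data[:, :n_samp] = rec.data
    if dims is None:
        dims = ["uV"] * n_ch
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767

    def fld(value, width):
        b = str(value).encode("ascii")
        if len(b) > width:
            raise ValidationError(f"EDF header field too long: {value!r}")
        return b.ljust(width)

    hdr = b"".join(
        [
            fld("0", 8),
            fld("X X X X", 80),
            fld("Startdate 01-JAN-2020 X X X", 80),
            fld("01.01.20", 8),
            fld("00.00.00", 8),
            fld(256 * (1 + n_ch), 8),
            fld("", 44),
            fld(n_rec, 8),
            fld(1, 8),
            fld(n_ch, 4),
        ]
    )
    hdr += b"".join(fld(l, 16) for l in rec.channel_labels)
    hdr += b"".join(fld("", 80) for _ in range(n_ch))
    hdr += b"".join(fld(d, 8) for d in dims)
    hdr += b"".join(fld(("%.6g" % -p)[:8], 8) for p in phys_max)
    hdr += b"".join(fld(("%.6g" % p)[:8], 8) for p in phys_max)
    hdr += b"".join(fld(dig_min, 8) for _ in range(n_ch))
    hdr += b"".join(fld(dig_max, 8) for _ in range(n_ch))
    hdr += b"".join(fld("", 80) for _ in range(n_ch))
    hdr += b"".join(fld(fs, 8) for _ in range(n_ch))
    hdr += b"".join(fld("", 32) for _ in range(n_ch))
    # map [-phys_max, phys_max] onto the full digital range; re-read the
    # physical bounds exactly as written so the round trip is consistent
    pmin = np.array([float(("%.6g" % -p)[:8]) for p in phys_max])
    pmax = np.array([float(("%.6g" % p)[:8]) for p in phys_max])
    scale = (dig_max - dig_min) / (pmax - pmin)
    dig = np.round((data - pmin[:, None]) * scale[:, None]) + dig_min
    dig = np.clip(dig, dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(dig[c, r * fs : (r + 1) * fs].tobytes())


def write_onsets(series: OnsetSeries, path, fmt: str = "tsv") -> None:
    """Write an onset series as TSV (0-based) or BrainVision ``.vmrk``
    (1-based positions, marker type ``Response``)."""
    path = Path(path)
    if fmt == "tsv":
        lines = [f"# fs={series.fs:g}", "sample_index\ttime_s\tlabel"]
        for idx in series.onsets:
            lines.append(f"{idx}\t{float(idx / series.fs)!r}\t{series.label}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "vmrk":
        lines = [
            "Brain Vision Data Exchange Marker File, Version 1.0",
            "",
            "[Common Infos]",
            "Codepage=UTF-8",
            f";fs={series.fs:g}",
            "",
            "[Marker Infos]",
        ]
        for i, idx in enumerate(series.onsets, start=1):
            lines.append(f"Mk{i}=Response,{series.label},{idx + 1},1,0")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown onset format {fmt!r}")


def read_onsets(path, fmt: str = "tsv") -> OnsetSeries:
    """Inverse of :func:`write_onsets` for both dialects."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if fmt == "tsv":
        fs = None
        onsets, labels = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"fs=([\d.eE+-]+)", line)
                if m:
                    fs = float(m.group(1))
                continue
            if line.startswith("sample_index"):
                continue
            parts = line.split("\t")
            onsets.append(int(parts[0]))
            labels.append(parts[2] if len(parts) > 2 else "GS")
        if fs is None:
            raise FormatError(f"no '# fs=' header in {path}")
        label = labels[0] if labels else "GS"
    elif fmt == "vmrk":
        fs = None
        onsets, labels = [], []
        for line in text.splitlines():
            m = re.search(r"fs=([\d.eE+-]+)", line)
            if m and fs is None:
                fs = float(m.group(1))
            m = re.match(r"Mk\d+=([^,]*),([^,]*),(\d+),", line)
            if m and m.group(1) != "New Segment":
                onsets.append(int(m.group(3)) - 1)  # back to 0-based
                labels.append(m.group(2))
        if fs is None:
            raise FormatError(f"no fs annotation in {path}")
        label = labels[0] if labels else "GS"
    else:
        raise ValueError(f"unknown onset format {fmt!r}")
    arr = np.asarray(onsets, dtype=np.int64)
    if arr.size and (np.diff(arr) <= 0).any():
        raise ValidationError(f"onsets in {path} are not strictly increasing")
    return OnsetSeries(arr, fs, label)
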