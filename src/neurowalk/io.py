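"""Reading and writing EEG recordings (BrainVision, EDF) and montage
positions.

Reading goes through MNE. Writing is provided by small writers covering the
subset of each format this package produces: EDF with 16-bit samples, and
BrainVision with IEEE float-32 or 16-bit integer payloads in multiplexed or
vectorized orientation.
"""

from __future__ import annotations

import configparser
import warnings
from pathlib import Path

import numpy as np

from .core import FormatError, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "write_edf",
    "write_brainvision",
    "standard_positions",
    "attach_standard_positions",
]


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".vhdr":
        return "brainvision"
    if suffix == ".edf":
        return "edf"
    raise FormatError(
        f"cannot infer format from {path.name!r}; expected .vhdr or .edf"
    )


def _check_brainvision_companions(vhdr: Path) -> None:
    """Verify the .vhdr's DataFile/MarkerFile references resolve and the
    binary payload size is consistent with the declared channel count."""
    cp = configparser.ConfigParser()
    text = vhdr.read_text(encoding="utf-8", errors="replace")
    # strip the magic first line, which is not INI syntax
    body = "\n".join(line for line in text.splitlines()
                     if not line.startswith("Brain Vision"))
    cp.read_string(body)
    try:
        common = cp["Common Infos"]
    except KeyError:
        raise FormatError(f"{vhdr.name}: no [Common Infos] section") from None
    for key in ("DataFile", "MarkerFile"):
        ref = common.get(key)
        if ref is None:
            if key == "MarkerFile":
                continue
            raise FormatError(f"{vhdr.name}: missing {key} entry")
        target = vhdr.parent / ref
        if not target.exists():
            raise FormatError(
                f"{vhdr.name} references missing companion file {ref!r}"
            )
    n_chan = common.getint("NumberOfChannels", fallback=None)
    fmt = cp.get("Binary Infos", "BinaryFormat", fallback="").strip()
    itemsize = {"INT_16": 2, "IEEE_FLOAT_32": 4}.get(fmt)
    if itemsize is None:
        raise FormatError(
            f"{vhdr.name}: unsupported BinaryFormat {fmt!r} "
            "(supported: INT_16, IEEE_FLOAT_32)"
        )
    if n_chan:
        payload = (vhdr.parent / common["DataFile"]).stat().st_size
        if payload % (n_chan * itemsize) != 0:
            raise FormatError(
                f"{common['DataFile']}: payload of {payload} bytes is not a "
                f"whole number of samples for {n_chan} channels "
                f"({fmt}, {itemsize} bytes/sample)"
            )


def read_recording(path, format: str = "auto") -> Recording:
    """Read an EEG recording from disk.

    Parameters
    ----------
    path : path-like
        The .vhdr (BrainVision) or .edf file.
    format : {"auto", "brainvision", "edf"}
        "auto" infers from the file extension.

    Returns
    -------
    Recording
        Channels in stored order, data in microvolts, sampling rate from the
        file header.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "brainvision":
        _check_brainvision_companions(path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_brainvision(path, preload=True,
                                              verbose="error")
    elif format == "edf":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise FormatError(f"unknown format {format!r}")
    data_uv = raw.get_data() * 1e6  # MNE holds EEG in volts
    return Recording(
        labels=list(raw.ch_names),
        sfreq=float(raw.info["sfreq"]),
        data=data_uv,
        meta={"source": str(path), "format": format},
    )


def write_recording(rec: Recording, path, format: str = "auto", **kwargs) -> Path:
    """Write a recording as EDF or BrainVision (dispatch on extension)."""
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "edf":
        return write_edf(rec, path)
    if format == "brainvision":
        return write_brainvision(rec, path, **kwargs)
    raise FormatError(f"unknown format {format!r}")


def write_edf(rec: Recording, path) -> Path:
    """Write a recording as a minimal EDF file (16-bit samples, one data
    record spanning the whole signal).

    Physical units are microvolts; each channel's physical range is fitted
    to its data, so the quantization step is max|x| / 32767 per channel.
    """
    path = Path(path)
    n_ch, n_samp = rec.data.shape
    duration = n_samp / rec.sfreq

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-9)
    dig_max = 32767
    scaled = np.round(rec.data / phys_max[:, None] * dig_max).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii", errors="replace")[:n]
        return b + b" " * (n - len(b))

    header = b"".join([
        pad("0", 8),                          # version
        pad("X X X X", 80),                   # patient id
        pad("Startdate X X X X", 80),         # recording id
        pad("01.01.00", 8),                   # start date
        pad("00.00.00", 8),                   # start time
        pad(str(256 * (1 + n_ch)), 8),        # header bytes
        pad("EDF", 44),                       # reserved
        pad("1", 8),                          # number of data records
        pad(f"{duration:.6f}"[:8], 8),        # record duration (s)
        pad(str(n_ch), 4),
    ])
    header += b"".join(pad(l, 16) for l in rec.labels)
    header += b"".join(pad("EEG", 80) for _ in range(n_ch))
    header += b"".join(pad("uV", 8) for _ in range(n_ch))
    header += b"".join(pad(f"{-p:.6g}"[:8], 8) for p in phys_max)
    header += b"".join(pad(f"{p:.6g}"[:8], 8) for p in phys_max)
    header += b"".join(pad(str(-dig_max), 8) for _ in range(n_ch))
    header += b"".join(pad(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(pad("", 80) for _ in range(n_ch))   # prefiltering
    header += b"".join(pad(str(n_samp), 8) for _ in range(n_ch))
    header += b"".join(pad("", 32) for _ in range(n_ch))   # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(scaled.tobytes())  # record = channels back to back
    return path


def write_brainvision(rec: Recording, vhdr_path, binary_format: str = "IEEE_FLOAT_32",
                      orientation: str = "MULTIPLEXED",
                      resolution: float | None = None) -> Path:
    """Write a recording as a BrainVision triplet (.vhdr/.vmrk/.eeg).

    Parameters
    ----------
    binary_format : {"IEEE_FLOAT_32", "INT_16"}
    orientation : {"MULTIPLEXED", "VECTORIZED"}
        Multiplexed interleaves channels per sample; vectorized stores each
        channel's samples contiguously.
    resolution : float or None
        Microvolts per integer step for INT_16 (default: fitted to data).
    """
    vhdr_path = Path(vhdr_path)
    if vhdr_path.suffix.lower() != ".vhdr":
        raise FormatError("BrainVision header must have a .vhdr extension")
    if binary_format not in ("IEEE_FLOAT_32", "INT_16"):
        raise FormatError(f"unsupported BinaryFormat {binary_format!r}")
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise FormatError(f"unsupported DataOrientation {orientation!r}")

    stem = vhdr_path.stem
    eeg_path = vhdr_path.with_suffix(".eeg")
    vmrk_path = vhdr_path.with_suffix(".vmrk")
    n_ch, n_samp = rec.data.shape

    if binary_format == "INT_16":
        if resolution is None:
            resolution = max(np.abs(rec.data).max() / 32000.0, 1e-9)
        payload = np.round(rec.data / resolution).astype("<i2")
        res_per_chan = [resolution] * n_ch
    else:
        payload = rec.data.astype("<f4")
        res_per_chan = [1.0] * n_ch

    if orientation == "MULTIPLEXED":
        payload = payload.T  # sample-major
    with open(eeg_path, "wb") as fh:
        fh.write(np.ascontiguousarray(payload).tobytes())

    sampling_interval_us = 1e6 / rec.sfreq
    si = (f"{sampling_interval_us:.6f}".rstrip("0").rstrip(".")
          if sampling_interval_us != int(sampling_interval_us)
          else str(int(sampling_interval_us)))
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        f"DataOrientation={orientation}",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={si}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for i, (label, res) in enumerate(zip(rec.labels, res_per_chan), start=1):
        res_s = f"{res:.10g}"
        lines.append(f"Ch{i}={label},,{res_s},µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    vmrk_path.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg_path.name}\n\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8",
    )
    return vhdr_path


# ---------------------------------------------------------------------------
# montage positions

_POSITION_CACHE: dict[str, np.ndarray] | None = None


def standard_positions(labels) -> dict[str, np.ndarray]:
    """Unit-sphere 3D positions for 10-20 / 10-10 electrode labels.

    Positions come from the standard idealized montage, re-centered on the
    best-fit sphere center and projected to unit radius — the geometry the
    spherical-spline interpolator assumes.
    """
    global _POSITION_CACHE
    if _POSITION_CACHE is None:
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            montage = mne.channels.make_standard_montage("standard_1005")
        raw_pos = montage.get_positions()["ch_pos"]
        pts = np.array([p for p in raw_pos.values()])
        center = pts.mean(axis=0)
        cache: dict[str, np.ndarray] = {}
        for name, p in raw_pos.items():
            v = np.asarray(p, float) - center
            cache[name.lower()] = v / np.linalg.norm(v)
        _POSITION_CACHE = cache
    out: dict[str, np.ndarray] = {}
    missing = []
    for lab in labels:
        pos = _POSITION_CACHE.get(lab.lower())
        if pos is None:
            missing.append(lab)
        else:
            out[lab] = pos
    if missing:
        raise KeyError(f"no standard montage position for: {missing}")
    return out


def attach_standard_positions(rec: Recording) -> Recording:
    """Return a copy of the recording with standard montage positions."""
    out = rec.copy()
    out.positions = standard_positions(rec.labels)
    return out
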