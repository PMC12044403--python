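"""Cleaning and segmentation of continuous EEG.

Stages mirror a standard mobile-EEG pipeline: zero-phase FIR bandpass,
sliding-window sinusoidal regression for power-line noise, average
re-referencing, flatline / low-correlation bad-channel detection,
spherical-spline interpolation of bad channels, and fixed-length epoch
extraction labeled with the study factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy.signal import fftconvolve, firwin

from .core import Epoch, Recording, SEGMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "BadChannelReport",
    "bandpass_filter",
    "remove_line_noise",
    "average_reference",
    "detect_bad_channels",
    "interpolate_channels",
    "segment_epochs",
]


@dataclass
class BadChannelReport:
    """Channels flagged by the flatline and low-correlation criteria."""

    flatline_channels: set[str] = field(default_factory=set)
    low_correlation_channels: set[str] = field(default_factory=set)
    flatline_s: float = 5.0
    corr_threshold: float = 0.8

    @property
    def all_bad(self) -> set[str]:
        return self.flatline_channels | self.low_correlation_channels


def _transition_width(low: float, high: float) -> float:
    # capped at 2*low so the stopband reaches DC (full attenuation there)
    return min(max(0.25 * low, 2.0), high / 4.0, 2.0 * low)


def bandpass_filter(rec: Recording, low: float = 0.5,
                    high: float = 40.0) -> Recording:
    """Zero-phase FIR bandpass (windowed-sinc, Hamming window).

    The symmetric odd-length kernel is applied by centered convolution, so
    the net phase response is zero. The transition width is
    ``min(max(0.25 * low, 2 Hz), high / 4)``; the Hamming window gives
    ~0.2% passband ripple and >50 dB stopband attenuation one transition
    width beyond the band edges.
    """
    sfreq = rec.sfreq
    if not 0 < low < high < sfreq / 2:
        raise ValueError(f"band ({low}, {high}) outside (0, {sfreq / 2}) Hz")
    width = _transition_width(low, high)
    numtaps = int(np.ceil(3.3 * sfreq / width))
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase
    if rec.n_samples < 3 * numtaps:
        raise ValueError(
            f"signal of {rec.n_samples} samples is shorter than 3x the "
            f"{numtaps}-tap filter; need >= {3 * numtaps} samples")
    h = firwin(numtaps, [low, high], pass_zero=False, window="hamming",
               fs=sfreq)
    out = fftconvolve(rec.data, h[None, :], mode="same", axes=1)
    return rec.copy(data=out)


def remove_line_noise(rec: Recording, line_freq: float = 50.0,
                      bandwidth: float = 2.0,
                      window_s: float = 4.0) -> Recording:
    """Power-line removal by sliding-window sinusoidal regression.

    Within each Hann-weighted window (50% overlap), sine and cosine
    regressors at the line frequency and at every window-grid frequency
    within ``bandwidth / 2`` of it are fit by least squares and the fitted
    narrowband component is subtracted via overlap-add. Broadband content
    away from the line band passes through essentially unchanged.
    """
    if not line_freq < rec.sfreq / 2:
        raise ValueError("line frequency must be below Nyquist")
    n = rec.n_samples
    n_win = min(int(round(window_s * rec.sfreq)), n)
    step = max(1, n_win // 2)

    # regression frequencies: the line itself plus grid frequencies in band
    df = rec.sfreq / n_win
    k_lo = int(np.ceil((line_freq - bandwidth / 2) / df))
    k_hi = int(np.floor((line_freq + bandwidth / 2) / df))
    freqs = sorted({line_freq, *(k * df for k in range(max(k_lo, 1), k_hi + 1)
                                 if 0 < k * df < rec.sfreq / 2)})
    t_win = np.arange(n_win) / rec.sfreq
    X = np.column_stack([f(2 * np.pi * fq * t_win)
                         for fq in freqs for f in (np.sin, np.cos)])
    # precompute pseudo-inverse once; windows share the design matrix
    pinv = np.linalg.pinv(X)

    taper = np.hanning(n_win)
    estimate = np.zeros_like(rec.data)
    weight = np.zeros(n)
    for start in range(0, max(n - n_win, 0) + 1, step):
        seg = rec.data[:, start:start + n_win]
        coeffs = pinv @ seg.T                 # (2F, n_ch)
        fitted = (X @ coeffs).T               # (n_ch, n_win)
        estimate[:, start:start + n_win] += fitted * taper
        weight[start:start + n_win] += taper
    weight[weight == 0] = 1.0
    # edges have partial taper coverage; normalize by accumulated weight
    return rec.copy(data=rec.data - estimate / weight)


def average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel
    (per-sample column sums of the output are zero)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return rec.copy(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def detect_bad_channels(rec: Recording, flatline_s: float = 5.0,
                        corr_threshold: float = 0.8) -> BadChannelReport:
    """Flag channels by the flatline and window-correlation criteria.

    *Flatline*: a run of at least ``flatline_s`` seconds where consecutive
    samples change by less than 1e-8 microvolts.
    *Low correlation*: for each 1-s window, take each channel's maximum
    absolute Pearson correlation with any other channel; a channel whose
    median over windows falls below ``corr_threshold`` is flagged.
    """
    report = BadChannelReport(flatline_s=flatline_s,
                              corr_threshold=corr_threshold)
    data = rec.data
    n_flat = int(np.ceil(flatline_s * rec.sfreq))
    for i, label in enumerate(rec.labels):
        quiet = np.abs(np.diff(data[i])) < 1e-8
        if quiet.size >= n_flat:
            # longest run of consecutive quiet steps
            run = best = 0
            for q in quiet:
                run = run + 1 if q else 0
                best = max(best, run)
            if best + 1 >= n_flat:  # run of k steps spans k+1 samples
                report.flatline_channels.add(label)

    n_win = int(round(rec.sfreq))
    n_windows = data.shape[1] // n_win
    if n_windows >= 1 and rec.n_channels >= 2:
        best_corr = np.zeros((n_windows, rec.n_channels))
        for w in range(n_windows):
            seg = data[:, w * n_win:(w + 1) * n_win]
            sd = seg.std(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                C = np.abs(np.corrcoef(seg))
            C = np.nan_to_num(C, nan=0.0)
            np.fill_diagonal(C, 0.0)
            C[sd == 0, :] = 0.0
            C[:, sd == 0] = 0.0
            best_corr[w] = C.max(axis=1)
        med = np.median(best_corr, axis=0)
        for i, label in enumerate(rec.labels):
            if med[i] < corr_threshold:
                report.low_correlation_channels.add(label)
    return report


# -- spherical-spline interpolation ----------------------------------------

_SPLINE_ORDER_M = 4
_SPLINE_TERMS = 7
_SPLINE_REG = 1e-5


def _g_spline(cos_angles: np.ndarray) -> np.ndarray:
    """Spherical-spline kernel g(cos theta): a truncated Legendre series
    with coefficients (2l + 1) / (l (l + 1))^m, l = 1..7, m = 4."""
    ls = np.arange(1, _SPLINE_TERMS + 1)
    coeffs = np.zeros(_SPLINE_TERMS + 1)
    coeffs[1:] = (2 * ls + 1) / (ls * (ls + 1.0)) ** _SPLINE_ORDER_M
    return legendre.legval(np.clip(cos_angles, -1.0, 1.0), coeffs) / (4 * np.pi)


def interpolate_channels(rec: Recording, bad) -> Recording:
    """Reconstruct bad channels by spherical-spline interpolation.

    Fits a spline over the good electrodes' unit-sphere positions
    (Legendre series of 7 terms, order m = 4, ridge regularization 1e-5 on
    the kernel diagonal) and evaluates it at the bad electrodes' positions.
    Good channels are returned untouched.
    """
    bad = {b.lower() for b in bad}
    if not bad:
        return rec.copy()
    if rec.positions is None:
        raise ValueError(
            "recording has no electrode positions; attach a montage first "
            "(see neurowalk.io.attach_standard_positions)")
    missing = [l for l in rec.labels if l not in rec.positions]
    if missing:
        raise ValueError(f"no positions for channels: {missing}; "
                         "attach a montage covering all channels")
    unknown = bad - {l.lower() for l in rec.labels}
    if unknown:
        raise ValueError(f"bad labels not in recording: {sorted(unknown)}")
    good_idx = [i for i, l in enumerate(rec.labels) if l.lower() not in bad]
    bad_idx = [i for i, l in enumerate(rec.labels) if l.lower() in bad]
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels to interpolate")

    pos = np.array([rec.positions[rec.labels[i]] for i in range(rec.n_channels)])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    Pg = pos[good_idx]
    Pb = pos[bad_idx]

    G = _g_spline(Pg @ Pg.T) + _SPLINE_REG * np.eye(len(good_idx))
    # augmented system enforces the zero-sum constraint on the coefficients
    A = np.zeros((len(good_idx) + 1, len(good_idx) + 1))
    A[:-1, :-1] = G
    A[-1, :-1] = 1.0
    A[:-1, -1] = 1.0
    rhs = np.zeros((len(good_idx) + 1, rec.n_samples))
    rhs[:-1] = rec.data[good_idx]
    sol = np.linalg.solve(A, rhs)
    coeffs, intercept = sol[:-1], sol[-1]

    Gb = _g_spline(Pb @ Pg.T)
    out = rec.data.copy()
    out[bad_idx] = Gb @ coeffs + intercept
    return rec.copy(data=out)


def segment_epochs(rec: Recording, boundaries, subject_id: str = "S001",
                   epoch_length: float = 60.0) -> list[Epoch]:
    """Cut fixed-length epochs from a continuous recording.

    ``boundaries`` is a list of (start_s, segment, condition); ``segment``
    is one of elevator / plank_start / plank_end and determines the task
    factor (elevator vs. plank). Overlapping segments are legal; a segment
    extending past the end of the recording raises, naming the offender.
    """
    n_len = int(round(epoch_length * rec.sfreq))
    epochs = []
    for start_s, segment, condition in boundaries:
        if segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}, "
                             f"got {segment!r}")
        start = int(round(start_s * rec.sfreq))
        if start < 0 or start + n_len > rec.n_samples:
            raise ValueError(
                f"segment {segment!r} ({condition}) starting at {start_s} s "
                f"with length {epoch_length} s exceeds the "
                f"{rec.duration:.1f}-s recording")
        sliced = Recording(list(rec.labels), rec.sfreq,
                           rec.data[:, start:start + n_len],
                           rec.positions, dict(rec.meta))
        task = "elevator" if segment == "elevator" else "plank"
        epochs.append(Epoch(sliced, subject_id, condition, task, segment))
    return epochs
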