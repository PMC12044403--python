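"""Channel-pair functional connectivity and network construction.

Two estimators are provided:

* **Pearson connectivity** — the absolute sample Pearson correlation between
  channel time series. Absolute values are taken because the downstream
  distance transform (d = 1/w) and shortest-path search require nonnegative
  weights.
* **weighted Phase Lag Index (wPLI)** — ``|E[Im S_ij]| / E[|Im S_ij|]`` over
  an ensemble of Welch cross-spectra (Hann-tapered sliding windows),
  averaged across frequency bins in the analysis band (default 1-40 Hz).
  wPLI is insensitive to zero-lag coupling (volume-conduction-like mixing
  produces a purely real cross-spectrum), and weights each window by the
  magnitude of its imaginary cross-spectrum.

Networks are built from a connectivity matrix either by the reciprocal
distance transform (for shortest-path efficiency) or by proportional
thresholding and binarization (for community detection), retaining a fixed
fraction of the strongest edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import Epoch, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "DistanceMatrix",
    "pearson_connectivity",
    "wpli_connectivity",
    "connectivity_to_distance",
    "proportional_threshold_binarize",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel connectivity with method metadata."""

    labels: list[str]
    W: np.ndarray
    method: str                      # "pearson" | "wpli" | "binary"
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.labels)
        if self.W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {self.W.shape}")
        if not np.allclose(self.W, self.W.T, atol=1e-12, equal_nan=True):
            raise ValueError("W must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        low = label.lower()
        for i, l in enumerate(self.labels):
            if l.lower() == low:
                return i
        raise KeyError(f"channel {label!r} not in matrix")

    def to_csv(self, path) -> None:
        """Square CSV with a label header row and column."""
        import pandas as pd

        pd.DataFrame(self.W, index=self.labels, columns=self.labels).to_csv(
            path, float_format="%.17g", encoding="utf-8")


@dataclass
class DistanceMatrix:
    """Pairwise distances derived from connectivity; infinite where the
    connection weight is at or below the floor."""

    labels: list[str]
    D: np.ndarray
    provenance: ConnectivityMatrix | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)

    @property
    def n(self) -> int:
        return len(self.labels)


def _epoch_data(epoch) -> tuple[list[str], float, np.ndarray]:
    rec: Recording = epoch.recording if isinstance(epoch, Epoch) else epoch
    return list(rec.labels), rec.sfreq, rec.data


def pearson_connectivity(epoch) -> ConnectivityMatrix:
    """Absolute Pearson correlation between all channel pairs of an epoch.

    Zero-variance channels get a zero row/column (with a logged warning)
    rather than raising, so one flat channel cannot abort a batch run.
    The diagonal is fixed at 0 by convention.
    """
    labels, _, data = _epoch_data(epoch)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    sd = data.std(axis=1)
    dead = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.abs(np.corrcoef(data))
    if dead.any():
        logger.warning("pearson_connectivity: zero-variance channels zeroed: %s",
                       [labels[i] for i in np.flatnonzero(dead)])
        W[dead, :] = 0.0
        W[:, dead] = 0.0
    W = np.nan_to_num(W, nan=0.0)
    np.clip(W, 0.0, 1.0, out=W)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    return ConnectivityMatrix(labels, W, method="pearson")


def _sliding_windows(data: np.ndarray, n_win: int, step: int) -> np.ndarray:
    """(windows, channels, samples) view of the signal."""
    n_ch, n_samp = data.shape
    starts = range(0, n_samp - n_win + 1, step)
    return np.stack([data[:, s:s + n_win] for s in starts])


def wpli_connectivity(epoch, band: tuple[float, float] = (1.0, 40.0),
                      window_s: float = 2.0,
                      overlap: float = 0.5) -> ConnectivityMatrix:
    """Weighted Phase Lag Index over an epoch.

    Cross-spectra are estimated per Hann-tapered sliding window and their
    imaginary parts averaged across the frequency bins inside ``band``;
    the index ``wpli = |sum_k Im S_k| / sum_k |Im S_k|`` is then formed
    over the window ensemble ``k``. A zero denominator (no imaginary
    cross-spectral mass, e.g. strictly zero-lag coupling) maps to
    wPLI = 0.
    """
    labels, sfreq, data = _epoch_data(epoch)
    low, high = band
    if not 0 < low < high < sfreq / 2:
        raise ValueError(f"band {band} outside (0, {sfreq / 2}) Hz")
    n_win = int(round(window_s * sfreq))
    step = max(1, int(round(n_win * (1.0 - overlap))))
    if data.shape[1] < n_win + step:
        raise ValueError(
            f"epoch of {data.shape[1]} samples too short for two "
            f"{window_s}-s windows at {overlap:.0%} overlap")
    windows = _sliding_windows(data, n_win, step)       # (K, n, T)
    taper = np.hanning(n_win)
    spect = np.fft.rfft(windows * taper, axis=-1)       # (K, n, bins)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / sfreq)
    in_band = (freqs >= low) & (freqs <= high)
    spect = spect[:, :, in_band]                        # (K, n, B)

    n = len(labels)
    W = np.zeros((n, n))
    # magnitude scale for flooring numerically-zero imaginary parts
    scale = np.mean(np.abs(spect) ** 2)
    floor = 1e-12 * max(scale, 1e-300)
    for i in range(n):
        cross = spect[:, i, None, :] * np.conj(spect[:, i + 1:, :])  # (K,m,B)
        im = cross.imag
        im = np.where(np.abs(im) < floor, 0.0, im)
        im_band = im.mean(axis=-1)                      # (K, m) bin-averaged
        num = np.abs(im_band.sum(axis=0))               # (m,)
        den = np.abs(im_band).sum(axis=0)
        W[i, i + 1:] = np.where(den > 0,
                                num / np.where(den > 0, den, 1.0), 0.0)
    W = W + W.T
    np.clip(W, 0.0, 1.0, out=W)
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(labels, W, method="wpli", band=(low, high))


def connectivity_to_distance(conn: ConnectivityMatrix,
                             weight_floor: float = 1e-6) -> DistanceMatrix:
    """Reciprocal distance transform: d_ij = 1 / w_ij, with disconnection
    (d = inf) wherever the weight is at or below ``weight_floor``."""
    W = conn.W
    with np.errstate(divide="ignore"):
        D = np.where(W > weight_floor, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(conn.labels), D, provenance=conn)


def proportional_threshold_binarize(conn: ConnectivityMatrix,
                                    keep: float = 0.75) -> ConnectivityMatrix:
    """Keep the strongest ``keep`` fraction of the n(n-1)/2 edges and
    binarize.

    Exactly ``ceil(keep * n_pairs)`` edges are set to 1. Ties at the cut
    are resolved deterministically: edges are ranked by descending weight,
    then ascending lexicographic (label_i, label_j) pair.
    """
    if not 0.0 < keep <= 1.0:
        raise ValueError("keep must be in (0, 1]")
    n = conn.n
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = len(iu)
    quota = int(np.ceil(keep * n_pairs))
    order = sorted(
        range(n_pairs),
        key=lambda k: (-conn.W[iu[k], ju[k]],
                       conn.labels[iu[k]], conn.labels[ju[k]]),
    )
    B = np.zeros((n, n))
    for k in order[:quota]:
        B[iu[k], ju[k]] = B[ju[k], iu[k]] = 1.0
    return ConnectivityMatrix(list(conn.labels), B, method="binary",
                              band=conn.band)
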