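"""Core data model: recordings, epochs, the electrode-region parcellation,
and the long-format metrics table.

A :class:`Recording` is a labeled multichannel time series in microvolts.
An :class:`Epoch` is a fixed-duration slice of a recording carrying the
within-subject factors of the 2 (condition: neutral / negative) x
2 (task: elevator / plank walking) design. The :class:`RegionMap` is the
fixed parcellation of the 32-electrode 10-20 montage into five cortical
regions (frontal, temporal, central, parietal, occipital) used for all
regional analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("neutral", "negative")
TASKS = ("elevator", "plank")
SEGMENTS = ("elevator", "plank_start", "plank_end")

REGIONS = ("frontal", "temporal", "central", "parietal", "occipital")

#: electrode -> region assignment of the analyzed 32-channel montage
_DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("FP1", "FP2", "Fz", "F3", "F7", "F4", "F8", "FT9", "FT10"),
    "temporal": ("T8", "T7", "TP9", "TP10"),
    "central": ("Cz", "C3", "C4", "FC1", "FC2", "FC5", "FC6",
                "CP1", "CP5", "CP2", "CP6"),
    "parietal": ("Pz", "P3", "P7", "P4", "P8"),
    "occipital": ("Oz", "O1", "O2"),
}


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk EEG data."""


@dataclass
class Recording:
    """Labeled multichannel time series.

    Parameters
    ----------
    labels : sequence of str
        Channel names, one per data row, unique (case-insensitively).
    sfreq : float
        Sampling frequency in Hz, > 0.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    positions : dict or None
        Optional per-channel 3D coordinates on (approximately) the unit
        sphere, keyed by channel label.
    meta : dict
        Free-form annotations.
    """

    labels: list[str]
    sfreq: float
    data: np.ndarray
    positions: dict[str, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels but {self.data.shape[0]} data rows"
            )
        lowered = [l.lower() for l in self.labels]
        if len(set(lowered)) != len(lowered):
            raise ValueError("channel labels must be unique (case-insensitive)")
        if not self.sfreq > 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sfreq

    def copy(self, data: np.ndarray | None = None) -> "Recording":
        return Recording(
            labels=list(self.labels),
            sfreq=self.sfreq,
            data=self.data.copy() if data is None else np.asarray(data, float),
            positions=None if self.positions is None else dict(self.positions),
            meta=dict(self.meta),
        )

    def index(self, label: str) -> int:
        """Row index of a channel, case-insensitive."""
        low = label.lower()
        for i, l in enumerate(self.labels):
            if l.lower() == low:
                return i
        raise KeyError(f"channel {label!r} not in recording")

    def pick(self, labels: Sequence[str]) -> "Recording":
        idx = [self.index(l) for l in labels]
        pos = None
        if self.positions is not None:
            pos = {self.labels[i]: self.positions[self.labels[i]]
                   for i in idx if self.labels[i] in self.positions}
        return Recording([self.labels[i] for i in idx], self.sfreq,
                         self.data[idx], pos, dict(self.meta))


@dataclass
class Epoch:
    """A fixed-length slice of a recording with its design-cell factors.

    ``segment`` records which of the three 60-s task segments the epoch came
    from (elevator ride, start of plank, end of plank); ``task`` is the
    two-level factor entering the ANOVA (elevator vs. plank walking).
    """

    recording: Recording
    subject_id: str
    condition: str
    task: str
    segment: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.segment is not None and self.segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}")

    @property
    def duration(self) -> float:
        return self.recording.duration


class RegionMap:
    """Mapping from the five cortical region names to electrode label sets.

    Lookup is case-insensitive ("FP1" and "Fp1" are the same electrode).
    The five sets must be pairwise disjoint.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, tuple[str, ...]] = {
            str(region): tuple(labels) for region, labels in mapping.items()
        }
        seen: dict[str, str] = {}
        for region, labels in self._map.items():
            for lab in labels:
                key = lab.lower()
                if key in seen:
                    raise ValueError(
                        f"electrode {lab!r} assigned to both "
                        f"{seen[key]!r} and {region!r}"
                    )
                seen[key] = region
        self._electrode_to_region = seen

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self._map)

    def electrodes(self, region: str) -> tuple[str, ...]:
        try:
            return self._map[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}; "
                           f"regions are {tuple(self._map)}") from None

    def lookup(self, electrode: str) -> str | None:
        """Region containing an electrode, or None if unassigned."""
        return self._electrode_to_region.get(electrode.lower())

    def __contains__(self, region: str) -> bool:
        return region in self._map

    def items(self):
        return self._map.items()

    @property
    def n_electrodes(self) -> int:
        return sum(len(v) for v in self._map.values())

    def restrict(self, labels: Iterable[str]) -> "RegionMap":
        """Sub-map containing only the given electrodes; regions left with
        fewer than two members are dropped (no pairwise structure)."""
        present = {str(l).lower() for l in labels}
        kept = {
            region: [e for e in elecs if e.lower() in present]
            for region, elecs in self._map.items()
        }
        return RegionMap({r: es for r, es in kept.items() if len(es) >= 2})


def default_region_map() -> RegionMap:
    """The fixed 32-electrode parcellation.

    frontal (9): FP1, FP2, Fz, F3, F7, F4, F8, FT9, FT10;
    temporal (4): T8, T7, TP9, TP10;
    central (11): Cz, C3, C4, FC1, FC2, FC5, FC6, CP1, CP5, CP2, CP6;
    parietal (5): Pz, P3, P7, P4, P8;
    occipital (3): Oz, O1, O2.
    """
    return RegionMap(_DEFAULT_REGIONS)


METRICS_COLUMNS = ("subject", "condition", "task", "scope", "metric", "value")


def metrics_table(rows: Iterable[tuple]) -> pd.DataFrame:
    """Build a long-format metrics table from (subject, condition, task,
    scope, metric, value) tuples, checking key uniqueness."""
    df = pd.DataFrame(list(rows), columns=METRICS_COLUMNS)
    key_cols = list(METRICS_COLUMNS[:-1])
    if df.duplicated(subset=key_cols).any():
        dup = df[df.duplicated(subset=key_cols)].iloc[0]
        raise ValueError(
            "duplicate metrics row for "
            + ", ".join(f"{c}={dup[c]!r}" for c in key_cols)
        )
    return df


def write_metrics(table: pd.DataFrame, path) -> None:
    """Write a metrics table as UTF-8 CSV, deterministically sorted by all
    key columns, values at full double precision."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty metrics table")
    out = table.loc[:, list(METRICS_COLUMNS)].sort_values(
        list(METRICS_COLUMNS[:-1]), kind="mergesort"
    )
    out.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metrics CSV missing columns: {sorted(missing)}")
    return df[list(METRICS_COLUMNS)]
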