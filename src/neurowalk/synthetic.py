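"""Synthetic multichannel EEG with planted coupling structure.

The generator builds each channel as a sum of shared sinusoidal sources plus
independent Gaussian noise. Every planted coupling is an *edge*: two channels
share one oscillator at a given frequency, with a fixed phase lag between
them and a coupling strength in [0, 1] scaling the oscillator's amplitude.
Because the lag and strength of every edge are known exactly, downstream
estimators (Pearson correlation, weighted Phase Lag Index, graph metrics)
can be validated against ground truth.

A full factorial *study* replicates the walking-under-height-threat design:
every subject contributes one epoch to each of the four cells of the
2 (condition: neutral / negative) x 2 (task: elevator / plank) layout. A
per-subject random intercept on coupling strength induces the within-subject
correlation a repeated-measures analysis assumes, and per-cell additive
deltas on regional coupling strength plant condition and task effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import CONDITIONS, TASKS, Epoch, Recording, RegionMap

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingEdge",
    "CouplingSpec",
    "StudyDesign",
    "generate_coupled_recording",
    "generate_study",
    "plant_lag_pair",
    "reduced_montage_labels",
    "reduced_region_map",
    "within_region_spec",
    "null_study_design",
    "frontal_condition_design",
    "cross_region_design",
]


@dataclass(frozen=True)
class CouplingEdge:
    """One planted coupling: a shared oscillator between two channels."""

    ch_i: str
    ch_j: str
    frequency: float        # Hz
    phase_lag: float        # radians, channel j lags channel i
    strength: float = 1.0   # in [0, 1], scales the shared amplitude


@dataclass(frozen=True)
class CouplingSpec:
    """A set of planted couplings plus the noise and amplitude scales.

    ``amplitude`` is the peak amplitude (microvolts) of a full-strength
    oscillator; ``noise_sd`` the standard deviation of the independent
    white Gaussian noise added to every channel.
    """

    edges: tuple[CouplingEdge, ...] = ()
    noise_sd: float = 1.0   # microvolts
    amplitude: float = 2.0  # microvolts

    def validate(self, labels: Sequence[str], sfreq: float) -> None:
        known = {l.lower() for l in labels}
        for e in self.edges:
            for ch in (e.ch_i, e.ch_j):
                if ch.lower() not in known:
                    raise ValueError(f"coupling edge names unknown channel {ch!r}")
            if not 0 < e.frequency < sfreq / 2:
                raise ValueError(
                    f"edge frequency {e.frequency} Hz outside (0, {sfreq / 2})"
                )
            if not 0.0 <= e.strength <= 1.0:
                raise ValueError(f"coupling strength {e.strength} outside [0, 1]")
            if not -np.pi < e.phase_lag <= np.pi:
                raise ValueError(f"phase lag {e.phase_lag} outside (-pi, pi]")

    def shift_strengths(self, delta: float,
                        members: set[str] | None = None
                        ) -> tuple["CouplingSpec", int]:
        """Additively shift edge strengths (clipped to [0, 1]); if ``members``
        is given only edges with both endpoints inside it are shifted.
        Returns (new spec, number of clipped edges)."""
        new_edges = []
        clipped = 0
        for e in self.edges:
            if members is None or (e.ch_i.lower() in members
                                   and e.ch_j.lower() in members):
                s = e.strength + delta
                if s < 0.0 or s > 1.0:
                    clipped += 1
                    s = min(1.0, max(0.0, s))
                new_edges.append(replace(e, strength=s))
            else:
                new_edges.append(e)
        return replace(self, edges=tuple(new_edges)), clipped


def generate_coupled_recording(spec: CouplingSpec, labels: Sequence[str],
                               sfreq: float, duration: float,
                               seed: int) -> Recording:
    """Realize one recording from a coupling specification.

    Each edge contributes ``strength * amplitude * sin(2 pi f t + phi)`` to
    channel i and the same waveform delayed by ``phase_lag`` to channel j,
    with a fresh uniform random base phase ``phi`` per edge per realization
    (so the coupling is genuine, not an artifact of a global clock).
    Independent N(0, noise_sd) noise is added to every channel. Deterministic
    given ``seed``.
    """
    n_samples = int(round(duration * sfreq))
    if n_samples < 2:
        raise ValueError("duration * sfreq must be at least 2 samples")
    spec.validate(labels, sfreq)
    rng = np.random.default_rng(seed)
    idx = {l.lower(): k for k, l in enumerate(labels)}
    t = np.arange(n_samples) / sfreq
    data = np.zeros((len(labels), n_samples))
    for e in spec.edges:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        amp = e.strength * spec.amplitude
        omega = 2.0 * np.pi * e.frequency
        data[idx[e.ch_i.lower()]] += amp * np.sin(omega * t + phi)
        data[idx[e.ch_j.lower()]] += amp * np.sin(omega * t + phi - e.phase_lag)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return Recording(list(labels), float(sfreq), data)


def plant_lag_pair(frequency: float, lag: float, snr: float, duration: float,
                   sfreq: float, seed: int = 0,
                   labels: tuple[str, str] = ("A", "B")) -> Recording:
    """Two channels sharing one sinusoidal source with a fixed phase lag.

    ``snr`` is the amplitude ratio of the shared sinusoid to the additive
    white noise; ``snr = inf`` (or any value >= 1e12) disables the noise.
    This is the canonical fixture for phase-lag estimator validation.
    """
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    noiseless = not np.isfinite(snr) or snr >= 1e12
    amplitude = 1.0
    noise_sd = 0.0 if noiseless else amplitude / max(snr, 1e-12)
    spec = CouplingSpec(
        edges=(CouplingEdge(labels[0], labels[1], frequency, lag, 1.0),),
        noise_sd=noise_sd,
        amplitude=amplitude,
    )
    return generate_coupled_recording(spec, list(labels), sfreq, duration, seed)


# ---------------------------------------------------------------------------
# factorial study generation


@dataclass(frozen=True)
class StudyDesign:
    """A complete 2 x 2 fully-within synthetic study.

    ``base_coupling`` maps every (condition, task) cell to the coupling
    specification of that cell; ``effect_map`` maps cells to per-region
    additive strength deltas applied to edges whose endpoints both lie in
    the region. ``subject_sd`` is the standard deviation of the per-subject
    random intercept on coupling strength.
    """

    n_subjects: int
    region_map: RegionMap
    base_coupling: Mapping[tuple[str, str], CouplingSpec]
    effect_map: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=dict)
    epoch_length: float = 10.0   # seconds
    sfreq: float = 250.0         # Hz
    labels: tuple[str, ...] | None = None
    subject_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a repeated-measures study needs >= 2 subjects")
        cells = {(c, t) for c in CONDITIONS for t in TASKS}
        missing = cells - set(self.base_coupling)
        if missing:
            raise ValueError(f"base_coupling missing cells: {sorted(missing)}")

    @property
    def cell_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        any_spec = next(iter(self.base_coupling.values()))
        labs: list[str] = []
        for e in any_spec.edges:
            for ch in (e.ch_i, e.ch_j):
                if ch not in labs:
                    labs.append(ch)
        return tuple(labs)


def _cell_seed(base_seed: int, subject: int, condition: str, task: str) -> int:
    """Stable per-epoch sub-seed independent of iteration order."""
    import zlib

    key = f"{base_seed}|{subject}|{condition}|{task}".encode()
    return zlib.crc32(key) % (2**31)


def generate_study(design: StudyDesign) -> list[Epoch]:
    """Generate ``n_subjects x 4`` epochs realizing the full factorial design.

    Every subject receives one epoch per (condition, task) cell. The
    subject's random intercept (N(0, subject_sd)) shifts all edge strengths
    in all four of their cells, creating within-subject correlation; the
    cell's effect-map deltas are applied on top, restricted to edges with
    both endpoints in the named region. Strengths that leave [0, 1] are
    clipped and counted in a logged warning.
    """
    rng = np.random.default_rng(design.seed)
    labels = list(design.cell_labels)
    region_members = {
        region: {l.lower() for l in design.region_map.electrodes(region)}
        for region in design.region_map.regions
    }
    epochs: list[Epoch] = []
    n_clipped = 0
    for s in range(design.n_subjects):
        subject_id = f"S{s + 1:03d}"
        intercept = rng.normal(0.0, design.subject_sd)
        for condition in CONDITIONS:
            for task in TASKS:
                spec = design.base_coupling[(condition, task)]
                spec, c = spec.shift_strengths(intercept)
                n_clipped += c
                for region, delta in design.effect_map.get(
                        (condition, task), {}).items():
                    if delta == 0.0:
                        continue
                    spec, c = spec.shift_strengths(delta, region_members[region])
                    n_clipped += c
                rec = generate_coupled_recording(
                    spec, labels, design.sfreq, design.epoch_length,
                    seed=_cell_seed(design.seed, s, condition, task),
                )
                segment = "elevator" if task == "elevator" else "plank_end"
                epochs.append(Epoch(rec, subject_id, condition, task, segment))
    if n_clipped:
        logger.warning("generate_study: clipped %d edge strengths to [0, 1]",
                       n_clipped)
    return epochs


# ---------------------------------------------------------------------------
# ready-made designs at the reduced test scale

#: 16-channel subset of the 32-electrode montage covering four regions
_REDUCED_LABELS = ("FP1", "FP2", "Fz", "F3", "F4",
                   "Cz", "C3", "C4", "CP1", "CP2",
                   "Pz", "P3", "P4",
                   "Oz", "O1", "O2")

def reduced_montage_labels() -> tuple[str, ...]:
    return _REDUCED_LABELS


def reduced_region_map() -> RegionMap:
    """Region map restricted to the 16-channel reduced montage."""
    from .core import default_region_map

    full = default_region_map()
    labels = {l.lower() for l in _REDUCED_LABELS}
    return RegionMap({
        region: [e for e in full.electrodes(region) if e.lower() in labels]
        for region in full.regions
        if any(e.lower() in labels for e in full.electrodes(region))
    })


def within_region_spec(region_map: RegionMap, strength: float = 0.6,
                       lag: float = np.pi / 4, noise_sd: float = 1.0,
                       amplitude: float = 3.0,
                       topology: str = "ring",
                       freq_band: tuple[float, float] = (4.0, 13.0)
                       ) -> CouplingSpec:
    """Within-region couplings, one oscillator (and one frequency) per edge.

    ``topology="ring"`` couples each region's electrodes in a cycle (a
    sparse modular backbone: every electrode is coupled, but not every
    within-region pair); ``topology="full"`` couples all within-region
    pairs. Each edge gets its own frequency, evenly spread over
    ``freq_band``: two deterministic sinusoids at the same frequency are
    phase-locked within a realization whether or not they share an
    oscillator, so distinct per-edge frequencies are what makes the planted
    edge set — and only it — the ground-truth coupling graph. The default
    lag of pi/4 is visible to both amplitude-based (Pearson) and phase-lag
    (wPLI) estimators.
    """
    pairs_by_region = []
    for region in region_map.regions:
        members = region_map.electrodes(region)
        k = len(members)
        if topology == "full" or k <= 2:
            pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
        elif topology == "ring":
            pairs = [(a, (a + 1) % k) for a in range(k)]
        else:
            raise ValueError(f"unknown topology {topology!r}")
        pairs_by_region.append((members, pairs))
    n_edges = sum(len(p) for _, p in pairs_by_region)
    lo, hi = freq_band
    step = (hi - lo) / max(n_edges - 1, 1)
    edges = []
    rank = 0
    for members, pairs in pairs_by_region:
        for a, b in pairs:
            i, j = (a, b) if a < b else (b, a)
            edges.append(CouplingEdge(members[i], members[j],
                                      lo + step * rank, lag, strength))
            rank += 1
    return CouplingSpec(tuple(edges), noise_sd=noise_sd, amplitude=amplitude)


def _uniform_cells(spec: CouplingSpec) -> dict[tuple[str, str], CouplingSpec]:
    return {(c, t): spec for c in CONDITIONS for t in TASKS}


def null_study_design(n_subjects: int = 20, seed: int = 0,
                      **kwargs) -> StudyDesign:
    """All four cells identical, no planted effects — the type-I-error
    calibration condition."""
    rm = reduced_region_map()
    return StudyDesign(
        n_subjects=n_subjects,
        region_map=rm,
        base_coupling=_uniform_cells(within_region_spec(rm)),
        labels=_REDUCED_LABELS,
        seed=seed,
        **kwargs,
    )


def frontal_condition_design(n_subjects: int = 75, delta: float = 0.3,
                             seed: int = 0, **kwargs) -> StudyDesign:
    """Frontal within-region coupling raised by ``delta`` in the negative
    condition (both tasks) — the planted condition main effect."""
    rm = reduced_region_map()
    effect = {("negative", t): {"frontal": delta} for t in TASKS}
    return StudyDesign(
        n_subjects=n_subjects,
        region_map=rm,
        base_coupling=_uniform_cells(within_region_spec(rm)),
        effect_map=effect,
        labels=_REDUCED_LABELS,
        seed=seed,
        **kwargs,
    )


def cross_region_design(n_subjects: int = 75, cross_strength: float = 0.8,
                        n_cross: int = 70, seed: int = 0,
                        **kwargs) -> StudyDesign:
    """Diffuse between-region coupling added in the negative cells only.

    The neutral cells keep the purely modular within-region network; the
    negative cells additionally couple ``n_cross`` between-region electrode
    pairs, each through its own oscillator at its own frequency. Spreading
    the added integration over many pairs and frequencies means no
    alternative partition can absorb it as community structure —
    concentrated bridges would instead hand the community detector new
    exploitable modules. Because proportional thresholding retains a fixed
    *count* of edges, the added cross-region couplings crowd within-region
    pairs out of the retained edge set, so the planted effect is a genuine
    loss of segregation (lower modularity Q); the default ``n_cross`` makes
    the true couplings nearly fill the retained-edge quota in the negative
    cells. The cross pairs are a fixed pseudo-random subset (part of the
    design, independent of the realization seed).
    """
    rm = reduced_region_map()
    base = within_region_spec(rm)
    pair_rng = np.random.default_rng(987654321)  # fixed: part of the design
    region_of = {e.lower(): r for r in rm.regions
                 for e in rm.electrodes(r)}
    labels = [e for r in rm.regions for e in rm.electrodes(r)]
    between = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]
               if region_of[a.lower()] != region_of[b.lower()]]
    chosen = pair_rng.choice(len(between), size=min(n_cross, len(between)),
                             replace=False)
    step = 12.0 / max(len(chosen) - 1, 1)
    cross_edges = tuple(
        CouplingEdge(between[k][0], between[k][1],
                     14.0 + step * rank, np.pi / 4, cross_strength)
        for rank, k in enumerate(sorted(chosen)))
    negative = replace(base, edges=base.edges + cross_edges)
    cells = {}
    for c in CONDITIONS:
        for t in TASKS:
            cells[(c, t)] = negative if c == "negative" else base
    return StudyDesign(
        n_subjects=n_subjects,
        region_map=rm,
        base_coupling=cells,
        labels=_REDUCED_LABELS,
        seed=seed,
        **kwargs,
    )
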