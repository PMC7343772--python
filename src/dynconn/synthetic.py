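"""Synthetic multichannel EEG cohorts with known phase-coupling structure.

Real event-related EEG with labelled intention conditions is not publicly
deposited, so every downstream stage (connectivity estimation, graph metrics,
feature fusion, classification, edgewise statistics) is exercised against
cohorts generated here, where the coupled node pairs, bands, micro-time
windows, phase lags and coupling strengths are all known exactly.

Generative model
----------------
Each channel is a sum of narrowband components (band-filtered white Gaussian
noise, one component per analysis sub-band, filtered with the same zero-phase
FIRs used on real data) plus white sensor noise. A coupling entry
``(class, (i, j), band, windows, lag, strength c)`` replaces channel *j*'s
band component inside the given window range with::

    c * lagged_copy(component_i) + (1 - c) * component_j

where the lagged copy applies an exact phase rotation through the analytic
signal (valid for narrowband components). PLI/WPLI on the coupled pair are
therefore monotone in ``c``, equal to 1 at ``c = 1`` with no sensor noise, and
0 for uncoupled pairs up to estimator noise. An optional instantaneous mixing
matrix emulates volume conduction (zero-lag leakage between channels) and, by
construction, inflates amplitude correlations without creating lagged
coupling.

Determinism: one master seed; each (class, subject) draws from an independent
stream derived via ``numpy.random.SeedSequence(master, spawn_key=(class_index,
subject_index))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .preprocess import (
    BANDS,
    DEFAULT_EPOCH_MS,
    EpochSet,
    WindowGrid,
    bandpass_array,
    partition_windows,
)

__all__ = [
    "OscillatorSpec",
    "Coupling",
    "CohortSpec",
    "GroundTruth",
    "generate_oscillator_pair",
    "generate_cohort",
]


@dataclass(frozen=True)
class OscillatorSpec:
    """A pair of sinusoidal oscillators with a fixed phase lag.

    Parameters: centre frequency (Hz), phase lag of channel B behind channel A
    (radians), amplitude (µV) and additive white-noise SD (µV).
    """

    center_frequency: float = 10.0
    phase_lag: float = 0.0
    amplitude: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")


def generate_oscillator_pair(
    spec: OscillatorSpec, n_samples: int, fs: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two sinusoidal channels where B lags A by ``spec.phase_lag`` radians.

    Independent Gaussian noise of ``spec.noise_sd`` is added per channel.
    Deterministic per seed.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n_samples) / fs
    omega = 2.0 * np.pi * spec.center_frequency
    a = spec.amplitude * np.cos(omega * t + phi0)
    b = spec.amplitude * np.cos(omega * t + phi0 - spec.phase_lag)
    if spec.noise_sd > 0:
        a = a + rng.normal(0.0, spec.noise_sd, n_samples)
        b = b + rng.normal(0.0, spec.noise_sd, n_samples)
    return a, b


@dataclass(frozen=True)
class Coupling:
    """One injected phase-coupling: class, node pair, band, inclusive 1-based
    window range, phase lag (rad) and coupling strength in [0, 1]."""

    class_label: str
    pair: tuple[int, int]
    band: str
    windows: tuple[int, int]
    phase_lag: float = np.pi / 4
    strength: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")
        if self.band not in BANDS:
            raise KeyError(f"unknown band {self.band!r}")
        if self.windows[0] > self.windows[1] or self.windows[0] < 1:
            raise ValueError("window range must be 1-based and increasing")
        if self.pair[0] == self.pair[1]:
            raise ValueError("coupling pair must join two distinct nodes")


@dataclass
class CohortSpec:
    """Study-scale description of a synthetic cohort.

    Defaults mirror the experimental scale emulated throughout the package:
    25 subjects per class, 98 trials per condition, 500 Hz sampling and a
    -650..2500 ms epoch. ``band_amplitude_uv`` is the SD of each narrowband
    background component and ``noise_sd_uv`` the white sensor-noise SD.
    """

    n_subjects_per_class: int = 25
    n_trials: int = 98
    n_channels: int = 8
    fs: float = 500.0
    epoch_window_ms: tuple[float, float] = DEFAULT_EPOCH_MS
    classes: tuple[str, ...] = ("A", "B")
    class_coupling: Sequence[Coupling] = field(default_factory=list)
    mixing_matrix: np.ndarray | None = None
    background_bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
    band_amplitude_uv: float = 5.0
    noise_sd_uv: float = 2.0
    window_ms: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.epoch_window_ms[0] >= self.epoch_window_ms[1]:
            raise ValueError("epoch window start must precede end")
        if self.n_subjects_per_class < 1 or self.n_trials < 1 or self.n_channels < 2:
            raise ValueError("cohort needs >=1 subject, >=1 trial, >=2 channels")
        for c in self.class_coupling:
            if c.class_label not in self.classes:
                raise ValueError(f"coupling references unknown class {c.class_label!r}")
            if max(c.pair) >= self.n_channels:
                raise IndexError(
                    f"coupling pair {c.pair} exceeds n_channels={self.n_channels}"
                )
        if self.mixing_matrix is not None:
            m = np.asarray(self.mixing_matrix, dtype=float)
            if m.shape != (self.n_channels, self.n_channels):
                raise ValueError("mixing matrix must be n_channels x n_channels")
            if not np.isfinite(m).all():
                raise ValueError("mixing matrix must be finite")

    @property
    def n_samples(self) -> int:
        w0, w1 = self.epoch_window_ms
        return int(round((w1 - w0) * self.fs / 1000.0))

    def grid(self) -> WindowGrid:
        return partition_windows(
            self.n_samples, self.window_ms, fs=self.fs, origin_ms=self.epoch_window_ms[0]
        )


@dataclass
class GroundTruth:
    """Exactly the injected coupling structure, plus the generator seed."""

    couplings: list[Coupling]
    classes: tuple[str, ...]
    n_channels: int
    seed: int

    def edges(self, class_label: str, band: str | None = None) -> set[tuple[int, int]]:
        """Injected (sorted) node pairs for a class, optionally one band."""
        out = set()
        for c in self.couplings:
            if c.class_label == class_label and (band is None or c.band == band):
                if c.strength > 0:
                    out.add(tuple(sorted(c.pair)))
        return out


def _lagged_copy(x: np.ndarray, lag: float) -> np.ndarray:
    """Phase-rotate a narrowband signal by ``lag`` radians (exact via the
    analytic signal)."""
    return np.real(hilbert(x, axis=-1) * np.exp(-1j * lag))


def _subject_epochs(spec: CohortSpec, class_idx: int, subj_idx: int) -> EpochSet:
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(class_idx, subj_idx))
    )
    n_samp = spec.n_samples
    grid = spec.grid()
    # pad generously so band filtering sees no epoch edges
    pad = max(2000, n_samp // 2)
    shape = (spec.n_trials, spec.n_channels, n_samp + 2 * pad)
    components: dict[str, np.ndarray] = {}
    for band in spec.background_bands:
        lo, hi = BANDS[band]
        noise = rng.standard_normal(shape)
        comp = bandpass_array(noise, lo, hi, spec.fs)[..., pad : pad + n_samp]
        sd = comp.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        components[band] = comp / sd * spec.band_amplitude_uv

    cls = spec.classes[class_idx]
    for c in spec.class_coupling:
        if c.class_label != cls or c.strength == 0.0:
            continue
        if c.band not in components:
            raise ValueError(
                f"coupling band {c.band!r} not among background bands {spec.background_bands}"
            )
        i, j = c.pair
        sl = grid.range_slice(*c.windows)
        src = components[c.band][:, i, :]
        shifted = _lagged_copy(src, c.phase_lag)
        own = components[c.band][:, j, sl]
        components[c.band][:, j, sl] = c.strength * shifted[:, sl] + (1.0 - c.strength) * own

    data = sum(components.values())
    if spec.mixing_matrix is not None:
        m = np.asarray(spec.mixing_matrix, dtype=float)
        data = np.einsum("ck,tks->tcs", m, data)
    if spec.noise_sd_uv > 0:
        data = data + rng.normal(0.0, spec.noise_sd_uv, data.shape)
    return EpochSet(
        data=data,
        fs=spec.fs,
        origin_ms=spec.epoch_window_ms[0],
        channels=[f"ch{i}" for i in range(spec.n_channels)],
        labels=np.repeat(cls, spec.n_trials),
    )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[tuple[str, int], EpochSet], GroundTruth]:
    """Generate one :class:`~dynconn.preprocess.EpochSet` per (class, subject).

    Returns a mapping keyed ``(class_label, subject_index)`` plus the exact
    injected :class:`GroundTruth`. Identical specs (including seed) produce
    bitwise-identical cohorts.
    """
    epochs: dict[tuple[str, int], EpochSet] = {}
    for ci, cls in enumerate(spec.classes):
        for si in range(spec.n_subjects_per_class):
            epochs[(cls, si)] = _subject_epochs(spec, ci, si)
    truth = GroundTruth(
        couplings=list(spec.class_coupling),
        classes=spec.classes,
        n_channels=spec.n_channels,
        seed=spec.seed,
    )
    return epochs, truth
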