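"""EEG preprocessing chain.

Reproduces the standard event-related pipeline used for dynamic functional
connectivity analysis: mastoid re-referencing, zero-phase band filtering,
epoching around stimulus onsets, pre-stimulus baseline subtraction,
amplitude-threshold artifact rejection, and partition of each epoch into
contiguous 50 ms micro-time windows.

Conventions
-----------
* Voltages are in microvolts, time in milliseconds relative to stimulus onset.
* A :class:`Recording` is ``channels x samples``; an :class:`EpochSet` is
  ``trials x channels x samples``.
* Micro-time windows are numbered from 1; with the default 500 Hz sampling
  rate and a -650..2500 ms epoch, window 1 covers samples 1-25
  (-650..-600 ms) and the grid has 63 windows of 25 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)

#: Canonical analysis bands (Hz): the four classical sub-bands plus the full band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "full": (1.0, 30.0),
}

#: Fixed band ordering used everywhere a "band-major" layout is required.
BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "full")

DEFAULT_EPOCH_MS: tuple[float, float] = (-650.0, 2500.0)
DEFAULT_BASELINE_MS: tuple[float, float] = (-650.0, 0.0)
DEFAULT_REJECT_UV: float = 75.0
DEFAULT_WINDOW_MS: float = 50.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """A continuous multichannel recording (``channels x samples``, microvolts)."""

    data: np.ndarray
    fs: float
    channels: list[str]
    reference: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} rows"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("Recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Epoched trials (``trials x channels x samples``) time-locked to stimulus onset."""

    data: np.ndarray
    fs: float
    origin_ms: float = DEFAULT_EPOCH_MS[0]
    channels: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be 3-D (trials x channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[1])]
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.data.shape[0]:
                raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        """Per-sample times in ms relative to stimulus onset."""
        return self.origin_ms + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass(frozen=True)
class WindowGrid:
    """Contiguous, non-overlapping micro-time windows covering an epoch.

    Windows are numbered from 1; window *w* spans samples
    ``(w-1)*samples_per_window .. w*samples_per_window - 1`` (0-based).
    """

    width_ms: float
    samples_per_window: int
    n_windows: int
    fs: float
    origin_ms: float

    def bounds(self, window: int) -> tuple[int, int]:
        """0-based half-open sample range ``(start, stop)`` of a 1-based window."""
        if not 1 <= window <= self.n_windows:
            raise ValueError(f"window {window} outside 1..{self.n_windows}")
        start = (window - 1) * self.samples_per_window
        return start, start + self.samples_per_window

    def sample_slice(self, window: int) -> slice:
        start, stop = self.bounds(window)
        return slice(start, stop)

    def range_slice(self, first: int, last: int) -> slice:
        """Samples covered by the inclusive window range ``first..last``."""
        if last < first:
            raise ValueError("window range must satisfy first <= last")
        return slice(self.bounds(first)[0], self.bounds(last)[1])

    def window_times_ms(self, window: int) -> tuple[float, float]:
        start, stop = self.bounds(window)
        step = 1000.0 / self.fs
        return self.origin_ms + start * step, self.origin_ms + stop * step

    @property
    def n_samples(self) -> int:
        return self.n_windows * self.samples_per_window


@dataclass
class RejectionReport:
    """Bookkeeping for amplitude-threshold artifact rejection."""

    max_abs: np.ndarray  # per-trial max |amplitude| (µV)
    kept: np.ndarray  # boolean mask over trials
    threshold: float

    @property
    def n_total(self) -> int:
        return int(self.kept.size)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def n_dropped(self) -> int:
        return self.n_total - self.n_kept


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _transition_bw(edge: float, headroom: float) -> float:
    # 25% of the edge, floored at 2 Hz, never wider than the available headroom
    return float(min(max(0.25 * edge, 2.0), headroom))


def design_bandpass(low: float, high: float, fs: float) -> np.ndarray:
    """Design a linear-phase Hamming windowed-sinc band-pass FIR.

    The number of taps follows the usual Hamming main-lobe rule
    ``numtaps ~ 3.3 * fs / transition_bw`` using the narrower of the two
    transition bands.
    """
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"invalid band ({low}, {high}) Hz for fs={fs} Hz")
    trans = min(_transition_bw(low, low), _transition_bw(high, fs / 2.0 - high))
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    return _signal.firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=fs)


def bandpass_array(x: np.ndarray, low: float, high: float, fs: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis.

    The linear-phase FIR from :func:`design_bandpass` is applied as its real
    (zero-phase) amplitude response in the frequency domain, after reflection
    padding; this is the exact zero-phase counterpart of the windowed-sinc
    filter and avoids the transient-length limits of ``filtfilt`` for long
    low-frequency filters on short signals.
    """
    x = np.asarray(x, dtype=float)
    taps = design_bandpass(low, high, fs)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("signal too short to filter")
    pad = min(n - 1, len(taps))
    width = [(0, 0)] * (x.ndim - 1) + [(pad, pad)]
    xp = np.pad(x, width, mode="reflect")
    nfft = xp.shape[-1]
    freqs_idx = np.arange(nfft // 2 + 1)
    # remove the linear phase exp(-i*omega*(numtaps-1)/2) -> real amplitude response
    amp = (
        np.fft.rfft(taps, nfft) * np.exp(1j * np.pi * freqs_idx * (len(taps) - 1) / nfft)
    ).real
    y = np.fft.irfft(np.fft.rfft(xp, axis=-1) * amp, n=nfft, axis=-1)
    return y[..., pad : pad + n]


def bandpass(rec: Recording, band: str | tuple[float, float]) -> Recording:
    """Zero-phase band-pass filter a recording.

    ``band`` is either a named band from :data:`BANDS` or a ``(low, high)``
    pair in Hz.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    return replace(rec, data=bandpass_array(rec.data, lo, hi, rec.fs))


def filter_epochs(ep: EpochSet, band: str | tuple[float, float]) -> EpochSet:
    """Band-pass already-epoched data (reflection-padded per trial).

    Prefer filtering the continuous recording before epoching when possible;
    this entry point exists for data that arrives pre-epoched (e.g. the
    synthetic cohorts) and accepts the residual edge leakage.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    out = replace(ep, data=bandpass_array(ep.data, lo, hi, ep.fs))
    out.band = band if isinstance(band, str) else f"{lo:g}-{hi:g}"
    return out


# ---------------------------------------------------------------------------
# re-referencing / epoching / baseline / rejection
# ---------------------------------------------------------------------------


def rereference(rec: Recording, ref_labels: Sequence[str]) -> Recording:
    """Re-reference to the average of the given channels (e.g. mastoids M1, M2)."""
    if not ref_labels:
        raise ValueError("at least one reference channel required")
    idx = []
    for lab in ref_labels:
        if lab not in rec.channels:
            raise KeyError(f"reference channel {lab!r} not in recording")
        idx.append(rec.channels.index(lab))
    ref = rec.data[idx].mean(axis=0)
    return replace(rec, data=rec.data - ref, reference="avg(" + ",".join(ref_labels) + ")")


def epoch(
    rec: Recording,
    events_ms: Sequence[float],
    window_ms: tuple[float, float] = DEFAULT_EPOCH_MS,
    labels: Sequence | None = None,
) -> EpochSet:
    """Cut trials around event onsets.

    Events whose window falls outside the recording are skipped with a logged
    warning (the trial count reflects only the kept events).
    """
    w0, w1 = window_ms
    if w1 <= w0:
        raise ValueError("epoch window start must precede end")
    n_samp = int(round((w1 - w0) * rec.fs / 1000.0))
    trials, kept_labels = [], []
    n_skipped = 0
    for k, onset in enumerate(events_ms):
        start = int(round((onset + w0) * rec.fs / 1000.0))
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            n_skipped += 1
            continue
        trials.append(rec.data[:, start:stop])
        if labels is not None:
            kept_labels.append(labels[k])
    if n_skipped:
        logger.warning("epoch(): skipped %d event(s) outside the recording", n_skipped)
    data = (
        np.stack(trials)
        if trials
        else np.empty((0, rec.n_channels, n_samp), dtype=float)
    )
    return EpochSet(
        data=data,
        fs=rec.fs,
        origin_ms=w0,
        channels=list(rec.channels),
        labels=np.asarray(kept_labels) if labels is not None else None,
    )


def baseline_correct(
    ep: EpochSet, interval_ms: tuple[float, float] = DEFAULT_BASELINE_MS
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over a pre-stimulus interval."""
    a, b = interval_ms
    i0 = int(round((a - ep.origin_ms) * ep.fs / 1000.0))
    i1 = int(round((b - ep.origin_ms) * ep.fs / 1000.0))
    if not (0 <= i0 < i1 <= ep.n_samples):
        raise ValueError(f"baseline interval {interval_ms} outside epoch or empty")
    base = ep.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return replace(ep, data=ep.data - base)


def reject_artifacts(
    ep: EpochSet, threshold: float = DEFAULT_REJECT_UV
) -> tuple[EpochSet, RejectionReport]:
    """Drop trials with any sample strictly outside ``[-threshold, +threshold]`` µV.

    Boundary values are retained (a trial whose extremum is exactly the
    threshold survives).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if ep.n_trials == 0:
        report = RejectionReport(np.empty(0), np.empty(0, dtype=bool), threshold)
        return ep, report
    max_abs = np.abs(ep.data).max(axis=(1, 2))
    kept = max_abs <= threshold
    out = replace(
        ep,
        data=ep.data[kept],
        labels=ep.labels[kept] if ep.labels is not None else None,
    )
    return out, RejectionReport(max_abs=max_abs, kept=kept, threshold=threshold)


def partition_windows(
    ep: EpochSet | int,
    width_ms: float = DEFAULT_WINDOW_MS,
    fs: float | None = None,
    origin_ms: float | None = None,
) -> WindowGrid:
    """Partition an epoch into contiguous non-overlapping micro-time windows.

    Accepts either an :class:`EpochSet` or a raw sample count (then ``fs`` is
    required). With the defaults (500 Hz, 50 ms, 1575-sample epoch) this
    yields 63 windows of 25 samples, window 1 starting at the epoch origin.
    """
    if isinstance(ep, EpochSet):
        n_samples, fs_, origin = ep.n_samples, ep.fs, ep.origin_ms
    else:
        if fs is None:
            raise ValueError("fs required when passing a raw sample count")
        n_samples, fs_, origin = int(ep), float(fs), float(origin_ms or 0.0)
    n_exact = width_ms * fs_ / 1000.0
    n = int(round(n_exact))
    if abs(n_exact - n) > 1e-9 or n < 1:
        raise ValueError(f"window width {width_ms} ms is not an integer sample count at fs={fs_}")
    if n_samples % n != 0:
        valid = [d * 1000.0 / fs_ for d in range(1, n_samples + 1) if n_samples % d == 0]
        raise ValueError(
            f"epoch of {n_samples} samples not divisible into {width_ms} ms windows; "
            f"valid widths (ms) include {valid[:10]}"
        )
    return WindowGrid(
        width_ms=float(width_ms),
        samples_per_window=n,
        n_windows=n_samples // n,
        fs=fs_,
        origin_ms=origin,
    )
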