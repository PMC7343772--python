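"""Phase-lag connectivity in micro-time windows.

Two estimators of phase coupling that are insensitive to zero-lag (volume
conducted) interactions:

* **PLI** (phase lag index): ``| (1/N) * sum_n sign(dtheta(t_n)) |`` where
  ``dtheta`` is the wrapped instantaneous phase difference between two
  channels, obtained from the Hilbert analytic signal. ``sign(0)`` contributes
  0 (strict signum), which is what makes purely instantaneous coupling
  invisible to the index.
* **WPLI** (weighted phase lag index):
  ``| <Im S_xy> | / < |Im S_xy| >`` with ``S_xy`` the cross-spectrum
  ``z_x * conj(z_y)`` of the analytic signals; phase-difference signs are
  weighted by the magnitude of the imaginary cross-spectrum, down-weighting
  near-zero-lag samples and reducing sensitivity to noise.

Both lie in [0, 1], are symmetric in the channel pair, and are computed here
per frequency band and per 50 ms micro-time window, pooling samples across
all retained trials within a window (25-point windows alone are too short for
a stable estimate; with T trials the effective count is ``25 * T``).

The identity ``sign(wrapped(theta_x - theta_y)) == sign(Im(z_x conj(z_y)))``
(for wrapped differences in (-pi, pi)) lets both estimators share the
cross-spectrum; the phase-series entry points below are the definitional
form and are tested against the cross-spectral route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import hilbert

from .preprocess import EpochSet, WindowGrid, filter_epochs

__all__ = [
    "instantaneous_phase",
    "wrap_phase",
    "pli",
    "wpli",
    "epoch_connectivity",
    "connectivity_tensor",
    "ConnectivityTensor",
]

METHODS = ("pli", "wpli")


def wrap_phase(d: np.ndarray) -> np.ndarray:
    """Wrap phase (differences) to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(d, dtype=float)))


def instantaneous_phase(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Instantaneous phase of the analytic (Hilbert) signal, wrapped to (-pi, pi].

    The input should already be band-limited; phase of broadband signals is
    not interpretable.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 2:
        raise ValueError("need at least 2 samples")
    if not np.any(x):
        raise ValueError("phase undefined for an all-zero signal")
    return np.angle(hilbert(x, axis=axis))


def pli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase lag index of two phase series: ``|mean(sign(wrapped(a - b)))|``.

    ``sign(0) = 0`` (strict signum), so identical signals score 0.
    """
    a = np.asarray(phase_a, dtype=float).ravel()
    b = np.asarray(phase_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 1:
        raise ValueError("need at least one sample")
    return float(np.abs(np.mean(np.sign(wrap_phase(a - b)))))


def wpli(imag_xspec: np.ndarray, return_flag: bool = False):
    """Weighted phase lag index from the imaginary cross-spectrum series.

    ``|mean(S)| / mean(|S|)``. When the denominator is zero (no lagged
    component at all) the value is 0 by convention; pass ``return_flag=True``
    to also receive that degeneracy flag.
    """
    s = np.asarray(imag_xspec, dtype=float).ravel()
    if s.size < 1:
        raise ValueError("need at least one sample")
    den = np.mean(np.abs(s))
    degenerate = den == 0.0
    value = 0.0 if degenerate else float(np.abs(np.mean(s)) / den)
    return (value, degenerate) if return_flag else value


def _windowed_estimates(
    imag_x: np.ndarray, grid: WindowGrid, method: str
) -> np.ndarray:
    """Per-window estimate from the imaginary cross-spectrum of one pair.

    ``imag_x`` has shape (trials, samples); samples are pooled across trials
    and the window's points before the modulus. Returns (n_windows,).
    """
    t, s = imag_x.shape
    n = grid.samples_per_window
    w = grid.n_windows
    blocks = imag_x[:, : w * n].reshape(t, w, n)
    if method == "pli":
        return np.abs(np.sign(blocks).mean(axis=(0, 2)))
    num = np.abs(blocks.mean(axis=(0, 2)))
    den = np.abs(blocks).mean(axis=(0, 2))
    out = np.zeros(w)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def epoch_connectivity(ep: EpochSet, grid: WindowGrid, method: str) -> np.ndarray:
    """Connectivity matrices for one band-filtered epoch set.

    Returns an array of shape ``(n_windows, n_channels, n_channels)``;
    each matrix is symmetric with zero diagonal and entries in [0, 1].
    The Hilbert transform is taken over the whole epoch (not per window) to
    limit edge artifacts; windows index into the epoch-length analytic signal.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if grid.n_samples > ep.n_samples:
        raise ValueError("window grid extends beyond the epoch")
    if ep.n_trials == 0:
        raise ValueError("no trials to estimate connectivity from")
    z = hilbert(ep.data, axis=-1)  # (trials, channels, samples)
    n = ep.n_channels
    out = np.zeros((grid.n_windows, n, n))
    for i in range(n):
        zi = z[:, i, :]
        for j in range(i + 1, n):
            imx = np.imag(zi * np.conj(z[:, j, :]))
            v = _windowed_estimates(imx, grid, method)
            out[:, i, j] = v
            out[:, j, i] = v
    return out


@dataclass
class ConnectivityTensor:
    """Connectivity matrices keyed by ``(condition, subject, band)``.

    Each value is ``(n_windows, n, n)``; ``method`` is ``"pli"`` or
    ``"wpli"``. :meth:`stack` gathers one condition/band across subjects into
    a ``(n_subjects, n_windows, n, n)`` array for the statistics stage.
    """

    values: dict[tuple[str, int, str], np.ndarray]
    method: str
    bands: tuple[str, ...]
    conditions: tuple[str, ...]
    channels: list[str] = field(default_factory=list)

    def subjects(self, condition: str) -> list[int]:
        return sorted({s for (c, s, _b) in self.values if c == condition})

    def get(self, condition: str, subject: int, band: str) -> np.ndarray:
        return self.values[(condition, subject, band)]

    def stack(self, condition: str, band: str) -> np.ndarray:
        subs = self.subjects(condition)
        return np.stack([self.values[(condition, s, band)] for s in subs])

    @property
    def n_windows(self) -> int:
        return next(iter(self.values.values())).shape[0]


def connectivity_tensor(
    epochs: Mapping[tuple[str, int], EpochSet],
    grid: WindowGrid,
    bands: Sequence[str],
    method: str,
    prefiltered: bool = False,
) -> ConnectivityTensor:
    """Build the full per-(condition, subject, band, window) tensor.

    ``epochs`` maps ``(condition, subject)`` to broadband epoch sets; each is
    band-pass filtered per band before phase extraction unless
    ``prefiltered=True`` (then ``bands`` must name the single band the data
    already occupy).
    """
    values: dict[tuple[str, int, str], np.ndarray] = {}
    conditions: list[str] = []
    channels: list[str] = []
    for (cond, subj), ep in epochs.items():
        if cond not in conditions:
            conditions.append(cond)
        channels = ep.channels
        for band in bands:
            fep = ep if prefiltered else filter_epochs(ep, band)
            values[(cond, subj, band)] = epoch_connectivity(fep, grid, method)
    return ConnectivityTensor(
        values=values,
        method=method,
        bands=tuple(bands),
        conditions=tuple(conditions),
        channels=channels,
    )
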