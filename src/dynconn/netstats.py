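"""Statistical battery for dynamic network comparisons.

Four tests mirror the analysis figures of event-related network studies:

* pointwise two-sample t-tests on ERP waveforms (uncorrected, alpha 0.05);
* per-window t-tests on graph-metric trajectories (paired within subjects);
* whole-network rank-sum tests per micro-time window (the per-subject network
  summary is the mean edge weight), Benjamini-Hochberg FDR across windows at
  alpha 0.01;
* edgewise two-sample t-tests per window, BH-FDR across the n(n-1)/2 edges
  within each window, with node degrees of the significant subgraph.

Welch's t (unequal variances) is the default for independent comparisons;
within-subject designs use the paired t. Degenerate points (zero variance in
both groups, or all-tied ranks) get p = 1 with a log message rather than NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "EdgeTestMap",
    "fdr_correct",
    "pointwise_ttest",
    "metric_ttest",
    "network_ranksum",
    "edgewise_ttest",
]


@dataclass
class TestResult:
    """Statistics, raw p-values and the (optionally corrected) significance mask."""

    statistic: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    alpha: float
    correction: str = "none"  # 'none' | 'fdr'


@dataclass
class EdgeTestMap:
    """Edgewise test over windows: symmetric t/p/mask arrays of shape
    (n_windows, n, n) plus significant-subgraph node degrees (n_windows, n)."""

    t: np.ndarray
    p_corrected: np.ndarray
    mask: np.ndarray
    degrees: np.ndarray
    windows: np.ndarray  # 1-based window numbers tested
    alpha: float

    def edges(self, window: int) -> set[tuple[int, int]]:
        """Significant (sorted) node pairs of one 1-based window."""
        wi = int(np.flatnonzero(self.windows == window)[0])
        i, j = np.nonzero(np.triu(self.mask[wi], 1))
        return {(int(a), int(b)) for a, b in zip(i, j)}

    def all_edges(self) -> set[tuple[int, int]]:
        """Union of significant pairs over all tested windows."""
        i, j = np.nonzero(np.triu(self.mask.any(axis=0), 1))
        return {(int(a), int(b)) for a, b in zip(i, j)}


def fdr_correct(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def _safe_welch(a: np.ndarray, b: np.ndarray, axis: int = 0, paired: bool = False):
    """t-test along an axis with degenerate points mapped to (t=0, p=1)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        if paired:
            t, p = _stats.ttest_rel(a, b, axis=axis)
        else:
            t, p = _stats.ttest_ind(a, b, axis=axis, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        logger.debug("t-test: %d degenerate point(s) set to p=1", bad.sum())
        t[bad] = 0.0
        p[bad] = 1.0
    return t, p


def pointwise_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.05,
    paired: bool = False,
) -> TestResult:
    """Per-time-point two-sample t-test on subject-wise waveforms.

    Inputs are ``subjects x samples``; the mask is uncorrected at ``alpha``
    (matching conventional ERP displays).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = _safe_welch(a, b, axis=0, paired=paired)
    return TestResult(statistic=t, p=p, mask=p < alpha, alpha=alpha)


def metric_ttest(
    traj_a: np.ndarray, traj_b: np.ndarray, alpha: float = 0.05
) -> TestResult:
    """Paired per-window t-test on metric trajectories.

    Inputs are ``subjects x windows`` (or ``subjects x windows x metrics``)
    for the same subjects under two conditions.
    """
    a = np.asarray(traj_a, dtype=float)
    b = np.asarray(traj_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired design requires identical shapes")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    t, p = _safe_welch(a, b, axis=0, paired=True)
    return TestResult(statistic=t, p=p, mask=p < alpha, alpha=alpha)


def _offdiag_mean(tensors: np.ndarray) -> np.ndarray:
    """Mean off-diagonal weight per (subject, window): (S, W, n, n) -> (S, W)."""
    n = tensors.shape[-1]
    iu = np.triu_indices(n, 1)
    return tensors[..., iu[0], iu[1]].mean(axis=-1)


def network_ranksum(
    tensors_a: np.ndarray,
    tensors_b: np.ndarray,
    alpha: float = 0.01,
    correction: str = "fdr",
) -> TestResult:
    """Whole-network rank-sum test per micro-time window.

    Each subject's network in each window is summarized by its mean edge
    weight; a Wilcoxon rank-sum test compares the two conditions' summaries
    per window, followed (by default) by BH-FDR across windows at ``alpha``.
    Inputs are ``(subjects, windows, n, n)``.
    """
    sa = _offdiag_mean(np.asarray(tensors_a, dtype=float))
    sb = _offdiag_mean(np.asarray(tensors_b, dtype=float))
    if sa.shape[1] != sb.shape[1]:
        raise ValueError("window counts differ between conditions")
    n_windows = sa.shape[1]
    stat = np.zeros(n_windows)
    p = np.ones(n_windows)
    for w in range(n_windows):
        if np.ptp(sa[:, w]) == 0 and np.ptp(sb[:, w]) == 0 and sa[0, w] == sb[0, w]:
            continue  # all tied: p stays 1
        stat[w], p[w] = _stats.ranksums(sa[:, w], sb[:, w])
    if correction == "fdr":
        mask = fdr_correct(p, q=alpha)
    elif correction == "none":
        mask = p < alpha
    else:
        raise ValueError("correction must be 'fdr' or 'none'")
    return TestResult(statistic=stat, p=p, mask=mask, alpha=alpha, correction=correction)


def edgewise_ttest(
    tensors_a: np.ndarray,
    tensors_b: np.ndarray,
    alpha: float = 0.01,
    windows: np.ndarray | list[int] | None = None,
    paired: bool = False,
) -> EdgeTestMap:
    """Per-edge two-sample t-tests with BH-FDR within each window.

    Inputs are ``(subjects, windows, n, n)`` connectivity stacks for the two
    conditions. ``windows`` selects 1-based window numbers (default: all).
    The FDR family is the n(n-1)/2 edges of one window, matching the display
    granularity of per-window connectivity maps. Node degrees of the
    significant subgraph are the row sums of the mask.
    """
    a = np.asarray(tensors_a, dtype=float)
    b = np.asarray(tensors_b, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("tensor shapes (windows, n, n) must agree")
    n_windows_total, n = a.shape[1], a.shape[-1]
    if windows is None:
        windows = np.arange(1, n_windows_total + 1)
    windows = np.asarray(windows, dtype=int)
    iu = np.triu_indices(n, 1)

    t_maps = np.zeros((len(windows), n, n))
    p_maps = np.ones((len(windows), n, n))
    mask_maps = np.zeros((len(windows), n, n), dtype=bool)
    for k, w in enumerate(windows):
        ea = a[:, w - 1][:, iu[0], iu[1]]  # (subjects, edges)
        eb = b[:, w - 1][:, iu[0], iu[1]]
        t, p = _safe_welch(ea, eb, axis=0, paired=paired)
        rej, p_adj = multipletests(p, alpha=alpha, method="fdr_bh")[:2]
        for arr, vals in ((t_maps[k], t), (p_maps[k], p_adj), (mask_maps[k], rej)):
            arr[iu] = vals
            arr[(iu[1], iu[0])] = vals
        np.fill_diagonal(p_maps[k], 1.0)
    degrees = mask_maps.sum(axis=2)
    return EdgeTestMap(
        t=t_maps,
        p_corrected=p_maps,
        mask=mask_maps,
        degrees=degrees,
        windows=windows,
        alpha=alpha,
    )
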