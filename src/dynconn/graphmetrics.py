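"""Nine threshold-free weighted graph measures.

Connectivity matrices are treated as weighted undirected graphs: nodes are
channels/ROIs, edge weights are the raw PLI/WPLI values in [0, 1] — no
binarizing threshold anywhere, since thresholding discards exactly the weak
edges whose weight carries information.

The measures, in their fixed output order:

======  =====================================================================
Cr      graph index complexity: ``4c(1-c)`` with ``c`` the largest adjacency
        eigenvalue normalized between the unit path (2 cos(pi/(n+1))) and the
        unit complete graph (n-1); 0 for both extremes, maximal in between.
GD      graph density: mean off-diagonal weight.
SGC     Shannon graph complexity: entropy of the normalized edge-weight
        distribution over the M = n(n-1)/2 edges, divided by log M.
K       average neighbour degree (weighted, Barrat): mean over non-isolated
        nodes of ``(1/s_i) sum_j w_ij s_j`` with strengths ``s``.
Ce      efficiency complexity: ``4e(1-e)`` with ``e`` the global efficiency
        normalized between the unit path and the unit complete graph.
Ge      global efficiency: mean inverse shortest-path distance on edge
        lengths ``1/w``.
C       clustering coefficient (weighted, Onnela): geometric-mean triangle
        intensity on weights normalized by the maximum weight.
L       characteristic path length: mean shortest-path distance over
        connected pairs.
SW      small-world index: ``(C/C_rand)/(L/L_rand)`` against weight-shuffled
        surrogates.
======  =====================================================================

Distances use the standard ``d = 1/w`` transform (w = 0 means no edge).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "METRIC_ORDER",
    "MetricVector",
    "validate_graph",
    "graph_density",
    "shannon_graph_complexity",
    "graph_index_complexity",
    "avg_neighbor_degree",
    "global_efficiency",
    "efficiency_complexity",
    "clustering_coefficient",
    "characteristic_path_length",
    "small_world",
    "metric_vector",
]

METRIC_ORDER: tuple[str, ...] = ("Cr", "GD", "SGC", "K", "Ce", "Ge", "C", "L", "SW")


def validate_graph(w: np.ndarray) -> np.ndarray:
    """Check symmetry, non-negativity and zero diagonal; return as float array."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if not np.allclose(np.diag(w), 0):
        raise ValueError("diagonal must be zero")
    return w


def _distances_batch(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances on edge lengths 1/w (no edge for w=0).

    Accepts ``(..., n, n)`` batches; a vectorized Floyd-Warshall, exact for
    the non-negative lengths used here and fast for the small dense matrices
    of this pipeline.
    """
    n = w.shape[-1]
    d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    idx = np.arange(n)
    d[..., idx, idx] = 0.0
    for k in range(n):
        via = d[..., :, k, None] + d[..., None, k, :]
        np.minimum(d, via, out=d)
    return d


def _distances(w: np.ndarray) -> np.ndarray:
    return _distances_batch(w)


def graph_density(w: np.ndarray) -> float:
    """Mean off-diagonal weight: ``(2 / (n(n-1))) * sum_{i<j} w_ij``."""
    w = validate_graph(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("graph density needs n >= 2 nodes")
    iu = np.triu_indices(n, 1)
    return float(w[iu].mean())


def shannon_graph_complexity(w: np.ndarray) -> float:
    """Normalized Shannon entropy of the edge-weight distribution.

    ``p_ij = w_ij / sum w`` over the M = n(n-1)/2 edges; returns
    ``H(p) / log M`` in [0, 1] (1 for uniform weights, 0 for a single edge).
    """
    w = validate_graph(w)
    n = w.shape[0]
    m = n * (n - 1) // 2
    if m < 2:
        raise ValueError("Shannon graph complexity needs n >= 3 nodes")
    weights = w[np.triu_indices(n, 1)]
    total = weights.sum()
    if total == 0:
        raise ValueError("all-zero weight matrix has no weight distribution")
    p = weights / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    return h / np.log(m)


def graph_index_complexity(w: np.ndarray) -> float:
    """``Cr = 4c(1-c)`` with the largest eigenvalue normalized between the
    unit path (lower reference) and the unit complete graph (upper)."""
    w = validate_graph(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("graph index complexity needs n >= 2 nodes")
    lam_max = float(np.linalg.eigvalsh(w)[-1])
    low = 2.0 * np.cos(np.pi / (n + 1))
    # weak graphs (all weights small) can fall below the unit-path reference;
    # clip so Cr stays in [0, 1] as for Ce
    c = float(np.clip((lam_max - low) / ((n - 1) - low), 0.0, 1.0))
    return float(4.0 * c * (1.0 - c))


def avg_neighbor_degree(w: np.ndarray) -> float:
    """Weighted average neighbour degree (Barrat): mean over non-isolated
    nodes of ``(1/s_i) * sum_j w_ij s_j``; isolated nodes are skipped."""
    w = validate_graph(w)
    s = w.sum(axis=1)
    active = s > 0
    if not active.any():
        raise ValueError("all nodes isolated: average neighbour degree undefined")
    if not active.all():
        logger.debug("avg_neighbor_degree: skipping %d isolated node(s)", (~active).sum())
    vals = (w[active] @ s) / s[active]
    return float(vals.mean())


def global_efficiency(w: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered pairs (1/inf = 0)."""
    w = validate_graph(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs n >= 2 nodes")
    d = _distances(w)
    iu = np.triu_indices(n, 1)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d[iu]), 0.0, 1.0 / d[iu])
    return float(inv.mean())


def _path_efficiency(n: int) -> float:
    # Ge of the unit-weight path graph P_n: distances are |i-j|
    ds = np.arange(1, n)
    return float((2.0 / (n * (n - 1))) * ((n - ds) / ds).sum())


def efficiency_complexity(w: np.ndarray) -> float:
    """``Ce = 4e(1-e)`` with efficiency normalized between the unit path and
    the unit complete graph on the same number of nodes (clipped to [0, 1])."""
    w = validate_graph(w)
    n = w.shape[0]
    if n < 3:
        raise ValueError("efficiency complexity needs n >= 3 nodes")
    ge = global_efficiency(w)
    lo, hi = _path_efficiency(n), 1.0
    e = float(np.clip((ge - lo) / (hi - lo), 0.0, 1.0))
    return float(4.0 * e * (1.0 - e))


def clustering_coefficient(w: np.ndarray) -> float:
    """Weighted clustering (Onnela): geometric-mean triangle intensity.

    Weights are first normalized by the maximum weight; node terms with fewer
    than two positive-weight neighbours contribute 0, and the coefficient is
    the mean over all nodes.
    """
    w = validate_graph(w)
    mx = w.max()
    if mx == 0:
        raise ValueError("all-zero weight matrix has no clustering")
    a = np.cbrt(w / mx)
    k = (w > 0).sum(axis=1)
    num = np.einsum("ij,jk,ki->i", a, a, a)  # twice the triangle intensity sum
    ci = np.zeros(w.shape[0])
    mask = k >= 2
    ci[mask] = num[mask] / (k[mask] * (k[mask] - 1))
    return float(ci.mean())


def characteristic_path_length(w: np.ndarray) -> float:
    """Mean shortest-path distance over unordered pairs on lengths 1/w.

    Disconnected pairs are excluded from the mean with a warning (dense
    phase-coupling matrices make this an edge case); an entirely disconnected
    graph yields inf.
    """
    w = validate_graph(w)
    n = w.shape[0]
    if n < 2:
        raise ValueError("characteristic path length needs n >= 2 nodes")
    d = _distances(w)[np.triu_indices(n, 1)]
    finite = np.isfinite(d)
    if not finite.all():
        warnings.warn(
            f"{(~finite).sum()} disconnected pair(s) excluded from path length",
            RuntimeWarning,
            stacklevel=2,
        )
    if not finite.any():
        return float("inf")
    return float(d[finite].mean())


def _shuffled_surrogates(
    w: np.ndarray, n_surrogates: int, rng: np.random.Generator
) -> np.ndarray:
    """(S, n, n) batch of weight-shuffled surrogates (off-diagonal weights
    permuted uniformly, symmetry preserved)."""
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    # permute the sorted weights so the draw depends only on the weight
    # multiset -> the index is exactly invariant to node relabelling
    vals = np.sort(w[iu])
    out = np.zeros((n_surrogates, n, n))
    for s in range(n_surrogates):
        out[s][iu] = rng.permutation(vals)
    return out + out.transpose(0, 2, 1)


def _clustering_batch(w: np.ndarray) -> np.ndarray:
    """Onnela clustering per graph for a (..., n, n) batch (mean over nodes)."""
    mx = w.max(axis=(-2, -1), keepdims=True)
    a = np.cbrt(np.divide(w, mx, out=np.zeros_like(w), where=mx > 0))
    k = (w > 0).sum(axis=-1)
    num = np.einsum("...ij,...jk,...ki->...i", a, a, a)
    denom = k * (k - 1)
    ci = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    return ci.mean(axis=-1)


def _path_length_batch(d: np.ndarray) -> np.ndarray:
    """Mean finite off-diagonal distance per graph for a (..., n, n) batch."""
    n = d.shape[-1]
    iu = np.triu_indices(n, 1)
    pairs = d[..., iu[0], iu[1]]
    finite = np.isfinite(pairs)
    n_finite = finite.sum(axis=-1)
    total = np.where(finite, pairs, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_finite > 0, total / n_finite, np.inf)


def small_world(
    w: np.ndarray, n_surrogates: int = 20, seed: int | np.random.Generator = 0
) -> float:
    """Small-world index ``(C/C_rand) / (L/L_rand)``.

    ``C_rand`` and ``L_rand`` are means over surrogates whose off-diagonal
    weights are uniformly permuted (symmetry preserved), seeded for
    reproducibility. A degenerate surrogate ensemble (zero clustering or path
    length) raises.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    w = validate_graph(w)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = clustering_coefficient(w)
    ell = characteristic_path_length(w)
    surr = _shuffled_surrogates(w, n_surrogates, rng)
    c_rand = float(_clustering_batch(surr).mean())
    l_rand = float(_path_length_batch(_distances_batch(surr)).mean())
    if c_rand == 0 or l_rand == 0 or not np.isfinite(l_rand):
        raise ValueError("degenerate surrogate ensemble (zero or infinite C/L)")
    return float((c / c_rand) / (ell / l_rand))


@dataclass(frozen=True)
class MetricVector:
    """The nine measures of one matrix, in the fixed order
    (Cr, GD, SGC, K, Ce, Ge, C, L, SW)."""

    Cr: float
    GD: float
    SGC: float
    K: float
    Ce: float
    Ge: float
    C: float
    L: float
    SW: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in METRIC_ORDER])

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_ORDER}


def metric_vector(
    w: np.ndarray, sw_surrogates: int = 20, seed: int | np.random.Generator = 0
) -> MetricVector:
    """All nine measures of one weighted matrix (order: Cr, GD, SGC, K, Ce,
    Ge, C, L, SW). Errors from individual measures propagate."""
    w = validate_graph(w)
    return MetricVector(
        Cr=graph_index_complexity(w),
        GD=graph_density(w),
        SGC=shannon_graph_complexity(w),
        K=avg_neighbor_degree(w),
        Ce=efficiency_complexity(w),
        Ge=global_efficiency(w),
        C=clustering_coefficient(w),
        L=characteristic_path_length(w),
        SW=small_world(w, n_surrogates=sw_surrogates, seed=seed),
    )
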