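"""Weighted graph metrics with surrogate-network normalisation.

From a non-negative symmetric connectivity matrix (PLI, or absolute
dbWPLI) the module computes, after rescaling weights to a maximum of 1:

* the weighted clustering coefficient ``C_w`` (functional segregation) —
  mean over nodes of the weighted triangle intensity around each node,
  using the geometric-mean (Onnela) triangle convention;
* the weighted characteristic path length ``L_w`` (functional
  integration) — mean shortest path over inverse-weight edge lengths;
* their surrogate-normalised versions ``C_w_norm`` and ``L_w_norm``,
  dividing by the mean metric over surrogate matrices that permute the
  empirical weights over pairs (preserving the weight distribution while
  randomising topology);
* the small-worldness index ``SWI = C_w_norm / L_w_norm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GraphMetricSet",
    "rescale_weights",
    "weighted_clustering",
    "weighted_path_length",
    "surrogate_matrix",
    "surrogate_normalise",
]


@dataclass(frozen=True)
class GraphMetricSet:
    """Raw and surrogate-normalised graph metrics of one matrix."""

    c_w: float
    c_w_norm: float
    l_w: float
    l_w_norm: float
    swi: float
    n_surrogates: int
    surrogate_seed: int


def _validate(matrix: np.ndarray) -> np.ndarray:
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    if np.any(w < 0):
        raise ValueError("graph metrics expect non-negative weights "
                         "(take absolute dbWPLI upstream)")
    return w


def rescale_weights(matrix: np.ndarray) -> np.ndarray:
    """Divide all weights by the maximum weight (max becomes 1).

    An all-zero matrix is returned unchanged.  Idempotent on already
    rescaled input.
    """
    w = _validate(matrix)
    m = w.max()
    return w.copy() if m == 0 else w / m


def weighted_clustering(matrix: np.ndarray) -> float:
    """Mean weighted clustering coefficient over all nodes.

    Node triangle intensity uses the geometric mean of the three rescaled
    edge weights (cube root of their product); node ``i`` contributes
    ``2*t_i / (k_i*(k_i-1))`` with ``k_i`` its number of non-zero-weight
    neighbours, and 0 when ``k_i < 2``.
    """
    w = _validate(matrix).copy()
    np.fill_diagonal(w, 0.0)
    wc = np.cbrt(w)
    # diag(Wc^3)_i = 2*t_i  (each triangle counted twice around i)
    two_t = np.einsum("ij,jk,ki->i", wc, wc, wc)
    k = np.count_nonzero(w, axis=1)
    denom = k * (k - 1)
    c = np.divide(two_t, denom, out=np.zeros(w.shape[0]), where=denom > 0)
    return float(c.mean())


def weighted_path_length(matrix: np.ndarray) -> float:
    """Mean shortest weighted path length over ordered node pairs.

    Edge lengths are inverse weights (zero weight = no edge); all-pairs
    shortest paths by Dijkstra's algorithm; the result is the mean over
    nodes of the mean distance to the other n-1 nodes.  Pairs in different
    components are excluded from the average with a warning (dense
    phase-lag matrices should not produce them).
    """
    w = _validate(matrix)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if finite.sum() < off.sum():
        warnings.warn("disconnected node pairs excluded from path length",
                      RuntimeWarning, stacklevel=2)
        if not finite.any():
            return float("inf")
        return float(d[finite].mean())
    return float(d[off].mean())


def surrogate_matrix(matrix: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Topology-randomised surrogate preserving the weight distribution.

    The strict-upper-triangle weights are uniformly permuted over pairs
    and mirrored back to symmetry.
    """
    w = _validate(matrix)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = rng.permutation(w[iu])
    s = np.zeros_like(w)
    s[iu] = vals
    return s + s.T


def surrogate_normalise(matrix: np.ndarray, n_surrogates: int = 1000,
                        seed: int = 0) -> GraphMetricSet:
    """Normalise graph metrics by their means over surrogate matrices.

    ``C_w_norm = C_w / mean(C_w over surrogates)``, likewise for ``L_w``,
    and ``SWI = C_w_norm / L_w_norm`` exactly.  Deterministic given
    ``seed``.  Weights are rescaled (max 1) before any metric, for the
    observed matrix and surrogates alike.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    w = rescale_weights(matrix)
    c_w = weighted_clustering(w)
    l_w = weighted_path_length(w)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_surrogates)
    l_rand = np.empty(n_surrogates)
    for s in range(n_surrogates):
        surr = surrogate_matrix(w, rng)
        c_rand[s] = weighted_clustering(surr)
        l_rand[s] = weighted_path_length(surr)
    c_mean = c_rand.mean()
    l_mean = l_rand.mean()
    if c_mean == 0 or l_mean == 0 or not np.isfinite(l_mean):
        raise ValueError("degenerate matrix: surrogate metric mean is 0 or "
                         "infinite, normalisation undefined")
    c_norm = c_w / c_mean
    l_norm = l_w / l_mean
    return GraphMetricSet(c_w=c_w, c_w_norm=c_norm, l_w=l_w, l_w_norm=l_norm,
                          swi=c_norm / l_norm, n_surrogates=int(n_surrogates),
                          surrogate_seed=int(seed))
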