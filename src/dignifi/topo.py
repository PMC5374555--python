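"""Topological similarity: direct-neighbor score and t-step local random walk.

Adjacent gene pairs are scored by a self-inclusive common-neighbor count
normalized by the larger node strength (the hub penalty); non-adjacent
pairs by a truncated t-step random walk. The walk operates on the
row-stochastic transition matrix P with P[i, j] = w(i, j) / K(i), which on
binary networks reduces to the classical a_ij / k_i form.

The neighborhood Γ(v) includes v itself, with w(v, v) = 1 by convention,
so an adjacent pair's endpoints each contribute 1 to the direct-neighbor
numerator. This makes the score of an isolated dyad exactly 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .network import Network

__all__ = [
    "WalkProfile",
    "walk_profile",
    "dn_similarity",
    "lrw_similarity",
    "lrw_scores_from",
    "topo_similarity",
    "topo_scores_from",
]

DEFAULT_STEPS = 3


@dataclass(frozen=True)
class WalkProfile:
    """Occupation probabilities of a t-step walk started at ``source``."""

    source: str
    t: int
    probabilities: np.ndarray  # aligned with Network.nodes

    def __getitem__(self, gene_index: int) -> float:
        return float(self.probabilities[gene_index])


def _self_inclusive_adjacency(net: Network) -> sparse.csr_matrix:
    """A + I: adjacency with the self-inclusive Γ convention (w(v,v)=1)."""
    key = "adjacency_self"
    if key not in net._cache:
        net._cache[key] = (net.adjacency() + sparse.eye_array(net.n_nodes, format="csr")).tocsr()
    return net._cache[key]


def _walk_row(net: Network, source_idx: int, t: int) -> np.ndarray:
    """pi_source(t): row ``source`` of P^t, by t sparse products with P^T."""
    key = ("walk_row", source_idx, t)
    if key not in net._cache:
        if t == 0:
            vec = np.zeros(net.n_nodes)
            vec[source_idx] = 1.0
        else:
            vec = _walk_row(net, source_idx, t - 1)
            vec = net.transition_matrix().T @ vec
        net._cache[key] = vec
    return net._cache[key]


def _walk_col(net: Network, source_idx: int, t: int) -> np.ndarray:
    """Column ``source`` of P^t: entry j is pi_j(t) evaluated at source."""
    key = ("walk_col", source_idx, t)
    if key not in net._cache:
        if t == 0:
            vec = np.zeros(net.n_nodes)
            vec[source_idx] = 1.0
        else:
            vec = _walk_col(net, source_idx, t - 1)
            vec = net.transition_matrix() @ vec
        net._cache[key] = vec
    return net._cache[key]


def walk_profile(net: Network, source: str, t: int) -> WalkProfile:
    """Evolve pi(s+1) = P^T pi(s) for t steps from the source indicator."""
    if t < 0:
        raise ValueError(f"step count must be >= 0, got {t}")
    idx = net.index(source)
    return WalkProfile(source, t, _walk_row(net, idx, t).copy())


def dn_similarity(net: Network, v_i: str, v_j: str) -> float:
    """Direct-neighbor similarity of an adjacent pair.

    sum over k in Γ(i) ∩ Γ(j) of w(i,k) · w(j,k), divided by
    sqrt(max(K(i), K(j))); Γ is self-inclusive. Only defined for edges —
    non-adjacent pairs must be routed to :func:`lrw_similarity`.
    """
    i, j = net.index(v_i), net.index(v_j)
    if not net.has_edge(v_i, v_j):
        raise ValueError(
            f"({v_i}, {v_j}) is not an edge; direct-neighbor similarity "
            "applies to adjacent pairs only"
        )
    b = _self_inclusive_adjacency(net)
    numerator = float((b[[i], :] @ b[:, [j]]).toarray()[0, 0])
    k_max = max(net.strengths[i], net.strengths[j])
    return float(numerator / np.sqrt(k_max))


def lrw_similarity(net: Network, v_i: str, v_j: str, t: int = DEFAULT_STEPS) -> float:
    """t-step local random walk similarity.

    (K(i)/M) · pi_i(t)[j] + (K(j)/M) · pi_j(t)[i]; zero whenever the two
    genes sit in different connected components.
    """
    if t < 1:
        raise ValueError(f"step count must be >= 1, got {t}")
    i, j = net.index(v_i), net.index(v_j)
    if i == j:
        raise ValueError("self-similarity is undefined; genes must differ")
    m = net.n_edges
    k = net.strengths
    return float(
        (k[i] / m) * _walk_row(net, i, t)[j] + (k[j] / m) * _walk_row(net, j, t)[i]
    )


def lrw_scores_from(net: Network, source: str, t: int = DEFAULT_STEPS) -> np.ndarray:
    """LRW similarity of ``source`` against every node, as one vector.

    Uses one forward walk (row of P^t) and one column recurrence, so the
    cost is O(t · |E|) regardless of how many targets are scored. The
    entry at the source itself is set to 0 (self-similarity excluded).
    """
    if t < 1:
        raise ValueError(f"step count must be >= 1, got {t}")
    i = net.index(source)
    m = net.n_edges
    k = net.strengths
    scores = (k[i] / m) * _walk_row(net, i, t) + (k / m) * _walk_col(net, i, t)
    scores[i] = 0.0
    return scores


def topo_similarity(net: Network, v_i: str, v_j: str, t: int = DEFAULT_STEPS) -> float:
    """Route an unordered pair: DN if adjacent, t-step LRW otherwise."""
    if v_i == v_j:
        raise ValueError("self-similarity is undefined; genes must differ")
    net.index(v_i), net.index(v_j)
    if net.has_edge(v_i, v_j):
        return dn_similarity(net, v_i, v_j)
    return lrw_similarity(net, v_i, v_j, t)


def topo_scores_from(net: Network, source: str, t: int = DEFAULT_STEPS) -> np.ndarray:
    """Topological similarity of ``source`` against every node (vectorized).

    LRW everywhere, overwritten with the DN score at the source's
    neighbors; the source's own entry is 0.
    """
    i = net.index(source)
    scores = lrw_scores_from(net, source, t)
    b = _self_inclusive_adjacency(net)
    dn_numerators = np.asarray((b[[i], :] @ b).todense()).ravel()
    adj_row = net.adjacency()[[i], :].tocoo()
    for j in adj_row.col:
        scores[j] = dn_numerators[j] / np.sqrt(max(net.strengths[i], net.strengths[j]))
    scores[i] = 0.0
    return scores
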