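"""Edge clustering coefficient and topology-only baseline centralities.

The edge clustering coefficient (ECC) of an edge (i, j) is the number of
common neighbors of its endpoints divided by the smaller endpoint degree,

    ECC(i, j) = |N_i ∩ N_j| / min(d_i, d_j),

a measure of how embedded the interaction is in triangles.  The six
baselines — degree (DC), subgraph (SC), eigenvector (EC), information (IC),
local average connectivity (LAC) and neighborhood (NC) centrality — are the
standard topology-only predictors of protein essentiality under the
centrality–lethality rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .data_io import ProteinNetwork

__all__ = [
    "EdgeScoreMap",
    "CentralityVector",
    "edge_clustering_coefficient",
    "degree_centrality",
    "subgraph_centrality",
    "eigenvector_centrality",
    "information_centrality",
    "lac",
    "neighborhood_centrality",
    "centrality_by_name",
]


@dataclass
class EdgeScoreMap:
    """Symmetric per-edge scores in [0, 1], keyed by unordered endpoint pair."""

    values: dict[frozenset[str], float]

    def __getitem__(self, edge: tuple[str, str] | frozenset[str]) -> float:
        return self.values[frozenset(edge)]

    def __contains__(self, edge: tuple[str, str] | frozenset[str]) -> bool:
        return frozenset(edge) in self.values

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CentralityVector:
    """One finite score per network node, under a method label."""

    method: str
    scores: dict[str, float]

    def ranking(self) -> list[str]:
        """All nodes in descending score order, ties broken by ID."""
        return sorted(self.scores, key=lambda p: (-self.scores[p], p))

    def __getitem__(self, pid: str) -> float:
        return self.scores[pid]


def edge_clustering_coefficient(network: ProteinNetwork) -> EdgeScoreMap:
    """ECC(i, j) = |N_i ∩ N_j| / min(d_i, d_j) for every edge of the network."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    values: dict[frozenset[str], float] = {}
    for i, j in network.edge_list():
        common = len(network.neighbors(i) & network.neighbors(j))
        values[frozenset((i, j))] = common / min(network.degree(i), network.degree(j))
    return EdgeScoreMap(values=values)


def degree_centrality(network: ProteinNetwork) -> CentralityVector:
    """DC(i) = d_i, the raw interaction count."""
    return CentralityVector(
        method="dc", scores={n: float(network.degree(n)) for n in network.nodes}
    )


def subgraph_centrality(network: ProteinNetwork, *, dense_limit: int = 5000,
                        tol: float = 1e-8) -> CentralityVector:
    """SC(i) = [e^A]_ii, closed walks from i weighted by 1/length!.

    Computed from the spectral decomposition of the adjacency matrix for
    networks up to ``dense_limit`` nodes; beyond that, the truncated
    walk-count series Σ_l (A^l)_ii / l! is summed until the additional term
    falls below ``tol``.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    order = network.sorted_nodes()
    n = len(order)
    idx = {p: k for k, p in enumerate(order)}
    if n <= dense_limit:
        a = np.zeros((n, n))
        for i, j in network.edge_list():
            a[idx[i], idx[j]] = a[idx[j], idx[i]] = 1.0
        w, v = eigh(a)
        diag = (v**2) @ np.exp(w)
    else:
        from scipy.sparse import csr_matrix, identity

        rows, cols = [], []
        for i, j in network.edge_list():
            rows += [idx[i], idx[j]]
            cols += [idx[j], idx[i]]
        a = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        term = identity(n, format="csr")
        diag = np.ones(n)
        for l in range(1, 400):
            term = (term @ a) / l
            diag = diag + term.diagonal()
            # odd powers have zero diagonal; stop on the whole term's size
            largest = np.abs(term.data).max() if term.nnz else 0.0
            if largest < tol:
                break
    return CentralityVector(
        method="sc", scores={p: float(diag[idx[p]]) for p in order}
    )


def eigenvector_centrality(network: ProteinNetwork) -> CentralityVector:
    """Principal-eigenvector entries, per connected component.

    Within each component the vector is non-negative with unit Euclidean
    norm (Perron–Frobenius sign convention); isolated nodes score 0.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    scores: dict[str, float] = {}
    for comp in network.connected_components():
        order = sorted(comp)
        if len(order) == 1:
            scores[order[0]] = 0.0
            continue
        idx = {p: k for k, p in enumerate(order)}
        a = np.zeros((len(order), len(order)))
        for i in order:
            for j in network.neighbors(i):
                a[idx[i], idx[j]] = 1.0
        w, v = eigh(a)
        vec = v[:, -1]
        # the Perron vector of a connected component has one sign throughout
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec)
        vec /= np.linalg.norm(vec)
        for p in order:
            scores[p] = float(vec[idx[p]])
    return CentralityVector(method="ec", scores=scores)


def information_centrality(network: ProteinNetwork) -> CentralityVector:
    """Stephenson–Zelen information centrality, per connected component.

    With B = D − A + J on a component of n ≥ 2 nodes and C = B⁻¹, the
    pairwise information is I_ij = 1 / (C_ii + C_jj − 2 C_ij) and
    IC(i) = n / Σ_j 1/I_ij with the self term 1/I_ii taken as 0.
    Isolated nodes score 0.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    scores: dict[str, float] = {}
    for comp in network.connected_components():
        order = sorted(comp)
        n = len(order)
        if n == 1:
            scores[order[0]] = 0.0
            continue
        idx = {p: k for k, p in enumerate(order)}
        b = np.ones((n, n))
        for i in order:
            b[idx[i], idx[i]] += network.degree(i)
            for j in network.neighbors(i):
                b[idx[i], idx[j]] -= 1.0
        c = np.linalg.inv(b)
        diag = np.diag(c)
        # Σ_j 1/I_ij over j ≠ i equals (n−1)·C_ii + trace(C) − C_ii − 2·(row sum − C_ii)
        inv_info = diag[:, None] + diag[None, :] - 2.0 * c
        np.fill_diagonal(inv_info, 0.0)
        totals = inv_info.sum(axis=1)
        for p in order:
            scores[p] = float(n / totals[idx[p]])
    return CentralityVector(method="ic", scores=scores)


def lac(network: ProteinNetwork) -> CentralityVector:
    """Local average connectivity: mean degree of i's neighbors within N_i.

    A node with no neighbors scores 0.
    """
    scores: dict[str, float] = {}
    for i in network.nodes:
        nbrs = network.neighbors(i)
        if not nbrs:
            scores[i] = 0.0
            continue
        total = sum(len(network.neighbors(u) & nbrs) for u in nbrs)
        scores[i] = total / len(nbrs)
    return CentralityVector(method="lac", scores=scores)


def neighborhood_centrality(
    network: ProteinNetwork, ecc: EdgeScoreMap | None = None
) -> CentralityVector:
    """NC(i) = Σ over incident edges (i, j) of ECC(i, j)."""
    if ecc is None:
        ecc = edge_clustering_coefficient(network) if network.n_nodes else EdgeScoreMap({})
    scores: dict[str, float] = {n: 0.0 for n in network.nodes}
    for edge, val in ecc.values.items():
        for endpoint in edge:
            scores[endpoint] += val
    return CentralityVector(method="nc", scores=scores)


_CENTRALITY_FUNCS = {
    "dc": degree_centrality,
    "sc": subgraph_centrality,
    "ec": eigenvector_centrality,
    "ic": information_centrality,
    "lac": lac,
    "nc": neighborhood_centrality,
}


def centrality_by_name(network: ProteinNetwork, method: str) -> CentralityVector:
    """Dispatch a topology-only centrality by its lowercase label."""
    try:
        func = _CENTRALITY_FUNCS[method.lower()]
    except KeyError:
        raise ValueError(
            f"unknown centrality {method!r}; choose from {sorted(_CENTRALITY_FUNCS)}"
        ) from None
    return func(network)
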