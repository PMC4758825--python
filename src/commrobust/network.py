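"""Association networks, community detection and weighted modularity.

Edge weights are simple ratio indices (SRI): for a dyad (i, j),

    SRI = x / (x + y_ij + y_i + y_j)

where, over all sampling units, x counts units in which i and j were
observed associating, y_ij units in which both were observed but not
together, and y_i / y_j units in which only one of the pair was observed.
In group mode ("gambit of the group") being in the same group *is*
associating, so y_ij = 0; in period mode both members of a dyad can be
present in a period without an observed association between them.

Communities are found by greedy agglomerative modularity optimization
(Clauset–Newman–Moore) on the weighted graph, cut at the merge step of
maximum modularity; modularity Q is the standard weighted Newman measure
computed from the community mixing matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .streams import AssociationNetwork, ObservationStream

__all__ = [
    "AssociationNetwork",
    "CommunityPartition",
    "build_sri_network",
    "detect_communities",
    "modularity",
]


@dataclass(frozen=True)
class CommunityPartition:
    """A hard partition of a network's roster into communities 0..c-1."""

    labels: dict
    c: int
    Q: float

    def __post_init__(self):
        used = set(self.labels.values())
        if used != set(range(self.c)):
            raise ValueError(f"labels must use exactly 0..{self.c - 1}, got {sorted(used)}")
        if not (-0.5 - 1e-12 <= self.Q <= 1 + 1e-12):
            raise ValueError(f"Q = {self.Q} outside [-0.5, 1]")

    def label_vector(self, roster) -> np.ndarray:
        return np.array([self.labels[r] for r in roster], dtype=np.intp)


def build_sri_network(stream: ObservationStream) -> AssociationNetwork:
    """Build the simple-ratio-index network from an observation stream.

    Vectorized over the whole stream: with X the dyadic association counts,
    B the co-presence counts and n_i the per-individual unit counts, the
    denominator x + y_ij + y_i + y_j telescopes to n_i + n_j − B_ij (the
    number of units containing i or j).  Pairs whose denominator is zero
    (neither ever observed) get weight 0.
    """
    if stream.n_units == 0:
        raise ValueError("cannot build a network from an empty stream")
    x = stream.association_counts().astype(float)
    pres = stream.presence_matrix().astype(np.int64)
    n_i = pres.sum(axis=0)
    both = (pres.T @ pres).astype(float)  # co-presence counts B
    denom = n_i[:, None] + n_i[None, :] - both
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(w, 0.0)
    return AssociationNetwork(stream.roster, w)


def _as_igraph(net: AssociationNetwork) -> ig.Graph:
    iu, ju = np.triu_indices(net.n, k=1)
    mask = net.weights[iu, ju] > 0
    g = ig.Graph(net.n)
    g.add_edges(list(zip(iu[mask].tolist(), ju[mask].tolist())))
    g.es["weight"] = net.weights[iu[mask], ju[mask]].tolist()
    return g


def detect_communities(net: AssociationNetwork) -> CommunityPartition:
    """Greedy modularity-maximizing partition of a weighted network.

    Uses igraph's fast-greedy (Clauset–Newman–Moore) agglomeration on the
    positive-weight edges, cut at maximum modularity.  Deterministic for a
    fixed roster order.  Isolated nodes (no positive edge) form singleton
    communities; a network with no edges at all yields one singleton per
    node with Q = 0 by convention.
    """
    n = net.n
    if n == 1:
        return CommunityPartition({net.roster[0]: 0}, 1, 0.0)
    g = _as_igraph(net)
    if g.ecount() == 0:
        labels = {r: k for k, r in enumerate(net.roster)}
        return CommunityPartition(labels, n, 0.0)
    dendro = g.community_fastgreedy(weights="weight")
    membership = dendro.as_clustering().membership
    # renumber communities by first appearance in roster order
    remap: dict = {}
    labels = {}
    for r, m in zip(net.roster, membership):
        labels[r] = remap.setdefault(m, len(remap))
    q = modularity(net, labels)
    return CommunityPartition(labels, len(remap), q)


def modularity(net: AssociationNetwork, labels: dict) -> float:
    """Weighted modularity Q = Σ_x (e_xx − a_x²) of a labelled network.

    The mixing matrix e counts each undirected edge once in each direction
    (symmetric ordered convention), so row and column marginals coincide:
    a_x = Σ_y e_xy.  A network with zero total weight has no mixing
    structure; Q is defined as 0 there, with a warning.
    """
    missing = [r for r in net.roster if r not in labels]
    if missing:
        raise ValueError(f"labels missing for {missing}")
    lab = np.array([labels[r] for r in net.roster])
    _, lab = np.unique(lab, return_inverse=True)
    total = net.weights.sum()
    if total == 0:
        warnings.warn("network has zero total weight; Q defined as 0", stacklevel=2)
        return 0.0
    c = lab.max() + 1
    ind = np.zeros((net.n, c))
    ind[np.arange(net.n), lab] = 1.0
    e = ind.T @ net.weights @ ind / total
    a = e.sum(axis=1)
    return float(np.trace(e) - a @ a)
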