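"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are joined agglomeratively in order of increasing raw
difference, inserting unsampled intermediate nodes so that every edge
spans exactly one mutational step, and stopping at a probabilistic
connection limit: the largest number of steps for which superimposed
(multiple-hit) change is unlikely at the chosen confidence.  A star score
quantifies how star-like each network is — the signature of recent
population expansion.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import pandas as pd

from .seqio import DistanceMatrix, HaplotypeTable

__all__ = ["connection_limit", "build_network", "star_score", "network_tables"]


def _p_multiple_hit(p_obs: float) -> float:
    """P(a differing site hides >= 2 hits), from a Jukes–Cantor hit estimate.

    The observed proportion p is corrected to an expected number of hits
    per site lambda = -3/4 ln(1 - 4p/3); superimposed change is then
    assessed as P(>= 2 hits | >= 1 hit) under a Poisson(lambda) hit count.
    """
    if p_obs <= 0:
        return 0.0
    p = min(p_obs, 0.7499)
    lam = -0.75 * math.log1p(-4.0 * p / 3.0)
    denom = -math.expm1(-lam)
    if denom <= 0:
        return 0.0
    return (1.0 - (1.0 + lam) * math.exp(-lam)) / denom


def connection_limit(length: int, confidence: float = 0.95, cap_factor: int = 3) -> int:
    """Largest j with P(no superimposed change among j differences) >= confidence.

    P_parsimony(j) = (1 - P_multiple_hit(j/L))^j, monotone non-increasing
    in j and non-decreasing in L.  The search is capped at ``cap_factor*L``
    steps (reached only at very small confidence, where every pair is
    connectable).
    """
    if length < 1:
        raise ValueError("need alignment length >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    cap = cap_factor * length
    log_conf = math.log(confidence)
    best = 0
    for j in range(1, cap + 1):
        pm = _p_multiple_hit(j / length)
        if pm >= 1.0:
            break
        if j * math.log1p(-pm) >= log_conf:  # log space: robust for tiny confidence
            best = j
        else:
            break
    return best if best > 0 else 1


def build_network(ht: HaplotypeTable, d: DistanceMatrix, limit: int) -> nx.Graph:
    """Agglomerative statistical-parsimony network on haplotype representatives.

    Pairs are processed in order of increasing raw difference; a pair in
    different components is joined when its difference is within ``limit``,
    with ``difference - 1`` inferred intermediates (count 0) on the path.
    Ties at equal difference prefer connections between higher-frequency
    haplotypes (frequency criterion of ancestral likelihood), then
    lexicographic ids.  Node attributes: ``count``, ``is_inferred``.
    """
    if ht.k == 0:
        raise ValueError("empty haplotype table")
    if limit < 1:
        raise ValueError("connection limit must be >= 1")
    if d.model != "raw_differences":
        raise ValueError("network construction requires raw_differences distances")
    if list(d.ids) != list(ht.ids):
        raise ValueError("distance matrix must be computed on the haplotype representatives")

    g = nx.Graph()
    counts = dict(zip(ht.ids, ht.counts))
    for hid in ht.ids:
        g.add_node(hid, count=counts[hid], is_inferred=False)

    pairs = []
    for i, j in itertools.combinations(range(ht.k), 2):
        diff = int(round(d.values[i, j]))
        a, b = ht.ids[i], ht.ids[j]
        pairs.append((diff, -(counts[a] + counts[b]), min(a, b), max(a, b)))
    pairs.sort()

    comp = {hid: hid for hid in ht.ids}  # union-find

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    inferred = itertools.count(1)
    for diff, _negfreq, a, b in pairs:
        if diff > limit:
            break
        if diff == 0:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        prev = a
        for _ in range(diff - 1):
            mid = f"m{next(inferred)}"
            g.add_node(mid, count=0, is_inferred=True)
            comp[mid] = ra
            g.add_edge(prev, mid)
            prev = mid
        g.add_edge(prev, b)
        comp[rb] = ra
    return g


def star_score(g: nx.Graph) -> float:
    """Degree of the busiest node divided by the edges of its component.

    1 for a perfect star; decreases as the topology elongates; 0 for an
    edgeless network.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        return 0.0
    hub, deg = max(g.degree, key=lambda kv: kv[1])
    component = nx.node_connected_component(g, hub)
    edges = g.subgraph(component).number_of_edges()
    return deg / edges


def network_tables(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(edge list, node table) ready for CSV export."""
    edges = pd.DataFrame(sorted(g.edges()), columns=["node_a", "node_b"])
    nodes = pd.DataFrame(
        [
            {"node": n, "count": attrs["count"], "is_inferred": attrs["is_inferred"]}
            for n, attrs in sorted(g.nodes(data=True))
        ]
    )
    return edges, nodes
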