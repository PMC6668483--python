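"""Seed-based initial clusters: seed selection, prior-timepoint attachment, refinement.

Before MCL runs on a subnetwork, a warm-start clustering is assembled in
three steps: (1) nodes whose clustering coefficient strictly exceeds a
threshold lambda_c become seeds; (2) a seed that was also a seed at the
previous timestamp inherits the surviving members of its previous cluster;
(3) each cluster is refined by iteratively discarding the member with the
smallest clustering coefficient until the cluster density reaches lambda_d
or the cluster drops below 3 members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import PPINetwork


@dataclass
class SeedParams:
    """Thresholds for seed selection (lambda_c) and density refinement (lambda_d)."""

    lambda_c: float = 0.5
    lambda_d: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_c <= 1.0 and 0.0 <= self.lambda_d <= 1.0):
            raise ValueError("lambda_c and lambda_d must lie in [0, 1]")


@dataclass
class Cluster:
    """A candidate complex inside one timestamp's subnetwork."""

    members: frozenset[str]
    timestamp: int
    n: int = field(default=0)
    l: int = field(default=0)
    density: float = field(default=0.0)

    @classmethod
    def from_members(
        cls, members: frozenset[str] | set[str], subnet: PPINetwork, timestamp: int
    ) -> "Cluster":
        members = frozenset(members)
        n = len(members)
        l = sum(
            1 for u, v in subnet.graph.edges if u in members and v in members
        )
        density = 2.0 * l / (n * (n - 1)) if n >= 2 else 0.0
        return cls(members=members, timestamp=timestamp, n=n, l=l, density=density)


def clustering_coefficient(net: PPINetwork, node: str) -> float:
    """Local clustering coefficient 2*n_i / (deg*(deg-1)); 0 when degree < 2."""
    if node not in net:
        raise KeyError(node)
    return float(nx.clustering(net.graph, node))


def select_seeds(net: PPINetwork, params: SeedParams) -> set[str]:
    """Nodes whose clustering coefficient strictly exceeds lambda_c."""
    cc = nx.clustering(net.graph)
    return {n for n, psi in cc.items() if psi > params.lambda_c}


def attach_previous(
    seeds_t: set[str],
    prev_clusters: dict[str, frozenset[str]],
    subnet_t: PPINetwork,
) -> list[Cluster]:
    """Build initial clusters at timestamp t from seeds and prior clusters.

    ``prev_clusters`` maps each seed of timestamp t-1 to the members of its
    final cluster there (empty at the first timestamp).  A seed that persists
    from t-1 carries over the prior members still present in the current
    subnetwork; a fresh seed starts as a singleton.
    """
    nodes_t = subnet_t.nodes
    clusters = []
    for seed in sorted(seeds_t):
        if seed in prev_clusters:
            members = ({seed} | set(prev_clusters[seed])) & nodes_t
        else:
            members = {seed}
        clusters.append(Cluster.from_members(members, subnet_t, timestamp=0))
    return clusters


def refine(cluster: Cluster, subnet: PPINetwork, params: SeedParams) -> Cluster:
    """Iteratively drop the lowest-clustering-coefficient member until dense enough.

    Stops when density >= lambda_d or fewer than 3 members remain (smaller
    clusters are discarded later by the minimum-size rule anyway).  Ties on
    the coefficient are broken by removing the lexicographically smallest ID,
    which makes refinement deterministic.  Coefficients are those of the full
    subnetwork, fixed over the loop; counts and density are recomputed after
    every removal.
    """
    members = set(cluster.members)
    if not members:
        return cluster
    psi = nx.clustering(subnet.graph, members)
    cur = Cluster.from_members(members, subnet, cluster.timestamp)
    while cur.density < params.lambda_d and cur.n >= 3:
        victim = min(members, key=lambda m: (psi.get(m, 0.0), m))
        members.discard(victim)
        cur = Cluster.from_members(members, subnet, cluster.timestamp)
    return cur
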