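"""Cross-group network comparison: keystone overlap, feature vectors, dendrograms.

Each diet group yields its own co-occurrence network; the questions asked of
them are comparative — do two keystones share their co-occurring partners
(match percent), and which groups have similar networks overall (hierarchical
clustering of per-group feature vectors built from node betweenness z-values
and edge correlations over a shared taxon universe)?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import CentralityReport, CooccurrenceNetwork

__all__ = [
    "GroupNetworkSet",
    "MatchResult",
    "neighbor_set",
    "keystone_match_percent",
    "edge_profile_vector",
    "group_feature_vector",
    "hierarchical_dendrogram",
    "DendrogramNode",
    "count_communities",
]


@dataclass
class GroupNetworkSet:
    """Per-group networks and centrality reports over a shared taxon universe."""

    networks: dict[str, CooccurrenceNetwork]
    reports: dict[str, CentralityReport]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.universe:
            seen: dict[str, None] = {}
            for net in self.networks.values():
                for n in net.nodes:
                    seen.setdefault(n, None)
            self.universe = list(seen)
        uni = set(self.universe)
        for g, net in self.networks.items():
            missing = set(net.nodes) - uni
            if missing:
                raise ValueError(f"group {g!r} has taxa outside the universe: {sorted(missing)[:3]}")

    @property
    def groups(self) -> list[str]:
        return list(self.networks)

    def pair_order(self) -> list[tuple[str, str]]:
        """Fixed ordering of universe pairs shared by all feature vectors."""
        u = self.universe
        return [(u[i], u[j]) for i in range(len(u)) for j in range(i + 1, len(u))]


@dataclass
class MatchResult:
    """Neighbor-set overlap between two keystone taxa in one group's network."""

    group: str
    keystone_pair: tuple[str, str]
    intersection_size: int
    union_size: int
    percent: float
    denominator: str = "union"
    both_empty: bool = False


def neighbor_set(net: CooccurrenceNetwork, taxon: str) -> set[str]:
    """Taxa adjacent to ``taxon``; excludes the taxon itself."""
    return net.neighbor_set(taxon)


def keystone_match_percent(
    net: CooccurrenceNetwork,
    a: str,
    b: str,
    denominator: str = "union",
    group: str = "",
) -> MatchResult:
    """Percent overlap of the co-occurring partners of keystones ``a`` and ``b``.

    The two keystones themselves are removed from both neighbor sets first.
    ``denominator="union"`` gives 100·|∩|/|∪| (Jaccard); ``"min"`` gives the
    overlap coefficient 100·|∩|/min(|A|,|B|).  Two empty neighbor sets yield
    0% with ``both_empty=True`` rather than a 0/0.
    """
    if a == b:
        raise ValueError("keystone pair must be two distinct taxa")
    if denominator not in {"union", "min"}:
        raise ValueError("denominator must be 'union' or 'min'")
    na = net.neighbor_set(a) - {a, b}
    nb = net.neighbor_set(b) - {a, b}
    inter = na & nb
    union = na | nb
    both_empty = not na and not nb
    if both_empty:
        pct = 0.0
    elif denominator == "union":
        pct = 100.0 * len(inter) / len(union)
    else:
        m = min(len(na), len(nb))
        pct = 0.0 if m == 0 else 100.0 * len(inter) / m
    return MatchResult(
        group=group,
        keystone_pair=(a, b),
        intersection_size=len(inter),
        union_size=len(union),
        percent=pct,
        denominator=denominator,
        both_empty=both_empty,
    )


def edge_profile_vector(net_set: GroupNetworkSet, taxon: str, group: str) -> np.ndarray:
    """Correlations of ``taxon``'s edges in one group, indexed by the universe.

    Entry u holds the signed edge correlation between ``taxon`` and u in that
    group's network, 0 where no edge exists.  A taxon absent from the group's
    network yields the all-zero vector (absence is the natural zero).
    """
    if taxon not in net_set.universe:
        raise KeyError(f"taxon not in universe: {taxon!r}")
    net = net_set.networks[group]
    out = np.zeros(len(net_set.universe))
    if taxon not in net.graph:
        return out
    for k, u in enumerate(net_set.universe):
        if u != taxon and u in net.graph:
            out[k] = net.edge_weight(taxon, u)
    return out


def group_feature_vector(
    net_set: GroupNetworkSet, group: str, node_feature: str = "z_value"
) -> np.ndarray:
    """Concatenated node-feature and edge-correlation vector for one group.

    First the node feature (betweenness z-value by default, raw betweenness as
    a variant) over the universe, then the edge correlation over all universe
    pairs in the fixed shared order; absent taxa and absent edges contribute 0.
    Length is D + D(D−1)/2.
    """
    if node_feature not in {"z_value", "raw_betweenness"}:
        raise ValueError("node_feature must be 'z_value' or 'raw_betweenness'")
    net = net_set.networks[group]
    rep = net_set.reports[group]
    src = rep.z_value if node_feature == "z_value" else rep.betweenness
    nodes = np.array([src.get(t, 0.0) for t in net_set.universe])
    edges = np.array(
        [net.edge_weight(a, b) if (a in net.graph and b in net.graph) else 0.0
         for a, b in net_set.pair_order()]
    )
    return np.concatenate([nodes, edges])


# ------------------------------------------------------------------ dendrogram
@dataclass
class DendrogramNode:
    """A merge-tree node; leaves carry a label, internal nodes two children."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def leaves(self) -> list[str]:
        if self.children is None:
            return [self.label]
        return self.children[0].leaves + self.children[1].leaves

    def merge_heights(self) -> list[float]:
        if self.children is None:
            return []
        return [self.height] + self.children[0].merge_heights() + self.children[1].merge_heights()

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""

        def rec(node: DendrogramNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.children is None:
                return f"{_newick_escape(node.label)}:{bl:.10g}"
            inner = ",".join(rec(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        if self.children is None:
            return f"{_newick_escape(self.label)};"
        inner = ",".join(rec(c, self.height) for c in self.children)
        return f"({inner});"


def _newick_escape(label: str) -> str:
    if any(c in label for c in " ();:,[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def hierarchical_dendrogram(
    vectors: dict[str, np.ndarray], metric: str = "euclidean", linkage: str = "average"
) -> DendrogramNode:
    """Agglomerative merge tree over group feature vectors.

    Cluster distance is the average (UPGMA) or maximum (complete) of the
    pairwise Euclidean point distances.  Ties are broken deterministically by
    the lexicographically smallest member labels of the candidate pair, so the
    tree does not depend on input ordering.
    """
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    if linkage not in {"average", "complete"}:
        raise ValueError("linkage must be 'average' or 'complete'")
    labels = sorted(vectors)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups to cluster")
    dim = len(np.asarray(vectors[labels[0]]).ravel())
    pts = {}
    for g in labels:
        v = np.asarray(vectors[g], dtype=float).ravel()
        if v.size != dim:
            raise ValueError(f"vector for {g!r} has length {v.size}, expected {dim}")
        pts[g] = v
    # point-to-point distances; cluster distances are linkage functions of these
    pdist = {
        (a, b): float(np.linalg.norm(pts[a] - pts[b]))
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }

    def point_d(a: str, b: str) -> float:
        return pdist[(a, b)] if (a, b) in pdist else pdist[(b, a)]

    clusters: dict[tuple[str, ...], DendrogramNode] = {
        (g,): DendrogramNode(height=0.0, label=g) for g in labels
    }

    def cluster_d(ka: tuple[str, ...], kb: tuple[str, ...]) -> float:
        ds = [point_d(a, b) for a in ka for b in kb]
        return float(np.mean(ds)) if linkage == "average" else float(max(ds))

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                d = cluster_d(ka, kb)
                cand = (d, ka, kb)  # lexicographic tie-break on member labels
                if best is None or cand < best:
                    best = cand
        d, ka, kb = best
        node = DendrogramNode(height=d, children=(clusters.pop(ka), clusters.pop(kb)))
        clusters[tuple(sorted(ka + kb))] = node
    return next(iter(clusters.values()))


def count_communities(
    report: CentralityReport,
    scope: str = "all_nodes",
    abundance: dict[str, float] | None = None,
    rank_cutoff: int = 4,
) -> int:
    """Number of distinct community labels among the nodes in scope.

    ``scope="displayed_subset"`` restricts to keystone taxa plus the
    ``rank_cutoff`` most abundant taxa (the display rule used for the study's
    network figures); it requires a per-taxon ``abundance`` map.
    """
    if scope == "all_nodes":
        nodes = list(report.community)
    elif scope == "displayed_subset":
        if abundance is None:
            raise ValueError("displayed_subset scope needs an abundance map")
        ranked = sorted(report.community, key=lambda n: (-abundance.get(n, 0.0), n))
        nodes = set(ranked[:rank_cutoff]) | report.keystones()
    else:
        raise ValueError("scope must be 'all_nodes' or 'displayed_subset'")
    return len({report.community[n] for n in nodes})
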