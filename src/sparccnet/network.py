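"""Co-occurrence network construction, centrality and keystone calling.

A co-occurrence network keeps every taxon as a node and draws an edge where
the estimated correlation magnitude exceeds a threshold (0.3 by default, the
common choice for gut-microbiome SparCC networks).  Node importance is
measured by betweenness centrality on the unweighted graph — correlation
weights are similarities, not path costs, so feeding them to a shortest-path
routine as distances would invert their meaning; a 1−|rho| distance mode is
available for sensitivity analysis.  Betweenness is standardized within each
network to a z-value and taxa with z > 2 (strict) are called keystones.
Communities come from Louvain modularity maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .sparcc import CorrelationEstimate

__all__ = [
    "CooccurrenceNetwork",
    "CentralityReport",
    "NetworkAnalyzer",
    "build_network",
    "betweenness_centrality",
    "zscore_centrality",
    "louvain_partition",
    "call_keystones",
    "analyze_network",
]


@dataclass
class CooccurrenceNetwork:
    """Undirected taxon graph; edges are supra-threshold correlations.

    Edge attributes: ``weight`` (signed correlation) and ``abs_weight``.
    Isolated taxa stay in the node set so per-network statistics cover the
    full taxon list.
    """

    graph: nx.Graph
    threshold: float
    mode: str = "absolute"

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbor_set(self, taxon: str) -> set[str]:
        """All taxa sharing an edge with ``taxon`` (never the taxon itself)."""
        if taxon not in self.graph:
            raise KeyError(f"taxon not in network: {taxon!r}")
        return set(self.graph.neighbors(taxon))

    def edge_weight(self, a: str, b: str) -> float:
        """Signed correlation of edge (a, b), or 0.0 if absent."""
        data = self.graph.get_edge_data(a, b)
        return 0.0 if data is None else float(data["weight"])

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def to_edge_tsv(self, path: str | Path) -> None:
        """Cytoscape-ready edge list: source, target, correlation, abs_correlation."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("source\ttarget\tcorrelation\tabs_correlation\n")
            for a, b, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{a}\t{b}\t{d['weight']:.10g}\t{abs(d['weight']):.10g}\n")


@dataclass
class CentralityReport:
    """Per-node betweenness, z-value, community label and keystone flag."""

    betweenness: dict[str, float]
    z_value: dict[str, float]
    community: dict[str, int]
    keystone: dict[str, bool]
    modularity: float
    sd_convention: str = "sample (ddof=1)"

    def keystones(self) -> set[str]:
        return {n for n, k in self.keystone.items() if k}

    def n_communities(self) -> int:
        return len(set(self.community.values()))

    def to_tsv(self, path: str | Path, extra: dict[str, dict] | None = None) -> None:
        """Node-attribute TSV; ``extra`` adds columns (e.g. phylum, abundance)."""
        cols = list(extra or {})
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("taxon\t" + "\t".join(cols) + ("\t" if cols else "")
                     + "betweenness\tz_value\tcommunity\tkeystone\n")
            for n in self.betweenness:
                ex = "\t".join(str((extra or {})[c].get(n, "")) for c in cols)
                fh.write(
                    f"{n}\t" + (ex + "\t" if cols else "")
                    + f"{self.betweenness[n]:.10g}\t{self.z_value[n]:.10g}\t"
                    + f"{self.community[n]}\t{self.keystone[n]}\n"
                )


def build_network(
    estimate: CorrelationEstimate | np.ndarray,
    threshold: float = 0.3,
    mode: str = "absolute",
    taxa: list | None = None,
) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into an undirected taxon graph.

    ``mode="absolute"`` keeps an edge when |rho| > threshold (negative
    correlations carry co-occurrence signal too); ``mode="positive"`` keeps
    only rho > threshold.  Strict inequality either way.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    if mode not in {"absolute", "positive"}:
        raise ValueError("mode must be 'absolute' or 'positive'")
    if isinstance(estimate, CorrelationEstimate):
        rho = estimate.rho
        labels = [t.raw for t in estimate.taxa]
    else:
        rho = np.asarray(estimate, dtype=float)
        labels = [str(t) for t in taxa] if taxa is not None else [str(i) for i in range(len(rho))]
    D = rho.shape[0]
    if rho.shape != (D, D) or len(labels) != D:
        raise ValueError("correlation matrix and taxa are inconsistent")
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(D):
        for j in range(i + 1, D):
            w = float(rho[i, j])
            keep = abs(w) > threshold if mode == "absolute" else w > threshold
            if keep:
                g.add_edge(labels[i], labels[j], weight=w, abs_weight=abs(w))
    return CooccurrenceNetwork(graph=g, threshold=threshold, mode=mode)


def betweenness_centrality(
    net: CooccurrenceNetwork | nx.Graph, distance_mode: str = "unweighted"
) -> dict[str, float]:
    """Raw Brandes betweenness: unordered node pairs, unnormalized.

    With ``distance_mode="one_minus_abs"`` shortest paths minimize
    sum(1 − |rho|) instead of hop count (sensitivity variant).
    Disconnected pairs contribute nothing.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if distance_mode == "unweighted":
        return dict(nx.betweenness_centrality(g, normalized=False))
    if distance_mode == "one_minus_abs":
        h = g.copy()
        for a, b, d in h.edges(data=True):
            h[a][b]["distance"] = 1.0 - abs(d.get("weight", 1.0))
        return dict(nx.betweenness_centrality(h, normalized=False, weight="distance"))
    raise ValueError("distance_mode must be 'unweighted' or 'one_minus_abs'")


def zscore_centrality(betweenness: dict[str, float]) -> dict[str, float]:
    """Standardize betweenness within the network: z = (b − mean) / sd(ddof=1).

    A constant betweenness vector (sd = 0) maps every node to z = 0.
    """
    if len(betweenness) < 2:
        raise ValueError("z-normalization needs at least 2 nodes")
    vals = np.array(list(betweenness.values()), dtype=float)
    sd = vals.std(ddof=1)
    if sd == 0:
        return {n: 0.0 for n in betweenness}
    mean = vals.mean()
    return {n: float((b - mean) / sd) for n, b in betweenness.items()}


def louvain_partition(
    net: CooccurrenceNetwork | nx.Graph,
    weight_mode: str = "unweighted",
    seed: int = 0,
    n_restarts: int = 8,
) -> tuple[dict[str, int], float]:
    """Louvain communities and the modularity Q of the returned flat partition.

    Louvain is greedy and seed-dependent, so the partition is taken as the
    best of ``n_restarts`` seeded runs (seeds derived deterministically from
    ``seed``); ties go to the earliest restart.  ``weight_mode="abs_weight"``
    maximizes modularity on |rho| edge weights; the default treats every edge
    equally, matching the betweenness convention.  An edgeless graph yields
    singleton communities with Q defined as 0.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if weight_mode not in {"unweighted", "abs_weight"}:
        raise ValueError("weight_mode must be 'unweighted' or 'abs_weight'")
    weight = None if weight_mode == "unweighted" else "abs_weight"
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(g.nodes)}, 0.0
    best_parts, best_q = None, -np.inf
    for r in range(n_restarts):
        parts = nx.community.louvain_communities(g, weight=weight, seed=seed + r)
        q = nx.community.modularity(g, parts, weight=weight)
        if q > best_q + 1e-12:
            best_parts, best_q = parts, q
    # stable community ids: ordered by first member in node order
    order = {n: i for i, n in enumerate(g.nodes)}
    best_parts = sorted(best_parts, key=lambda c: min(order[n] for n in c))
    labels = {n: cid for cid, comm in enumerate(best_parts) for n in comm}
    return labels, float(best_q)


def call_keystones(z_value: dict[str, float]) -> set[str]:
    """Keystone taxa: betweenness z-value strictly greater than 2."""
    return {n for n, z in z_value.items() if z > 2.0}


class NetworkAnalyzer(BaseEstimator):
    """Correlation matrix → network, communities, z-values, keystones.

    scikit-learn-style transformer over a square correlation matrix
    (or :class:`~sparccnet.sparcc.CorrelationEstimate`).

    Parameters
    ----------
    threshold : float, default=0.3
        Edge cutoff on correlation magnitude.
    mode : {"absolute", "positive"}, default="absolute"
        Sign handling of the cutoff.
    distance_mode : {"unweighted", "one_minus_abs"}, default="unweighted"
        Shortest-path convention for betweenness.
    louvain_weight : {"unweighted", "abs_weight"}, default="unweighted"
    random_state : int, default=0
        Seed for the Louvain restarts.

    Attributes
    ----------
    network_ : CooccurrenceNetwork
    report_ : CentralityReport
    keystones_ : set of str
    """

    def __init__(
        self,
        threshold: float = 0.3,
        mode: str = "absolute",
        distance_mode: str = "unweighted",
        louvain_weight: str = "unweighted",
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.mode = mode
        self.distance_mode = distance_mode
        self.louvain_weight = louvain_weight
        self.random_state = random_state

    def fit(self, X, y=None, taxa: list | None = None):
        net = build_network(X, threshold=self.threshold, mode=self.mode, taxa=taxa)
        b = betweenness_centrality(net, distance_mode=self.distance_mode)
        if len(b) >= 2:
            z = zscore_centrality(b)
        else:
            z = {n: 0.0 for n in b}
        community, q = louvain_partition(
            net, weight_mode=self.louvain_weight, seed=self.random_state
        )
        keystone_set = call_keystones(z)
        self.network_ = net
        self.report_ = CentralityReport(
            betweenness=b,
            z_value=z,
            community=community,
            keystone={n: n in keystone_set for n in b},
            modularity=q,
        )
        self.keystones_ = keystone_set
        self.n_features_in_ = len(b)
        return self

    def fit_transform(self, X, y=None, **kw):
        """Fit and return the z-value vector in node order."""
        self.fit(X, y, **kw)
        return np.array(list(self.report_.z_value.values()))


def analyze_network(
    estimate: CorrelationEstimate | np.ndarray,
    threshold: float = 0.3,
    mode: str = "absolute",
    seed: int = 0,
    taxa: list | None = None,
    distance_mode: str = "unweighted",
    louvain_weight: str = "unweighted",
) -> tuple[CooccurrenceNetwork, CentralityReport]:
    """One-call wrapper over :class:`NetworkAnalyzer`."""
    ana = NetworkAnalyzer(
        threshold=threshold,
        mode=mode,
        distance_mode=distance_mode,
        louvain_weight=louvain_weight,
        random_state=seed,
    ).fit(estimate, taxa=taxa)
    return ana.network_, ana.report_
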