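"""Denoising step: prune inconsistent edges, extract the maximal component.

Pruning removes edges whose observed correlation sign contradicts the
prior; nodes stay (genes disconnected by pruning simply drop out of the
component).  Activity is then estimated over the largest connected
component of the pruned network, whose node degrees supply the weights of
the degree-weighted activity metric and the hub ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .consistency import annotate_consistency
from .io import PathwaySignature, RelevanceNetwork

__all__ = [
    "EmptyComponentError",
    "PrunedComponent",
    "prune_inconsistent",
    "max_connected_component",
    "hub_ranking",
]


class EmptyComponentError(ValueError):
    """Raised when the pruned network has no edges to form a component.

    Callers may fall back to the unpruned simple-average estimator.
    """


@dataclass
class PrunedComponent:
    """Largest connected component of the pruned (consistent-edge) network."""

    graph: nx.Graph
    signs: dict[str, int]
    parent_network_size: int

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> dict[str, int]:
        return {g: int(d) for g, d in self.graph.degree()}

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((u, v))
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "correlation": d.get("corr"),
                    "observed_sign": d.get("observed_sign"),
                    "predicted_sign": d.get("predicted_sign"),
                    "consistent": d.get("consistent"),
                }
            )
        cols = ["gene_a", "gene_b", "correlation", "observed_sign", "predicted_sign", "consistent"]
        return pd.DataFrame(rows, columns=cols)


def prune_inconsistent(net: RelevanceNetwork, sig: PathwaySignature) -> RelevanceNetwork:
    """Remove edges inconsistent with the prior; keep every node.

    Idempotent: pruning an already-consistent network returns an identical
    copy.
    """
    annotate_consistency(net, sig)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes(data=True))
    for u, v, d in net.graph.edges(data=True):
        if d["consistent"]:
            g.add_edge(u, v, **d)
    return RelevanceNetwork(graph=g, p_threshold=net.p_threshold, n_samples=net.n_samples)


def max_connected_component(
    net: RelevanceNetwork, sig: PathwaySignature | None = None
) -> PrunedComponent:
    """Largest connected component (>= 2 nodes) of a pruned network.

    Ties on node count break by edge count, then by smallest node
    identifier, so extraction is deterministic and invariant to input
    order.
    """
    components = [c for c in nx.connected_components(net.graph) if len(c) >= 2]
    if not components:
        raise EmptyComponentError(
            "pruned network has no connected component with edges; "
            "fall back to the unpruned simple-average estimator"
        )
    best = sorted(
        components,
        key=lambda c: (-len(c), -net.graph.subgraph(c).number_of_edges(), min(c)),
    )[0]
    sub = nx.Graph(net.graph.subgraph(best))
    if sig is not None:
        signs = {g: sig.signs[g] for g in sub.nodes}
    else:
        signs = {g: d.get("prior_sign") for g, d in sub.nodes(data=True)}
        if any(s is None for s in signs.values()):
            raise ValueError("node prior signs unavailable; pass the signature explicitly")
    return PrunedComponent(graph=sub, signs=signs, parent_network_size=net.n_nodes)


def hub_ranking(comp: PrunedComponent) -> pd.DataFrame:
    """Genes of a component ranked by degree (hubs first).

    Descending by degree; ties break lexicographically by gene identifier.
    """
    if comp.n_nodes == 0:
        raise ValueError("empty component")
    df = pd.DataFrame(
        {
            "gene": list(comp.degrees),
            "degree": list(comp.degrees.values()),
            "prior_sign": [comp.signs[g] for g in comp.degrees],
        }
    )
    return df.sort_values(["degree", "gene"], ascending=[False, True]).reset_index(drop=True)
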