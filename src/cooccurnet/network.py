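"""Consensus co-occurrence networks from per-replicate correlations.

An edge joins two taxa when their rank correlation passes a stringency
cutoff (default levels 0.5 and 0.75) in **every** replicate of the
ecosystem — the all-replicates consensus rule that suppresses spurious
single-replicate correlations. Edges carry the highest level they pass and
the weakest correlation magnitude seen across replicates. Positive and
negative co-occurrence are built as separate networks.

Thresholds follow the asymmetric convention: positive edges require
``rho > cutoff`` (strict) while negative edges require ``rho <= -cutoff``
(inclusive); ``inclusive=True`` makes both bounds inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .correlate import CorrelationSet

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceNetwork",
    "threshold_edges",
    "consensus_network",
    "build_consensus",
    "replicate_network",
    "union_levels",
    "intersect_networks",
]

DEFAULT_CUTOFFS = (0.5, 0.75)

Pair = tuple[str, str]


@dataclass
class CooccurrenceNetwork:
    """An ecosystem-level co-occurrence network of one sign.

    ``graph`` is a simple undirected networkx graph whose edges carry
    ``level`` (highest cutoff passed in all replicates) and ``min_abs_rho``
    (weakest correlation magnitude across replicates). Isolated nodes and
    self-loops are never present.
    """

    ecosystem: str
    sign: str  # "positive" | "negative"
    graph: nx.Graph
    provenance: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> dict[Pair, dict]:
        return {_canon(a, b): dict(d) for a, b, d in self.graph.edges(data=True)}

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": a, "taxon_b": b, "level": d["level"],
             "min_abs_rho": d["min_abs_rho"], "sign": self.sign,
             "ecosystem": self.ecosystem}
            for (a, b), d in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["taxon_a", "taxon_b", "level", "min_abs_rho",
                           "sign", "ecosystem"]
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _canon(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


def threshold_edges(
    cs: CorrelationSet, cutoff: float, sign: str = "positive",
    inclusive: bool = False,
) -> dict[Pair, float]:
    """Pairs passing the cutoff in one replicate, mapped to their rho."""
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    out: dict[Pair, float] = {}
    for (a, b), (rho, _p, _n) in cs.pairs.items():
        if sign == "positive":
            ok = rho >= cutoff if inclusive else rho > cutoff
        else:
            ok = rho <= -cutoff
        if ok:
            out[_canon(a, b)] = rho
    return out


def consensus_network(
    replicate_edge_sets: list[dict[Pair, float]],
    ecosystem: str,
    sign: str,
    level: float,
    provenance: list[str] | None = None,
) -> CooccurrenceNetwork:
    """Single-level consensus: keep an edge iff it appears in **every**
    replicate edge set; ``min_abs_rho`` is the smallest magnitude across
    replicates. Self-loops and isolated nodes are removed (isolated nodes
    cannot arise from an edge intersection, but the contract is explicit).
    An empty intersection yields a valid empty network.
    """
    if len(replicate_edge_sets) < 2:
        raise ValueError("consensus requires >= 2 replicate edge sets")
    shared = set(replicate_edge_sets[0])
    for es in replicate_edge_sets[1:]:
        shared &= set(es)
    g = nx.Graph()
    for a, b in sorted(shared):
        if a == b:
            continue
        min_abs = min(abs(es[(a, b)]) for es in replicate_edge_sets)
        g.add_edge(a, b, level=level, min_abs_rho=min_abs)
    g.remove_edges_from(nx.selfloop_edges(g))
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        logger.info("consensus_network(%s, %s, %.2f): empty intersection",
                    ecosystem, sign, level)
    return CooccurrenceNetwork(ecosystem, sign, g, provenance or [])


def union_levels(
    net_lo: CooccurrenceNetwork, net_hi: CooccurrenceNetwork
) -> CooccurrenceNetwork:
    """Name-based union of two stringency levels of the same network.

    Every edge of the higher level is also valid at the lower one, so the
    union keeps each edge at the highest level it reaches.
    """
    if (net_lo.ecosystem, net_lo.sign) != (net_hi.ecosystem, net_hi.sign):
        raise ValueError(
            f"cannot union networks from ({net_lo.ecosystem}, {net_lo.sign}) "
            f"and ({net_hi.ecosystem}, {net_hi.sign})"
        )
    g = nx.Graph()
    for net in (net_lo, net_hi):
        for (a, b), d in net.edges.items():
            if g.has_edge(a, b):
                prev = g.edges[a, b]
                g.add_edge(a, b,
                           level=max(prev["level"], d["level"]),
                           min_abs_rho=max(prev["min_abs_rho"], d["min_abs_rho"]))
            else:
                g.add_edge(a, b, **d)
    prov = sorted(set(net_lo.provenance) | set(net_hi.provenance))
    return CooccurrenceNetwork(net_lo.ecosystem, net_lo.sign, g, prov)


def build_consensus(
    correlation_sets: list[CorrelationSet],
    sign: str = "positive",
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    inclusive: bool = False,
) -> CooccurrenceNetwork:
    """Full pipeline for one ecosystem and sign: threshold each replicate at
    every cutoff, intersect across replicates per cutoff, and union the
    levels so each edge is stored at the highest cutoff it passes everywhere.
    """
    if not correlation_sets:
        raise ValueError("no correlation sets given")
    ecos = {cs.ecosystem for cs in correlation_sets}
    if len(ecos) != 1:
        raise ValueError(f"correlation sets span multiple ecosystems: {ecos}")
    eco = ecos.pop()
    prov = [cs.replicate for cs in correlation_sets]
    nets = [
        consensus_network(
            [threshold_edges(cs, c, sign, inclusive) for cs in correlation_sets],
            eco, sign, c, prov,
        )
        for c in sorted(cutoffs)
    ]
    out = nets[0]
    for net in nets[1:]:
        out = union_levels(out, net)
    return out


def replicate_network(
    cs: CorrelationSet, cutoff: float, sign: str = "positive",
    inclusive: bool = False,
) -> CooccurrenceNetwork:
    """Single-replicate thresholded network (no consensus), used for the
    per-replicate node statistics feeding the mixed model."""
    g = nx.Graph()
    for (a, b), rho in threshold_edges(cs, cutoff, sign, inclusive).items():
        g.add_edge(a, b, level=cutoff, min_abs_rho=abs(rho))
    g.remove_edges_from(nx.selfloop_edges(g))
    g.remove_nodes_from(list(nx.isolates(g)))
    net = CooccurrenceNetwork(cs.ecosystem, sign, g, [cs.replicate])
    return net


def intersect_networks(
    a: CooccurrenceNetwork, b: CooccurrenceNetwork
) -> list[Pair]:
    """Taxon pairs whose edge is present (by name) in both networks — the
    cross-ecosystem consistency report."""
    return sorted(set(a.edges) & set(b.edges))
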