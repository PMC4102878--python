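"""Divisive module detection by edge-betweenness removal (Girvan-Newman).

Modules are groups of densely interconnected taxa, poorly connected to the
rest of the network. The divisive procedure repeatedly recomputes
shortest-path edge betweenness on the remaining graph and removes the
single most-between edge; the partition kept is the one along the removal
sequence that maximizes Newman-Girvan modularity

    Q = sum_c (e_cc - a_c^2)

evaluated against the ORIGINAL edge set. Ties in edge betweenness are
broken by the lexicographically smallest edge, and Q ties by the partition
with fewer modules, so the result is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network import CooccurrenceNetwork

__all__ = ["ModulePartition", "girvan_newman", "module_summary"]

_TIE_TOL = 1e-12


@dataclass
class ModulePartition:
    """A node-to-module assignment with its modularity and removal history."""

    assignment: dict[str, int]
    n_modules: int
    modularity: float
    removal_trace: list[tuple[str, str]] = field(default_factory=list)

    def module_sizes(self) -> list[int]:
        sizes: dict[int, int] = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return [sizes[m] for m in sorted(sizes)]


def _components_assignment(g: nx.Graph) -> tuple[dict[str, int], list[set]]:
    comps = sorted(nx.connected_components(g), key=min)
    assignment = {node: i for i, comp in enumerate(comps) for node in comp}
    return assignment, comps


def _most_between_edge(g: nx.Graph) -> tuple[str, str]:
    eb = nx.edge_betweenness_centrality(g, normalized=False)
    best_val = max(eb.values())
    tied = [tuple(sorted(e)) for e, v in eb.items() if v >= best_val - _TIE_TOL]
    return min(tied)


def girvan_newman(net: CooccurrenceNetwork | nx.Graph) -> ModulePartition:
    """Best-modularity partition along the edge-betweenness removal sequence.

    Accepts either a :class:`CooccurrenceNetwork` or a bare undirected
    graph. Every module is a connected subgraph of the original network by
    construction (partitions are the connected components at some stage of
    removal). Raises on an empty network.
    """
    original = net.graph if isinstance(net, CooccurrenceNetwork) else net
    if original.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    work = nx.Graph(original)

    best_assignment, best_comps = _components_assignment(work)
    best_q = (
        nx.community.modularity(original, best_comps)
        if original.number_of_edges()
        else 0.0
    )
    best_n = len(best_comps)
    trace: list[tuple[str, str]] = []

    while work.number_of_edges():
        edge = _most_between_edge(work)
        work.remove_edge(*edge)
        trace.append(edge)
        assignment, comps = _components_assignment(work)
        q = nx.community.modularity(original, comps)
        if q > best_q + _TIE_TOL or (
            abs(q - best_q) <= _TIE_TOL and len(comps) < best_n
        ):
            best_q, best_assignment, best_n = q, assignment, len(comps)
    return ModulePartition(best_assignment, best_n, float(best_q), trace)


def module_summary(
    parts: list[tuple[str, str, float, ModulePartition]],
) -> pd.DataFrame:
    """Tabulate partitions as (ecosystem, sign, level, n_modules, sizes).

    ``parts`` holds ``(ecosystem, sign, level, partition)`` records, one per
    analyzed network.
    """
    rows = []
    for eco, sign, level, part in parts:
        sizes = part.module_sizes()
        rows.append(
            {
                "ecosystem": eco,
                "sign": sign,
                "level": level,
                "n_modules": part.n_modules,
                "max_module_size": max(sizes) if sizes else 0,
                "module_sizes": ",".join(str(s) for s in sorted(sizes, reverse=True)),
                "modularity": part.modularity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["ecosystem", "sign", "level", "n_modules", "max_module_size",
                 "module_sizes", "modularity"],
    )
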