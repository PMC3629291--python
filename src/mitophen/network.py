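"""Disease similarity network.

Nodes are diseases; an edge exists whenever two diseases share at least one
clinical parameter with positive prevalence in both.  The edge weight is the
prevalence-product overlap kernel used throughout the package:

    w(A, B) = sum over shared parameters of  p_A * p_B / 10000

so each shared parameter contributes a term in [0, 1], maximal when both
diseases show it in 100 % of patients.  In a database where one group shares
a core of high-prevalence parameters this produces the characteristic
picture of a tightly connected hub of that group with the heterogeneous
control diseases loosely attached at the periphery.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .phenodb import PhenotypeMatrix

__all__ = [
    "build_network",
    "filter_network",
    "hub_coefficient",
    "export_graphml",
    "export_edges_tsv",
]


def build_network(matrix: PhenotypeMatrix) -> nx.Graph:
    """Build the disease network from a phenotype matrix.

    Returns a :class:`networkx.Graph`; nodes carry a ``group`` attribute,
    edges carry ``weight`` (the product kernel), ``shared`` (the list of
    shared parameter names) and ``n_shared``.
    """
    n = len(matrix.diseases)
    if n < 2:
        raise ValidationError("network requires at least 2 diseases")
    g = nx.Graph()
    for name, group in zip(matrix.diseases, matrix.groups):
        g.add_node(name, group=group)
    v = matrix.values
    for i in range(n):
        for j in range(i + 1, n):
            both = (v[i] > 0) & (v[j] > 0)
            if not both.any():
                continue
            weight = float((v[i][both] * v[j][both]).sum() / 10000.0)
            shared = [matrix.parameters[k] for k in both.nonzero()[0]]
            g.add_edge(
                matrix.diseases[i],
                matrix.diseases[j],
                weight=weight,
                shared=shared,
                n_shared=len(shared),
            )
    return g


def filter_network(net: nx.Graph, threshold: float) -> nx.Graph:
    """Keep edges with weight >= threshold; every node is retained."""
    out = nx.Graph()
    out.add_nodes_from(net.nodes(data=True))
    out.add_edges_from(
        (a, b, data) for a, b, data in net.edges(data=True) if data["weight"] >= threshold
    )
    return out


def hub_coefficient(net: nx.Graph, group: str) -> float:
    """Ratio of mean within-group edge weight to mean between-group weight.

    Values > 1 indicate the group forms a hub: its members overlap each
    other more strongly than they overlap outside diseases.
    """
    within, between = [], []
    for a, b, data in net.edges(data=True):
        ga = net.nodes[a]["group"] == group
        gb = net.nodes[b]["group"] == group
        if ga and gb:
            within.append(data["weight"])
        elif ga or gb:
            between.append(data["weight"])
    if not between:
        raise ValidationError(f"hub coefficient undefined: no between-group edges for {group!r}")
    if not within:
        return 0.0
    return (sum(within) / len(within)) / (sum(between) / len(between))


def export_graphml(net: nx.Graph, path: str | Path) -> None:
    """Write GraphML; the shared-parameter list is joined with '|'."""
    out = nx.Graph()
    out.add_nodes_from(net.nodes(data=True))
    for a, b, data in net.edges(data=True):
        out.add_edge(
            a,
            b,
            weight=float(data["weight"]),
            shared="|".join(data.get("shared", [])),
            n_shared=int(data.get("n_shared", 0)),
        )
    nx.write_graphml(out, str(path))


def export_edges_tsv(net: nx.Graph, path: str | Path) -> None:
    rows = [
        {"a": a, "b": b, "weight": data["weight"], "n_shared": data.get("n_shared", 0)}
        for a, b, data in net.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["a", "b", "weight", "n_shared"])
    df.to_csv(path, sep="\t", index=False)
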