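"""Cross-MR subnetwork and summary tables.

The subnetwork connects state-significant master regulators whose
regulons share targets; edges are weighted by the Jaccard coefficient of
the two target sets and node degree statistics summarize how intertwined
the regulatory program is.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import SignedRegulon

__all__ = ["jaccard", "MrSubnetwork", "build_mr_subnetwork"]


def jaccard(set_a: set, set_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


@dataclass(frozen=True)
class MrSubnetwork:
    """Weighted MR-MR graph with per-node metadata and degree statistics."""

    nodes: pd.DataFrame  # index tf; columns: size, state, degree
    edges: pd.DataFrame  # columns: tf_a, tf_b, jaccard
    mean_degree: float
    sd_degree: float

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.index)
        for _, row in self.edges.iterrows():
            g.add_edge(row["tf_a"], row["tf_b"], weight=row["jaccard"])
        return g


def build_mr_subnetwork(
    regulons: Mapping[str, SignedRegulon],
    states: Mapping[str, str],
    min_jaccard: float = 0.0,
) -> MrSubnetwork:
    """Build the MR-MR overlap graph (edge iff Jaccard > min_jaccard).

    ``states`` maps each TF to its activation call, carried through as
    node metadata. Degrees are incident-edge counts; the summary reports
    their mean and (population) standard deviation.
    """
    tfs = sorted(regulons)
    if len(tfs) < 2:
        raise ValueError("need at least 2 master regulators")
    rows = []
    for i, a in enumerate(tfs):
        for b in tfs[i + 1:]:
            w = jaccard(regulons[a].targets, regulons[b].targets)
            if w > min_jaccard:
                rows.append((a, b, w))
    edges = pd.DataFrame(rows, columns=["tf_a", "tf_b", "jaccard"])
    degree = pd.Series(0, index=pd.Index(tfs, name="tf"), dtype=int)
    for _, row in edges.iterrows():
        degree[row["tf_a"]] += 1
        degree[row["tf_b"]] += 1
    nodes = pd.DataFrame(
        {
            "size": [regulons[tf].size for tf in tfs],
            "state": [states.get(tf, "ns") for tf in tfs],
            "degree": degree,
        },
        index=pd.Index(tfs, name="tf"),
    )
    return MrSubnetwork(
        nodes=nodes,
        edges=edges,
        mean_degree=float(degree.mean()),
        sd_degree=float(np.std(degree.to_numpy(), ddof=0)),
    )
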