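"""Hierarchical clustering of association matrices and progression-network export.

Percentage matrices are clustered with the Manhattan distance and average
linkage; RR/OR matrices are clustered on log2 values with the Euclidean
distance and average linkage.  Cells that are undefined on the log scale
(zero or undefined ratios) are masked pairwise: distances are computed over
mutually defined coordinates and rescaled by coverage.

Progression networks have one node per primary (size = patient count) and per
secondary site (size = hit count) and one edge per nonzero progression-matrix
cell, carrying the fraction as weight and the RR-screen flag as edge color.
Networks are exported to GraphML with typed attributes plus a JSON sidecar
for plotting tools.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ConsistencyError
from .patterns import AssociationMatrix
from .registry import Cohort

COLOR_ENRICHED = "enriched"
COLOR_DEPLETED = "depleted"
COLOR_NEUTRAL = "neutral"


@dataclass
class ClusterResult:
    """Average-linkage dendrogram of matrix rows (or columns)."""

    labels: tuple[str, ...]        # input order of the clustered items
    leaf_order: tuple[str, ...]    # canonical dendrogram leaf order
    merges: list[tuple[int, int, float, int]]  # scipy linkage rows
    metric: str
    linkage_method: str
    excluded: tuple[str, ...] = ()  # all-undefined items dropped with warning

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "labels": list(self.labels),
                    "leaf_order": list(self.leaf_order),
                    "merges": [list(m) for m in self.merges],
                    "metric": self.metric,
                    "linkage": self.linkage_method,
                    "excluded": list(self.excluded),
                },
                fh,
                indent=1,
            )


def _masked_pdist(values: np.ndarray, metric: str) -> np.ndarray:
    """Condensed pairwise distances with NaN cells masked pairwise.

    Distances use only mutually defined coordinates and are rescaled by
    coverage (m / k for Manhattan, sqrt(m / k) inside the Euclidean root), so
    sparsely observed pairs are not artificially close.
    """
    n, m = values.shape
    defined = np.isfinite(values)
    out = np.zeros(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = defined[i] & defined[j]
            k = int(both.sum())
            if k == 0:
                raise ConsistencyError(
                    "two rows share no defined coordinates; cannot cluster"
                )
            diff = values[i, both] - values[j, both]
            if metric == "cityblock":
                out[idx] = np.abs(diff).sum() * (m / k)
            else:  # euclidean
                out[idx] = np.sqrt((diff**2).sum() * (m / k))
            idx += 1
    return out


def _canonical_leaf_order(Z: np.ndarray, labels: list[str]) -> tuple[str, ...]:
    """Leaf order with the mirror ambiguity resolved: at every merge the
    subtree containing the lexicographically smallest label comes first."""
    n = len(labels)
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    minlab: dict[int, str] = {i: labels[i] for i in range(n)}
    for t, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        first, second = (a, b) if minlab[a] <= minlab[b] else (b, a)
        leaves[n + t] = leaves[first] + leaves[second]
        minlab[n + t] = min(minlab[a], minlab[b])
    root = n + len(Z) - 1 if len(Z) else 0
    return tuple(labels[i] for i in leaves[root])


def cluster_matrix(
    matrix: AssociationMatrix | pd.DataFrame,
    kind: str,
    axis: str = "rows",
) -> ClusterResult:
    """Cluster the rows (or columns) of an association matrix.

    ``kind`` is ``percent`` (Manhattan distance on raw fractions) or ``ratio``
    (Euclidean distance on log2-transformed values, nonpositive cells masked).
    Rows that are entirely undefined are excluded with a warning.
    """
    df = matrix.statistic if isinstance(matrix, AssociationMatrix) else matrix
    if axis == "cols":
        df = df.T
    elif axis != "rows":
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    if kind == "percent":
        values = df.to_numpy(float)
        metric = "cityblock"
    elif kind == "ratio":
        raw = df.to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(raw > 0, np.log2(np.where(raw > 0, raw, 1.0)), np.nan)
        metric = "euclidean"
    else:
        raise ValueError(f"kind must be 'percent' or 'ratio', got {kind!r}")

    labels = [str(x) for x in df.index]
    keep = np.isfinite(values).any(axis=1)
    excluded = tuple(l for l, k in zip(labels, keep) if not k)
    if excluded:
        warnings.warn(f"excluding all-undefined rows from clustering: {excluded}")
    values = values[keep]
    labels = [l for l, k in zip(labels, keep) if k]
    if len(labels) < 2:
        raise ValueError("clustering requires at least 2 defined rows")

    dists = _masked_pdist(values, metric)
    Z = linkage(dists, method="average")
    return ClusterResult(
        labels=tuple(labels),
        leaf_order=_canonical_leaf_order(Z, labels),
        merges=[(int(a), int(b), float(h), int(c)) for a, b, h, c in Z],
        metric=metric,
        linkage_method="average",
        excluded=excluded,
    )


@dataclass
class ProgressionGraph:
    """Directed primary -> secondary progression network."""

    graph: nx.DiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_json(self, path: str) -> None:
        payload = {
            "nodes": [
                {"label": n, **{k: v for k, v in d.items()}}
                for n, d in self.graph.nodes(data=True)
            ],
            "edges": [
                {"source": u, "target": v, **{k: w for k, w in d.items()}}
                for u, v, d in self.graph.edges(data=True)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_graph(
    cohort: Cohort,
    progression: AssociationMatrix,
    rr_screened: AssociationMatrix,
) -> ProgressionGraph:
    """Assemble the progression network from matching matrices of one cohort.

    Node size is the patient count (primaries) or metastasis hit count
    (secondaries); edge width is the progression fraction; edge color encodes
    the RR-screen flag (enriched / depleted / neutral).
    """
    v = cohort.vocab
    if (
        tuple(progression.statistic.index) != tuple(rr_screened.statistic.index)
        or tuple(progression.statistic.columns) != tuple(rr_screened.statistic.columns)
    ):
        raise ConsistencyError("progression and RR matrices have mismatched labels")
    if tuple(progression.statistic.index) != v.primary_sites or tuple(
        progression.statistic.columns
    ) != v.secondary_sites:
        raise ConsistencyError("matrix labels do not match the cohort vocabulary")

    primaries = cohort.primaries()
    hits = cohort.met_matrix().sum(axis=0)
    g = nx.DiGraph()
    for p in v.primary_sites:
        g.add_node(f"primary:{p}", label=p, role="primary",
                   size_count=int(np.sum(primaries == p)))
    for j, s in enumerate(v.secondary_sites):
        g.add_node(f"secondary:{s}", label=s, role="secondary", size_count=int(hits[j]))

    stat = progression.statistic
    for p in v.primary_sites:
        for s in v.secondary_sites:
            w = stat.at[p, s]
            if not np.isfinite(w) or w <= 0:
                continue
            flag = rr_screened.flag.at[p, s] if rr_screened.flag is not None else "null"
            color = {
                "enriched": COLOR_ENRICHED,
                "depleted": COLOR_DEPLETED,
            }.get(flag, COLOR_NEUTRAL)
            g.add_edge(
                f"primary:{p}",
                f"secondary:{s}",
                weight_fraction=float(w),
                rr=float(rr_screened.statistic.at[p, s]),
                q=float(rr_screened.q.at[p, s]) if rr_screened.q is not None else 1.0,
                color=color,
            )
    return ProgressionGraph(graph=g)


def write_graphml(pg: ProgressionGraph, path: str) -> None:
    """Export the network to GraphML with typed node/edge attributes."""
    nx.write_graphml(pg.graph, path)


def read_graphml(path: str) -> ProgressionGraph:
    """Read a network previously written by :func:`write_graphml`."""
    return ProgressionGraph(graph=nx.read_graphml(path))
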