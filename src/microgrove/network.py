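"""Factor-overlap networks.

Nodes are covariates with a significant compositional signal; a pair is
connected when the Jaccard overlap of their significant-taxon sets reaches
the empirical 80th percentile of all pairwise overlaps, so with distinct
values the top 20% of pairs form edges.  Edges are annotated with a
type-appropriate between-factor correlation (Pearson, point-biserial, or
phi) and its significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import UntestableError

__all__ = ["overlap_proportion", "build_network", "factor_correlation",
           "FactorNetwork"]


def overlap_proportion(sig_a: set, sig_b: set) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when the union is empty."""
    a, b = set(sig_a), set(sig_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def factor_correlation(x: pd.Series, y: pd.Series,
                       kinds: tuple[str, str]) -> tuple[float, str, float]:
    """Between-factor correlation dispatched on declared kinds.

    continuous-continuous -> Pearson; continuous-binary -> point-biserial
    (Pearson on the 0/1 coding); binary-binary -> phi with a 1-df chi-square
    p-value.  Requires >= 3 pairwise-complete observations.
    """
    joint = pd.concat([x, y], axis=1, keys=["x", "y"]).dropna()
    if len(joint) < 3:
        raise UntestableError("fewer than 3 pairwise-complete observations")

    def coded(series: pd.Series, kind: str) -> np.ndarray:
        if kind == "continuous":
            return series.astype(float).to_numpy()
        levels = sorted(series.astype(str).unique())
        if len(levels) < 2:
            raise UntestableError("constant factor")
        if len(levels) > 2:
            raise UntestableError("correlation defined for binary/continuous")
        return (series.astype(str) == levels[1]).to_numpy(float)

    kx, ky = kinds
    xv, yv = coded(joint["x"], kx), coded(joint["y"], ky)
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        raise UntestableError("constant factor")
    if kx == "continuous" and ky == "continuous":
        r, p = stats.pearsonr(xv, yv)
        return float(r), "pearson", float(p)
    if kx != "continuous" and ky != "continuous":
        tab = pd.crosstab(xv, yv).to_numpy(float)
        (a, b), (c, d) = tab
        denom = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        phi = (a * d - b * c) / denom if denom else 0.0
        chi2 = len(joint) * phi ** 2
        return float(phi), "phi", float(stats.chi2.sf(chi2, df=1))
    r, p = stats.pearsonr(xv, yv)
    return float(r), "point_biserial", float(p)


@dataclass
class FactorNetwork:
    nodes: list[str]
    overlaps: pd.DataFrame  # symmetric pairwise Jaccard overlaps
    adjacency: pd.DataFrame  # boolean
    edges: pd.DataFrame  # node_a, node_b, overlap, correlation, method, correlation_significant
    threshold: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples():
            g.add_edge(row.node_a, row.node_b, overlap=row.overlap,
                       correlation=row.correlation,
                       significant=bool(row.correlation_significant))
        return g


def build_network(significant_sets: dict[str, set],
                  factor_data: pd.DataFrame | None = None,
                  kinds: dict[str, str] | None = None,
                  percentile: float = 80.0,
                  alpha: float = 0.05) -> FactorNetwork:
    """Build the overlap network over the given factors.

    ``significant_sets`` maps each included factor to its set of
    significantly associated taxa (factors should already be restricted to
    those with a significant single- or multi-factor association).  Edges
    are the pairs whose overlap reaches the rank-based ``percentile`` cut:
    exactly ``ceil((1 - percentile/100) * n_pairs)`` pairs qualify when the
    overlaps are distinct, ties included above the cut.  If ``factor_data``
    and ``kinds`` are given, each edge also carries the between-factor
    correlation.
    """
    nodes = list(significant_sets)
    n = len(nodes)
    overlaps = pd.DataFrame(0.0, index=nodes, columns=nodes)
    if n < 2:
        empty = pd.DataFrame(columns=["node_a", "node_b", "overlap",
                                      "correlation", "method",
                                      "correlation_significant"])
        return FactorNetwork(nodes, overlaps,
                             overlaps.astype(bool), empty, float("nan"))
    pair_vals = {}
    for a, b in combinations(nodes, 2):
        v = overlap_proportion(significant_sets[a], significant_sets[b])
        pair_vals[(a, b)] = v
        overlaps.loc[a, b] = overlaps.loc[b, a] = v
    values = np.array(sorted(pair_vals.values(), reverse=True))
    k = math.ceil((1 - percentile / 100.0) * len(values))
    k = max(k, 1)
    threshold = values[k - 1]
    adjacency = pd.DataFrame(False, index=nodes, columns=nodes)
    rows = []
    for (a, b), v in pair_vals.items():
        if v < threshold:
            continue
        adjacency.loc[a, b] = adjacency.loc[b, a] = True
        corr, method, p = np.nan, "", np.nan
        if factor_data is not None and kinds is not None:
            try:
                corr, method, p = factor_correlation(
                    factor_data[a], factor_data[b], (kinds[a], kinds[b]))
            except UntestableError:
                pass
        rows.append({"node_a": a, "node_b": b, "overlap": v,
                     "correlation": corr, "method": method,
                     "correlation_significant": bool(p < alpha)
                     if np.isfinite(p) else False})
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "overlap",
                                        "correlation", "method",
                                        "correlation_significant"])
    return FactorNetwork(nodes, overlaps, adjacency, edges, float(threshold))
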