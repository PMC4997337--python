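"""UniFrac beta-diversity distances.

Unweighted UniFrac between two communities is the branch length unique to
one presence set divided by the branch length in the union (a branch counts
for a sample when any descendant tip is present).  Weighted UniFrac is the
branch-length-weighted L1 distance between per-branch relative-abundance
totals; the raw (non-normalized) form is the default, with an optional
normalization by the abundance-weighted total branch length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import InvariantError
from .io import OtuTable
from .tree import PhyloTree

__all__ = [
    "DistanceMatrix", "unweighted_unifrac", "weighted_unifrac",
    "unifrac_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric distances with sample ids and a metric tag."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise InvariantError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-10):
            raise InvariantError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise InvariantError("nonzero diagonal")
        if np.any(v < -1e-12):
            raise InvariantError("negative distances")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def select(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)], self.metric)

    def __len__(self) -> int:
        return len(self.sample_ids)


def _branch_profiles(counts: np.ndarray, tree: PhyloTree, taxa) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-branch presence and relative-abundance totals for each sample."""
    counts = np.atleast_2d(np.asarray(counts, float))
    inc = tree.incidence(list(taxa)).astype(float)  # branches x taxa
    lengths = tree.branch_lengths
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise InvariantError("empty sample: UniFrac undefined")
    rel = counts / totals[:, None]
    abund = rel @ inc.T  # samples x branches
    presence = ((counts > 0).astype(float) @ inc.T) > 0
    return lengths, presence, abund


def unweighted_unifrac(sample_a, sample_b, tree: PhyloTree, taxa) -> float:
    lengths, presence, _ = _branch_profiles(np.vstack([sample_a, sample_b]),
                                            tree, taxa)
    pa, pb = presence[0], presence[1]
    union = lengths[pa | pb].sum()
    shared = lengths[pa & pb].sum()
    if union == 0:
        raise InvariantError("no branches observed for either sample")
    return float((union - shared) / union)


def weighted_unifrac(sample_a, sample_b, tree: PhyloTree, taxa,
                     normalized: bool = False) -> float:
    lengths, _, abund = _branch_profiles(np.vstack([sample_a, sample_b]),
                                         tree, taxa)
    raw = float((lengths * np.abs(abund[0] - abund[1])).sum())
    if not normalized:
        return raw
    denom = float((lengths * (abund[0] + abund[1])).sum())
    return raw / denom if denom > 0 else 0.0


def unifrac_matrix(table: OtuTable, tree: PhyloTree, metric: str,
                   normalized: bool = False) -> DistanceMatrix:
    """All-pairs UniFrac distances for a table.

    ``metric`` is ``unweighted_unifrac`` or ``weighted_unifrac``.
    """
    lengths, presence, abund = _branch_profiles(table.counts, tree,
                                                table.taxon_ids)
    if metric == "unweighted_unifrac":
        lw = presence.astype(float) * lengths  # samples x branches
        shared = lw @ presence.astype(float).T
        tot = lw.sum(axis=1)
        union = tot[:, None] + tot[None, :] - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - shared / union
        np.fill_diagonal(d, 0.0)
        d = np.where(union > 0, d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    elif metric == "weighted_unifrac":
        d = squareform(pdist(abund * lengths, metric="cityblock"))
        if normalized:
            denom = (abund * lengths).sum(axis=1)
            d = d / (denom[:, None] + denom[None, :])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(table.sample_ids), d, metric)
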