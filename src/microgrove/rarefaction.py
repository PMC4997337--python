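"""Representative rarefaction.

A single rarefaction draw is a multivariate-hypergeometric subsample
(without replacement) of a sample's reads down to a fixed depth.  Because a
single draw can be unrepresentative when many rare taxa are present, the
representative procedure draws ``n_draws`` vectors per sample and keeps the
one with the minimum average Euclidean distance to the other draws; the
rarefied table is the concatenation of these per-sample central draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvariantError
from .io import OtuTable, stage_rng

logger = logging.getLogger("microgrove")

__all__ = ["rarefy_once", "representative_rarefy", "RarefactionResult",
           "RepresentativeRarefaction"]


def rarefy_once(sample_counts: np.ndarray, depth: int,
                rng: np.random.Generator) -> np.ndarray:
    """One without-replacement subsample of a count vector to ``depth``.

    The marginal expectation of each taxon is ``depth * count / total``.
    """
    counts = np.asarray(sample_counts)
    total = int(counts.sum())
    if total < depth:
        raise InvariantError(f"sample total {total} below depth {depth}")
    if total == depth:
        return counts.astype(np.int64).copy()
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


@dataclass
class RarefactionResult:
    table: OtuTable
    chosen_draw: pd.Series  # 1-based index of the retained draw, per sample
    mean_distance: pd.Series  # mean Euclidean distance of the retained draw
    dropped_samples: list[str]  # totals below depth


def _central_draw(draws: np.ndarray) -> tuple[int, float]:
    """Index (0-based) of the draw minimizing mean distance to the others,
    ties broken by lowest index, plus that mean distance."""
    n = draws.shape[0]
    if n == 1:
        return 0, 0.0
    d = squareform(pdist(draws.astype(float)))
    means = d.sum(axis=1) / (n - 1)
    idx = int(np.argmin(means))  # argmin takes the first minimum: lowest index
    return idx, float(means[idx])


def representative_rarefy(table: OtuTable, depth: int, n_draws: int,
                          seed: int) -> RarefactionResult:
    """Rarefy every sample ``n_draws`` times and keep the central draw.

    Samples whose totals fall below ``depth`` are dropped with a warning.
    """
    if n_draws < 1:
        raise InvariantError("n_draws must be >= 1")
    rng = stage_rng(seed, "rarefaction")
    kept_rows, kept_ids, chosen, mean_d, dropped = [], [], [], [], []
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        total = int(counts.sum())
        if total < depth:
            logger.warning("sample %s total %d < depth %d: dropped", sid, total, depth)
            dropped.append(sid)
            continue
        if total == depth:
            draws = np.tile(counts, (n_draws, 1))
        else:
            colors = counts.astype(np.int64)
            draws = rng.multivariate_hypergeometric(colors, depth, size=n_draws)
        idx, md = _central_draw(draws)
        kept_rows.append(draws[idx])
        kept_ids.append(sid)
        chosen.append(idx + 1)
        mean_d.append(md)
    if not kept_ids:
        raise InvariantError("no sample reaches the rarefaction depth")
    out = OtuTable(kept_ids, list(table.taxon_ids),
                   np.vstack(kept_rows), list(table.lineages))
    return RarefactionResult(
        out,
        pd.Series(chosen, index=kept_ids, name="chosen_draw"),
        pd.Series(mean_d, index=kept_ids, name="mean_distance"),
        dropped,
    )


class RepresentativeRarefaction(BaseEstimator, TransformerMixin):
    """Transformer wrapper: equal-depth subsampling via the central draw.

    Parameters
    ----------
    depth : target reads per sample.
    n_draws : rarefied vectors drawn per sample before picking the most
        central one.
    random_state : master seed.

    After ``transform``, ``chosen_draw_`` and ``mean_distance_`` hold the
    per-sample provenance and ``dropped_samples_`` the samples below depth.
    """

    def __init__(self, depth: int = 202367, n_draws: int = 100,
                 random_state: int = 0):
        self.depth = depth
        self.n_draws = n_draws
        self.random_state = random_state

    def fit(self, X: OtuTable, y=None):
        self.n_features_in_ = len(X.taxon_ids)
        return self

    def transform(self, X: OtuTable) -> OtuTable:
        res = representative_rarefy(X, self.depth, self.n_draws, self.random_state)
        self.chosen_draw_ = res.chosen_draw
        self.mean_distance_ = res.mean_distance
        self.dropped_samples_ = res.dropped_samples
        return res.table
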