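"""Alpha diversity, factor-association tests, and family-level summaries.

Measures: richness (number of taxa present), Pielou's evenness (Shannon
entropy over ln richness, natural logs), and Faith's phylogenetic diversity
(total branch length of the union of root-to-tip paths of observed taxa).

Association tests follow the factor's declared kind: rank-sum for binary,
Kruskal-Wallis for >=3-level categorical, Spearman correlation for
continuous.  Family-level age trends come from log-link count regressions of
within-family richness on age, reported as percent change per month with
Benjamini-Hochberg adjustment across families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvariantError, UntestableError
from .io import FactorTable, OtuTable
from .multitest import bh_adjust
from .tree import PhyloTree

logger = logging.getLogger("microgrove")

__all__ = [
    "richness", "pielou_evenness", "faith_pd", "alpha_diversity_table",
    "alpha_factor_tests", "summarize_family_composition",
    "family_richness_trend", "FamilyTrend",
]


def richness(sample_counts: np.ndarray) -> int:
    """Number of taxa with strictly positive counts."""
    return int(np.count_nonzero(np.asarray(sample_counts) > 0))


def pielou_evenness(sample_counts: np.ndarray) -> float:
    """Shannon entropy (natural log) divided by ln(richness).

    Returns NaN (undefined) for single-taxon communities; raises on all-zero
    input.
    """
    counts = np.asarray(sample_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise UntestableError("evenness undefined for an empty community")
    s = richness(counts)
    if s == 1:
        return float("nan")
    p = counts[counts > 0] / total
    h = -(p * np.log(p)).sum()
    return float(h / np.log(s))


def faith_pd(sample_counts: np.ndarray, tree: PhyloTree,
             taxa: list[str]) -> float:
    """Total branch length spanned by the observed taxa (root-to-tip union)."""
    counts = np.asarray(sample_counts)
    present = counts > 0
    observed = [t for t, keep in zip(taxa, present) if keep]
    inc = tree.incidence(observed)  # raises listing missing taxa
    if not observed:
        return 0.0
    touched = inc.any(axis=1)
    return float(tree.branch_lengths[touched].sum())


def alpha_diversity_table(table: OtuTable, tree: PhyloTree) -> pd.DataFrame:
    """Per-sample richness / evenness / Faith PD."""
    inc = tree.incidence(table.taxon_ids)
    lengths = tree.branch_lengths
    rows = []
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        present = counts > 0
        pd_val = float(lengths[(inc[:, present]).any(axis=1)].sum()) if present.any() else 0.0
        rows.append({
            "sample_id": sid,
            "richness": richness(counts),
            "evenness": pielou_evenness(counts) if counts.sum() > 0 else np.nan,
            "pd": pd_val,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def alpha_factor_tests(alpha_values: pd.Series, factors: FactorTable) -> pd.DataFrame:
    """Test each factor against one alpha-diversity measure.

    Missing values are omitted pairwise; factors constant after omission are
    marked untestable.
    """
    rows = []
    for name in factors.factors():
        kind = factors.kind(name)
        col = factors.data[name]
        joint = pd.concat([alpha_values, col], axis=1, keys=["alpha", "x"]).dropna()
        out = {"factor": name, "kind": kind, "n": len(joint),
               "test": None, "stat": np.nan, "p": np.nan, "note": ""}
        if len(joint) < 2:
            out["note"] = "untestable: fewer than 2 observations"
            rows.append(out)
            continue
        if kind == "continuous":
            x = joint["x"].astype(float)
            if x.nunique() < 2:
                out["note"] = "untestable: constant factor"
            else:
                rho, p = stats.spearmanr(joint["alpha"], x)
                out.update(test="spearman", stat=float(rho), p=float(p))
        else:
            groups = [g["alpha"].to_numpy() for _, g in joint.groupby("x")]
            if len(groups) < 2:
                out["note"] = "untestable: constant factor"
            elif len(groups) == 2:
                u, p = stats.mannwhitneyu(groups[0], groups[1],
                                          alternative="two-sided")
                out.update(test="rank_sum", stat=float(u), p=float(p))
            else:
                h, p = stats.kruskal(*groups)
                out.update(test="kruskal_wallis", stat=float(h), p=float(p))
        rows.append(out)
    return pd.DataFrame(rows).set_index("factor")


def summarize_family_composition(table: OtuTable, top_k: int = 5,
                                 order_by: str = "Bifidobacteriaceae") -> pd.DataFrame:
    """Per-sample relative abundance of the ``top_k`` most abundant families
    (cohort mean), remainder pooled as ``other``; samples ordered by
    descending share of ``order_by`` (falls back to the top family when that
    family is absent)."""
    fams = table.families()
    totals = table.counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    rel = table.counts / totals
    shares = pd.DataFrame(rel, index=table.sample_ids, columns=table.taxon_ids)
    fam_shares = shares.T.groupby(fams).sum().T
    top = fam_shares.mean(axis=0).sort_values(ascending=False).index[:top_k]
    out = fam_shares[list(top)].copy()
    out["other"] = 1.0 - out.sum(axis=1)
    out["other"] = out["other"].clip(lower=0.0)
    key = order_by if order_by in out.columns else out.columns[0]
    return out.sort_values(key, ascending=False, kind="mergesort")


@dataclass
class FamilyTrend:
    family: str
    effect: float  # percent change in family richness per month
    effect_lo: float
    effect_hi: float
    p: float
    q: float
    model: str  # nb | poisson
    converged: bool


def _fit_count_trend(y: np.ndarray, age: np.ndarray):
    """Log-link count regression of richness on age: NB first, Poisson when
    dispersion estimation fails."""
    import warnings
    X = sm.add_constant(age)
    try:
        from statsmodels.discrete.discrete_model import NegativeBinomialP
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = NegativeBinomialP(y, X, p=2).fit(disp=0, maxiter=200)
        beta, se = res.params[1], res.bse[1]
        if res.mle_retvals.get("converged", False) and np.isfinite(se) and se > 0:
            lo, hi = res.conf_int()[1]
            return beta, lo, hi, float(res.pvalues[1]), "nb", True
    except Exception:
        pass
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    lo, hi = res.conf_int()[1]
    return res.params[1], lo, hi, float(res.pvalues[1]), "poisson", True


def family_richness_trend(table: OtuTable, ages: pd.Series) -> pd.DataFrame:
    """Per family: percent change in within-sample family richness per month
    of age, with BH adjustment across families."""
    if len(table.sample_ids) < 10:
        raise InvariantError("family trends need at least 10 samples")
    age = ages.loc[table.sample_ids].to_numpy(float)
    fams = table.families()
    rows = []
    for fam in pd.unique(fams):
        cols = fams == fam
        y = (table.counts[:, cols] > 0).sum(axis=1)
        if y.sum() == 0:
            continue
        try:
            beta, lo, hi, p, model, conv = _fit_count_trend(y, age)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("family %s: trend fit failed (%s)", fam, exc)
            rows.append({"family": fam, "effect": np.nan, "effect_lo": np.nan,
                         "effect_hi": np.nan, "p": np.nan, "q": np.nan,
                         "model": "failed", "converged": False})
            continue
        rows.append({
            "family": fam,
            "effect": 100.0 * (np.exp(beta) - 1.0),
            "effect_lo": 100.0 * (np.exp(lo) - 1.0),
            "effect_hi": 100.0 * (np.exp(hi) - 1.0),
            "p": p, "q": np.nan, "model": model, "converged": conv,
        })
    df = pd.DataFrame(rows).set_index("family")
    ok = df["converged"] & df["p"].notna()
    if ok.any():
        df.loc[ok, "q"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    return df
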