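"""Per-taxon differential abundance.

Each taxon's rarefied counts are modelled with a zero-inflated negative
binomial (intercept-only inflation, the covariate entering the count mean);
when the ZINB optimizer fails the plain negative binomial is fitted instead.
Significance is the two-sided Wald test of the count-component slope, with
BH adjustment across the tested taxa.  Overly sparse taxa (column total
below a threshold) are excluded before testing, and several multi-category
covariates are reduced to the study's fixed binary contrasts first.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import MicrogroveError, UntestableError
from .io import OtuTable
from .multitest import bh_adjust

logger = logging.getLogger("microgrove")

__all__ = [
    "filter_sparse_taxa", "dichotomize_factor", "fit_zinb", "ZinbFit",
    "test_all_taxa", "TaxonTestResult", "top_genera", "bh_adjust",
    "DICHOTOMIZATION_RULES",
]


# ---------------------------------------------------------------------------
# sparsity filter and dichotomization
# ---------------------------------------------------------------------------


def filter_sparse_taxa(table: OtuTable, min_total: int = 5) -> OtuTable:
    """Drop taxa whose total count across samples is below ``min_total``."""
    if min_total < 1:
        raise MicrogroveError("min_total must be >= 1")
    keep = table.counts.sum(axis=0) >= min_total
    removed = int((~keep).sum())
    if removed:
        logger.info("sparsity filter removed %d of %d taxa", removed, keep.size)
    return table.select_taxa(keep)


def _income_ge_80k(level: str) -> int:
    """Bracket qualifies when its lower bound is >= $80,000."""
    s = level.replace("–", "-").replace(",", "").lower()
    nums = [int(x) for x in re.findall(r"\d+", s)]
    nums = [n // 1000 if n >= 1000 else n for n in nums]
    if not nums:
        raise KeyError(level)
    if "<" in s:  # bottom bracket: incomes below its bound
        return 0
    return int(min(nums) >= 80)


def _education_ge_bachelor(level: str) -> int:
    s = level.lower()
    if any(k in s for k in ("bachelor", "master", "graduate", "doctor", "phd")):
        return 1
    if any(k in s for k in ("high school", "some college", "associate",
                            "less than", "ged", "technical")):
        return 0
    raise KeyError(level)


def _married(level: str) -> int:
    s = level.lower()
    if s == "married":
        return 1
    if s in {"not married", "never married", "single", "divorced", "widowed",
             "separated", "living together", "cohabiting"}:
        return 0
    raise KeyError(level)


def _african_american(level: str) -> int:
    s = level.lower()
    if "african american" in s or s == "black":
        return 1
    return 0


def _any_indoor_pets(level: str) -> int:
    s = level.lower()
    if s in {"none", "no", "0"}:
        return 0
    if s in {"yes", "cat", "dog", "cat and dog", "both", "other", "1", "2+"}:
        return 1
    raise KeyError(level)


DICHOTOMIZATION_RULES = {
    "income_ge_80k": _income_ge_80k,
    "education_ge_bachelor": _education_ge_bachelor,
    "married_indicator": _married,
    "african_american_vs_other": _african_american,
    "any_indoor_pets": _any_indoor_pets,
    "identity": lambda level: {"0": 0, "1": 1, "no": 0, "yes": 1}[level.lower()],
}


def dichotomize_factor(factor: pd.Series, rule: str) -> pd.Series:
    """Reduce a multi-category factor to a 0/1 indicator using a fixed rule.

    Missing values stay missing; a level the rule cannot map raises.
    """
    if rule not in DICHOTOMIZATION_RULES:
        raise MicrogroveError(f"unknown dichotomization rule {rule!r}")
    fn = DICHOTOMIZATION_RULES[rule]

    def apply(v):
        if pd.isna(v):
            return np.nan
        try:
            return float(fn(str(v)))
        except KeyError:
            raise MicrogroveError(
                f"rule {rule!r} does not cover level {v!r}") from None

    return factor.map(apply)


# ---------------------------------------------------------------------------
# ZINB fit
# ---------------------------------------------------------------------------


@dataclass
class ZinbFit:
    beta: float  # count-component slope
    se: float
    p: float  # two-sided Wald p on beta
    pi: float  # zero-inflation probability
    dispersion: float  # NB alpha (variance = mu + alpha mu^2)
    loglik: float
    converged: bool
    model_used: str  # "zinb" | "nb"


def _finite(*vals) -> bool:
    return all(np.isfinite(v) for v in vals)


def fit_zinb(counts: np.ndarray, x: np.ndarray) -> ZinbFit:
    """ML fit of the zero-inflated NB with intercept-only inflation.

    Count mean: ``log mu = b0 + b1 x``.  Falls back to the plain NB when the
    ZINB optimizer fails to converge, yields non-finite standard errors, or
    drives the inflation probability onto its boundary.
    """
    from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
    from statsmodels.discrete.discrete_model import NegativeBinomialP

    y = np.asarray(counts)
    x = np.asarray(x, float)
    if np.all(y == 0):
        raise UntestableError("all counts zero")
    if np.unique(x).size < 2:
        raise MicrogroveError("covariate is constant")
    design = np.column_stack([np.ones(y.size), x])

    zinb_ok = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = ZeroInflatedNegativeBinomialP(
                y, design, exog_infl=np.ones((y.size, 1)), p=2)
            res = model.fit(disp=0, maxiter=300, method="bfgs")
            beta = float(res.params[2])
            se = float(res.bse[2])
            pi = float(expit(res.params[0]))
            alpha = float(res.params[-1])
            conv = bool(res.mle_retvals.get("converged", False))
            boundary = pi <= 1e-6 or pi >= 1 - 1e-6
            if conv and _finite(beta, se) and se > 0 and not boundary \
                    and alpha > 0:
                zinb_ok = True
        except Exception:
            pass
    if zinb_ok:
        z = beta / se
        from scipy.stats import norm
        return ZinbFit(beta, se, float(2 * norm.sf(abs(z))), pi, alpha,
                       float(res.llf), True, "zinb")

    logger.debug("ZINB fit failed; falling back to NB")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nb = NegativeBinomialP(y, design, p=2).fit(disp=0, maxiter=300)
    beta = float(nb.params[1])
    se = float(nb.bse[1])
    if not (_finite(beta, se) and se > 0):
        raise UntestableError("NB fallback produced non-finite estimates")
    from scipy.stats import norm
    return ZinbFit(beta, se, float(2 * norm.sf(abs(beta / se))), 0.0,
                   float(max(nb.params[-1], 1e-12)), float(nb.llf),
                   bool(nb.mle_retvals.get("converged", False)), "nb")


def zinb_zero_probability(pi: float, mu: float, theta: float) -> float:
    """Model-implied P(Y=0) = pi + (1-pi) * NB(0 | mu, theta)."""
    nb0 = (theta / (theta + mu)) ** theta
    return pi + (1 - pi) * nb0


# ---------------------------------------------------------------------------
# per-taxon sweep and genus summary
# ---------------------------------------------------------------------------


@dataclass
class TaxonTestResult:
    taxon: str
    genus: str
    direction: int  # sign of the count-component slope
    beta: float
    p: float
    q: float
    model_used: str


def test_all_taxa(table: OtuTable, factor: pd.Series,
                  rule: str | None = None) -> pd.DataFrame:
    """Fit every taxon against one covariate; BH across tested taxa only.

    ``factor`` may be continuous (numeric) or categorical with a
    dichotomization ``rule``.  Samples with a missing covariate are dropped.
    Per-taxon failures are recorded, never abort the sweep.
    """
    x = dichotomize_factor(factor, rule) if rule else factor.astype(float)
    keep = x.notna()
    ids = [s for s in table.sample_ids if keep.get(s, False)]
    sub = table.select_samples(ids)
    xv = x.loc[ids].to_numpy(float)
    genera = sub.genera()
    rows = []
    for j, taxon in enumerate(sub.taxon_ids):
        y = sub.counts[:, j]
        try:
            fit = fit_zinb(y, xv)
        except MicrogroveError as exc:
            logger.debug("taxon %s untestable: %s", taxon, exc)
            rows.append({"taxon": taxon, "genus": genera[j],
                         "direction": 0, "beta": np.nan, "p": np.nan,
                         "q": np.nan, "model_used": "untestable"})
            continue
        rows.append({"taxon": taxon, "genus": genera[j],
                     "direction": int(np.sign(fit.beta)), "beta": fit.beta,
                     "p": fit.p, "q": np.nan, "model_used": fit.model_used})
    df = pd.DataFrame(rows).set_index("taxon")
    tested = df["p"].notna()
    if tested.any():
        df.loc[tested, "q"] = bh_adjust(df.loc[tested, "p"].to_numpy())
    return df


def top_genera(results: pd.DataFrame, min_sig: int = 5, top_k: int = 10,
               alpha: float = 0.05) -> pd.DataFrame:
    """Rank genera by how consistently their significant taxa move.

    Genera with at least ``min_sig`` significant taxa (q < alpha) are scored
    by consistency = max(n_up, n_down)/n_significant, then by the number of
    significant taxa, then name; the ``top_k`` best are returned.
    """
    sig = results[(results["q"] < alpha) & results["q"].notna()]
    rows = []
    for genus, grp in sig.groupby("genus"):
        n = len(grp)
        if n < min_sig:
            continue
        n_pos = int((grp["direction"] > 0).sum())
        n_neg = int((grp["direction"] < 0).sum())
        rows.append({"genus": genus, "n_significant": n, "n_positive": n_pos,
                     "consistency": max(n_pos, n_neg) / n})
    if not rows:
        return pd.DataFrame(columns=["genus", "n_significant", "n_positive",
                                     "consistency", "rank"]).set_index("genus")
    df = pd.DataFrame(rows).sort_values(
        ["consistency", "n_significant", "genus"],
        ascending=[False, False, True]).head(top_k)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.set_index("genus")
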