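"""PERMANOVA on distance matrices, with marginal (type III) tests,
mean/missing-category imputation, VIF-guided redundancy filtering of
repeated measurements, and backward elimination.

The sum-of-squares machinery follows the classical Gower decomposition:
``G = -1/2 J D^2 J`` with ``J`` the centering matrix; the SS explained by a
design ``X`` is ``tr(H G)`` for the hat projection ``H`` of ``X``, and the
pseudo-F compares explained to residual mean squares.  Significance comes
from permuting sample identities (equivalently, simultaneous row/column
shuffles of the distance matrix); marginal SS of a term is the drop in
explained SS when the term leaves the full model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .errors import AliasingError, InvariantError, UntestableError
from .io import FactorInfo, FactorTable, TIMEPOINT_MONTHS, stage_rng

logger = logging.getLogger("microgrove")

__all__ = [
    "PermanovaResult", "SelectionTrace", "permanova_single",
    "permanova_marginal", "impute_factors", "vif_prefilter",
    "backward_eliminate",
]


# ---------------------------------------------------------------------------
# linear-algebra plumbing
# ---------------------------------------------------------------------------


def gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * np.asarray(d, float) ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _hat_and_rank(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x and its rank."""
    q, r, _ = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    q = q[:, :rank]
    return q @ q.T, rank


def _term_columns(values: pd.Series, kind: str) -> np.ndarray:
    """Design columns for one factor: numeric column for continuous,
    drop-first indicators for binary/categorical."""
    if kind == "continuous":
        v = values.astype(float).to_numpy()
        return v[:, None]
    dummies = pd.get_dummies(values.astype(str), drop_first=True, dtype=float)
    return dummies.to_numpy()


def _design(factors: FactorTable, terms: list[str]) -> dict[str, np.ndarray]:
    return {t: _term_columns(factors.data[t], factors.kind(t)) for t in terms}


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Per-term and whole-model PERMANOVA summary."""

    terms: pd.DataFrame  # index term; columns df, ss, F, r2, p
    total_ss: float
    residual_ss: float
    residual_df: int
    model_r2: float
    adj_r2: float
    n: int
    n_perm: int | str
    seed: int
    mode: str  # sequential-equivalent "single" or "marginal"


@dataclass
class SelectionTrace:
    steps: pd.DataFrame  # step, dropped, p_at_drop, ss_at_drop
    retained: list[str]
    final_max_vif: float = float("nan")


# ---------------------------------------------------------------------------
# single-factor test
# ---------------------------------------------------------------------------


def _perm_indices(n: int, n_perm: int, rng: np.random.Generator):
    for _ in range(n_perm):
        yield rng.permutation(n)


def permanova_single(dist, factor: pd.Series, kind: str,
                     n_perm: int | str = 10000, seed: int = 0) -> PermanovaResult:
    """One-factor PERMANOVA; samples with a missing factor value are dropped.

    ``n_perm="all"`` enumerates every distinct relabelling (exact test,
    p = share of enumerated F >= observed, the identity included).
    """
    name = factor.name or "factor"
    keep = factor.notna()
    ids = [s for s, k in zip(dist.sample_ids, keep.loc[dist.sample_ids]) if k]
    if len(ids) < 3:
        raise UntestableError(f"{name}: fewer than 3 usable samples")
    sub = dist.select(ids)
    values = factor.loc[ids]
    if values.nunique() < 2:
        raise UntestableError(f"{name}: constant after missing-value omission")
    x = _term_columns(values, kind)
    n = len(ids)
    g = gower_center(sub.values)
    total_ss = float(np.trace(g))
    design = np.column_stack([np.ones(n), x])
    h, rank = _hat_and_rank(design)
    df_f = rank - 1
    if df_f == 0:
        raise UntestableError(f"{name}: zero model degrees of freedom")
    ss_f = float((h * g).sum())
    df_res = n - rank
    ss_res = total_ss - ss_f
    f_obs = (ss_f / df_f) / (ss_res / df_res)

    if n_perm == "all":
        # enumerate distinct label arrangements
        from sympy.utilities.iterables import multiset_permutations
        labels = list(values.astype(str)) if kind != "continuous" else list(values)
        count = 0
        total = 0
        for perm in multiset_permutations(list(range(n))) if kind == "continuous" \
                else multiset_permutations(labels):
            if kind == "continuous":
                xp = x[list(perm)]
            else:
                xp = _term_columns(pd.Series(perm, index=ids), kind)
            hp, rp = _hat_and_rank(np.column_stack([np.ones(n), xp]))
            ssp = float((hp * g).sum())
            fp = (ssp / df_f) / ((total_ss - ssp) / df_res)
            count += fp >= f_obs - 1e-12
            total += 1
        p = count / total
        n_perm_used: int | str = total
    else:
        rng = stage_rng(seed, f"permanova_single:{name}")
        exceed = 0
        for idx in _perm_indices(n, int(n_perm), rng):
            gp = g[np.ix_(idx, idx)]
            ssp = float((h * gp).sum())
            fp = (ssp / df_f) / ((total_ss - ssp) / df_res)
            exceed += fp >= f_obs
        p = (1 + exceed) / (1 + int(n_perm))
        n_perm_used = int(n_perm)

    r2 = ss_f / total_ss
    adj = 1 - (1 - r2) * (n - 1) / (n - df_f - 1)
    terms = pd.DataFrame(
        {"df": [df_f], "ss": [ss_f], "F": [f_obs], "r2": [r2], "p": [p]},
        index=pd.Index([name], name="term"),
    )
    return PermanovaResult(terms, total_ss, ss_res, df_res, r2, adj,
                           n, n_perm_used, seed, "single")


# ---------------------------------------------------------------------------
# marginal (type III) multi-factor test
# ---------------------------------------------------------------------------


def permanova_marginal(dist, factors: FactorTable, terms: list[str] | None = None,
                       n_perm: int = 1000, seed: int = 0) -> PermanovaResult:
    """Marginal test of each term given all others.

    Requires an imputed factor table (no missing values among the tested
    terms).  Permutations shuffle the distance matrix rows/columns.
    """
    terms = list(terms if terms is not None else factors.factors())
    if not terms:
        raise UntestableError("no terms to test")
    data = factors.data.loc[dist.sample_ids, terms]
    if data.isna().any().any():
        raise InvariantError("marginal tests require imputed factors")
    n = len(dist)
    cols = _design(factors.select_samples(dist.sample_ids), terms)
    g = gower_center(dist.values)
    total_ss = float(np.trace(g))

    ones = np.ones((n, 1))
    x_full = np.column_stack([ones] + [cols[t] for t in terms])
    h_full, rank_full = _hat_and_rank(x_full)
    ss_full = float((h_full * g).sum())
    df_res = n - rank_full
    if df_res <= 0:
        raise UntestableError("saturated model: no residual degrees of freedom")
    ss_res = total_ss - ss_full
    ms_res = ss_res / df_res

    h_red, df_term = {}, {}
    for t in terms:
        others = [u for u in terms if u != t]
        x_red = np.column_stack([ones] + [cols[u] for u in others]) if others else ones
        h_r, rank_r = _hat_and_rank(x_red)
        d = rank_full - rank_r
        if d == 0:
            raise AliasingError(f"term {t!r} aliased with the rest of the model")
        h_red[t], df_term[t] = h_r, d

    ss_term = {t: ss_full - float((h_red[t] * g).sum()) for t in terms}
    f_obs = {t: (ss_term[t] / df_term[t]) / ms_res for t in terms}

    rng = stage_rng(seed, "permanova_marginal:" + ",".join(terms))
    exceed = {t: 0 for t in terms}
    for idx in _perm_indices(n, int(n_perm), rng):
        gp = g[np.ix_(idx, idx)]
        ss_full_p = float((h_full * gp).sum())
        ms_res_p = (total_ss - ss_full_p) / df_res
        for t in terms:
            ss_t = ss_full_p - float((h_red[t] * gp).sum())
            if (ss_t / df_term[t]) / ms_res_p >= f_obs[t]:
                exceed[t] += 1
    p = {t: (1 + exceed[t]) / (1 + int(n_perm)) for t in terms}

    m = rank_full - 1
    r2 = ss_full / total_ss
    adj = 1 - (1 - r2) * (n - 1) / (n - m - 1)
    tdf = pd.DataFrame(
        {
            "df": [df_term[t] for t in terms],
            "ss": [ss_term[t] for t in terms],
            "F": [f_obs[t] for t in terms],
            "r2": [ss_term[t] / total_ss for t in terms],
            "p": [p[t] for t in terms],
        },
        index=pd.Index(terms, name="term"),
    )
    return PermanovaResult(tdf, total_ss, ss_res, df_res, r2, adj,
                           n, int(n_perm), seed, "marginal")


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_factors(factors: FactorTable) -> FactorTable:
    """Mean-impute continuous factors; give categorical/binary factors an
    explicit ``missing`` level.  A binary factor that gains the level
    becomes categorical downstream."""
    data = factors.data.copy()
    info = dict(factors.info)
    for name in factors.factors():
        col = data[name]
        n_miss = int(col.isna().sum())
        if n_miss == len(col):
            raise InvariantError(f"factor {name!r} entirely missing")
        if n_miss == 0:
            continue
        fi = factors.info[name]
        if fi.kind == "continuous":
            data[name] = col.fillna(col.astype(float).mean())
        else:
            data[name] = col.fillna("missing")
            kind = "categorical" if fi.kind == "binary" else fi.kind
            info[name] = FactorInfo(kind, fi.timepoint, fi.measurement_group)
        logger.info("imputed %d missing value(s) in %s", n_miss, name)
    return FactorTable(data, info)


# ---------------------------------------------------------------------------
# VIF pre-filtering of repeated measurements
# ---------------------------------------------------------------------------


def _numeric_codings(values: pd.Series, kind: str) -> np.ndarray:
    """Numeric response representation(s): one column for continuous/binary,
    one indicator column per non-reference level otherwise."""
    if kind == "continuous":
        return values.astype(float).to_numpy()[:, None]
    return _term_columns(values, "categorical")


def pairwise_vif(a: pd.Series, kind_a: str, b: pd.Series, kind_b: str) -> float:
    """1/(1-R^2) of one measurement regressed on the other, complete cases.

    Both directions are computed (indicator contrasts for categorical
    members) and the larger VIF is returned.
    """
    joint = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
    if len(joint) < 3:
        raise UntestableError("fewer than 3 complete pairs for VIF")
    best_r2 = 0.0
    for (resp, rk), (pred, pk) in (
        ((joint["a"], kind_a), (joint["b"], kind_b)),
        ((joint["b"], kind_b), (joint["a"], kind_a)),
    ):
        ys = _numeric_codings(resp, rk)
        x = np.column_stack([np.ones(len(joint)), _numeric_codings(pred, pk)])
        h, _ = _hat_and_rank(x)
        for j in range(ys.shape[1]):
            y = ys[:, j]
            yc = y - y.mean()
            sst = float(yc @ yc)
            if sst == 0:
                continue
            resid = y - h @ y
            r2 = 1 - float(resid @ resid) / sst
            best_r2 = max(best_r2, min(r2, 1.0))
    if best_r2 >= 1.0:
        return float("inf")
    return 1.0 / (1.0 - best_r2)


def _time_of(fi: FactorInfo) -> float:
    return TIMEPOINT_MONTHS[fi.timepoint]


def vif_prefilter(factors: FactorTable, stool_time: float,
                  threshold: float = 2.5) -> tuple[list[str], pd.DataFrame]:
    """Collapse redundant repeated measurements within measurement groups.

    Rules: two measurements with VIF > threshold keep only the one closest
    to stool collection; three measurements with any pairwise VIF > threshold
    keep the two furthest apart, re-check their VIF, and fall back to the
    closest-to-stool single measurement if still above threshold.
    """
    retained: list[str] = []
    log_rows = []
    groups: dict[str, list[str]] = {}
    for name, fi in factors.info.items():
        groups.setdefault(fi.measurement_group, []).append(name)
    for group, members in groups.items():
        if len(members) == 1:
            retained.extend(members)
            continue
        times = {}
        for m in members:
            t = _time_of(factors.info[m])
            if t in times.values():
                raise InvariantError(
                    f"measurement group {group!r}: duplicate timepoints, "
                    "closest-to-stool ordering undefined"
                )
            times[m] = t
        if len(members) == 2:
            m1, m2 = members
            v = pairwise_vif(factors.data[m1], factors.kind(m1),
                             factors.data[m2], factors.kind(m2))
            if v > threshold:
                keep = min(members, key=lambda m: abs(times[m] - stool_time))
                decision = f"VIF {v:.2f} > {threshold}: kept closest to stool"
                kept = [keep]
            else:
                kept = members
                decision = f"VIF {v:.2f} <= {threshold}: kept both"
            retained.extend(kept)
            log_rows.append({"group": group, "members": ",".join(members),
                             "vif": v, "kept": ",".join(kept),
                             "decision": decision})
        elif len(members) == 3:
            vifs = {}
            for m1, m2 in itertools.combinations(members, 2):
                vifs[(m1, m2)] = pairwise_vif(
                    factors.data[m1], factors.kind(m1),
                    factors.data[m2], factors.kind(m2))
            if max(vifs.values()) <= threshold:
                kept = members
                decision = "all pairwise VIF <= threshold: kept all three"
            else:
                far = max(itertools.combinations(members, 2),
                          key=lambda pair: abs(times[pair[0]] - times[pair[1]]))
                v2 = pairwise_vif(factors.data[far[0]], factors.kind(far[0]),
                                  factors.data[far[1]], factors.kind(far[1]))
                if v2 > threshold:
                    keep = min(members, key=lambda m: abs(times[m] - stool_time))
                    kept = [keep]
                    decision = (f"furthest pair VIF {v2:.2f} still > threshold: "
                                "kept closest to stool")
                else:
                    kept = list(far)
                    decision = f"kept furthest-apart pair (VIF {v2:.2f})"
            retained.extend(kept)
            log_rows.append({"group": group, "members": ",".join(members),
                             "vif": max(vifs.values()), "kept": ",".join(kept),
                             "decision": decision})
        else:
            raise InvariantError(
                f"measurement group {group!r} has {len(members)} members; "
                "redundancy rules are defined for up to three"
            )
    order = [f for f in factors.factors() if f in set(retained)]
    return order, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------


def _design_vifs(factors: FactorTable, terms: list[str],
                 sample_ids: list[str]) -> float:
    """Largest column-wise VIF of the final design (each column regressed on
    all others)."""
    sub = factors.select_samples(sample_ids)
    cols = _design(sub, terms)
    blocks = [cols[t] for t in terms if cols[t].size]
    if len(blocks) < 2:
        return float("nan")
    x = np.column_stack(blocks)
    x = x - x.mean(axis=0)
    worst = 1.0
    for j in range(x.shape[1]):
        y = x[:, j]
        sst = float(y @ y)
        if sst == 0:
            continue
        others = np.delete(x, j, axis=1)
        h, _ = _hat_and_rank(np.column_stack([np.ones(len(y)), others]))
        resid = y - h @ y
        r2 = min(1 - float(resid @ resid) / sst, 1.0 - 1e-12)
        worst = max(worst, 1.0 / (1.0 - r2))
    return worst


def backward_eliminate(dist, factors: FactorTable,
                       candidates: list[str] | None = None,
                       alpha: float = 0.05, n_perm: int = 1000,
                       seed: int = 0) -> tuple[PermanovaResult | None, SelectionTrace]:
    """Drop the least-significant marginal term until all p < alpha.

    Ties on p drop the term with the smaller marginal SS.  An empty final
    model is a valid outcome (all candidates eliminated).
    """
    terms = list(candidates if candidates is not None else factors.factors())
    steps = []
    step = 0
    result: PermanovaResult | None = None
    while terms:
        result = permanova_marginal(dist, factors, terms, n_perm=n_perm,
                                    seed=seed + step)
        t = result.terms
        worst_p = t["p"].max()
        if worst_p < alpha:
            break
        at_worst = t[t["p"] == worst_p]
        drop = at_worst.sort_values(["ss"]).index[0]
        steps.append({"step": step + 1, "dropped": drop,
                      "p_at_drop": float(worst_p),
                      "ss_at_drop": float(t.loc[drop, "ss"])})
        terms = [u for u in terms if u != drop]
        step += 1
        result = None
    if result is None and terms:
        result = permanova_marginal(dist, factors, terms, n_perm=n_perm,
                                    seed=seed + step)
    trace = SelectionTrace(
        pd.DataFrame(steps, columns=["step", "dropped", "p_at_drop",
                                     "ss_at_drop"]),
        list(terms),
    )
    if terms:
        trace.final_max_vif = _design_vifs(factors, terms, dist.sample_ids)
        logger.info("final model VIF check: max %.3f", trace.final_max_vif)
    return result, trace
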