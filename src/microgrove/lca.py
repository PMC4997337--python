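"""Latent class analysis of maternal categorical factors.

A K-class finite mixture for J categorical items: class prevalences ``pi``
(a simplex over classes) and item-response probabilities ``rho[j][c, l]``
(per item, per class, a simplex over levels), fitted by EM from multiple
random starts.  Model choice combines the parametric-bootstrap likelihood
ratio test of K vs K+1 with the sample-size-adjusted BIC
(``-2 loglik + n_params * ln((n+2)/24)``).  Subjects are assigned to their
maximum-posterior class; measurement invariance across a binary grouping is
a likelihood-ratio chi-square comparing shared vs group-specific response
probabilities; and the profiles' added explanatory value for community
composition is the marginal PERMANOVA increment of the class term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .errors import InvariantError, MicrogroveError
from .io import FactorInfo, FactorTable, stage_rng
from .permanova import permanova_marginal

logger = logging.getLogger("microgrove")

__all__ = [
    "LcaModel", "fit_lca", "LatentClassAnalysis", "bootstrap_lrt",
    "select_k", "assign_profiles", "measurement_invariance",
    "profile_report", "ProfileReport", "mmp_added_variance",
]

_EPS = 1e-300


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def _encode(items: pd.DataFrame, levels: list[list[str]] | None = None):
    """Complete-case integer coding of categorical items.

    Returns (codes n x J, levels per item, index of retained rows).
    """
    clean = items.dropna()
    dropped = len(items) - len(clean)
    if dropped:
        logger.info("LCA: dropped %d incomplete row(s) of %d", dropped, len(items))
    if levels is None:
        levels = [sorted(clean[c].astype(str).unique()) for c in clean.columns]
    codes = np.empty((len(clean), clean.shape[1]), dtype=np.int64)
    for j, col in enumerate(clean.columns):
        lookup = {lev: i for i, lev in enumerate(levels[j])}
        try:
            codes[:, j] = [lookup[str(v)] for v in clean[col]]
        except KeyError as exc:
            raise MicrogroveError(
                f"item {col!r}: unseen level {exc.args[0]!r}") from None
    return codes, levels, clean.index


def _onehots(codes: np.ndarray, levels) -> list[np.ndarray]:
    return [np.eye(len(levels[j]))[codes[:, j]] for j in range(codes.shape[1])]


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a row-stochastic matrix."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    return np.minimum((u[:, None] > cum).sum(axis=1), probs.shape[1] - 1)


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------


def _loglik_matrix(pi, rho, onehots) -> np.ndarray:
    """log p(x_i, class=c): n x K."""
    lw = np.log(np.clip(pi, _EPS, None))[None, :]
    out = np.tile(lw, (onehots[0].shape[0], 1))
    for j, oh in enumerate(onehots):
        out += oh @ np.log(np.clip(rho[j], _EPS, None)).T
    return out


def _em(codes, levels, K, rng, tol, max_iter):
    n, J = codes.shape
    onehots = _onehots(codes, levels)
    pi = rng.dirichlet(np.ones(K))
    rho = [rng.dirichlet(np.ones(len(levels[j])), size=K) for j in range(J)]
    prev = -np.inf
    trace = []
    for _ in range(max_iter):
        lw = _loglik_matrix(pi, rho, onehots)
        norm = logsumexp(lw, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        if ll < prev - 1e-8:  # EM guarantee; numerically impossible to break
            raise InvariantError("EM log-likelihood decreased")
        resp = np.exp(lw - norm[:, None])
        if abs(ll - prev) < tol:
            break
        prev = ll
        weight = resp.sum(axis=0)
        pi = weight / n
        rho = [(resp.T @ onehots[j]) / weight[:, None] for j in range(J)]
    return pi, rho, trace[-1], resp, trace


@dataclass
class LcaModel:
    K: int
    pi: np.ndarray
    rho: list[np.ndarray]
    loglik: float
    n: int
    item_names: list[str]
    item_levels: list[list[str]]
    posterior: pd.DataFrame  # rows sum to 1
    em_trace: list[float] = field(repr=False, default_factory=list)

    @property
    def n_params(self) -> int:
        return (self.K - 1) + self.K * sum(len(l) - 1 for l in self.item_levels)

    @property
    def bic(self) -> float:
        return -2 * self.loglik + self.n_params * np.log(self.n)

    @property
    def abic(self) -> float:
        return -2 * self.loglik + self.n_params * np.log((self.n + 2) / 24.0)

    def simulate(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        classes = rng.choice(self.K, size=n, p=self.pi)
        data = {}
        for j, name in enumerate(self.item_names):
            levels = np.asarray(self.item_levels[j], object)
            idx = _sample_rows(self.rho[j][classes], rng)
            data[name] = levels[idx]
        return pd.DataFrame(data)


def fit_lca(items: pd.DataFrame, K: int, n_starts: int = 20, seed: int = 0,
            tol: float = 1e-7, max_iter: int = 500,
            levels: list[list[str]] | None = None) -> LcaModel:
    """Best-of-``n_starts`` EM fit; classes ordered by descending prevalence."""
    codes, levels, index = _encode(items, levels)
    n_patterns = len({tuple(r) for r in codes})
    if K > n_patterns:
        raise MicrogroveError(
            f"K={K} exceeds the {n_patterns} distinct response pattern(s)")
    rng = stage_rng(seed, f"lca:K={K}")
    best = None
    for _ in range(max(1, n_starts)):
        pi, rho, ll, resp, trace = _em(codes, levels, K, rng, tol, max_iter)
        if best is None or ll > best[2]:
            best = (pi, rho, ll, resp, trace)
    pi, rho, ll, resp, trace = best
    order = np.argsort(-pi, kind="stable")
    pi = pi[order]
    rho = [r[order] for r in rho]
    resp = resp[:, order]
    posterior = pd.DataFrame(resp, index=index,
                             columns=[f"class_{c + 1}" for c in range(K)])
    return LcaModel(K, pi, rho, ll, codes.shape[0], list(items.columns),
                    levels, posterior, trace)


class LatentClassAnalysis(BaseEstimator):
    """Estimator facade over :func:`fit_lca`.

    Parameters: ``n_classes``, ``n_starts``, ``tol``, ``max_iter``,
    ``random_state``.  After ``fit``: ``weights_`` (prevalences),
    ``response_probs_``, ``loglik_``, ``bic_``, ``abic_``, ``model_``.
    """

    def __init__(self, n_classes: int = 3, n_starts: int = 20,
                 tol: float = 1e-7, max_iter: int = 500, random_state: int = 0):
        self.n_classes = n_classes
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        self.model_ = fit_lca(X, self.n_classes, self.n_starts,
                              self.random_state, self.tol, self.max_iter)
        self.weights_ = self.model_.pi
        self.response_probs_ = self.model_.rho
        self.loglik_ = self.model_.loglik
        self.bic_ = self.model_.bic
        self.abic_ = self.model_.abic
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        m = self.model_
        codes, _, _ = _encode(X, m.item_levels)
        lw = _loglik_matrix(m.pi, m.rho, _onehots(codes, m.item_levels))
        return np.exp(lw - logsumexp(lw, axis=1)[:, None])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def bootstrap_lrt(items: pd.DataFrame, K_small: int, n_starts: int = 4,
                  B: int = 99, seed: int = 0,
                  tol: float = 1e-4) -> tuple[float, float]:
    """Parametric-bootstrap LRT of K_small vs K_small+1 classes.

    Returns ``(p, observed_lrt)`` with ``p = (1 + #{boot >= obs}) / (1 + B)``.
    The observed and bootstrap models are fitted with an identical protocol
    (same number of starts, same tolerance): an asymmetric protocol biases
    the test, since a better-optimized observed LRT looks extreme against
    under-optimized bootstrap replicates.
    """
    if B < 19:
        raise MicrogroveError("B must be >= 19")
    small = fit_lca(items, K_small, n_starts, seed, tol=tol)
    big = fit_lca(items, K_small + 1, n_starts, seed + 1, tol=tol)
    obs = 2 * (big.loglik - small.loglik)
    rng = stage_rng(seed, f"bootstrap_lrt:K={K_small}")
    exceed = 0
    for b in range(B):
        sim = small.simulate(small.n, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        s0 = fit_lca(sim, K_small, n_starts, sub_seed, tol=tol)
        s1 = fit_lca(sim, K_small + 1, n_starts, sub_seed + 1, tol=tol)
        if 2 * (s1.loglik - s0.loglik) >= obs - 1e-9:
            exceed += 1
    return (1 + exceed) / (1 + B), float(obs)


def select_k(items: pd.DataFrame, K_max: int = 5, n_starts: int = 10,
             B: int = 99, alpha: float = 0.05, seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Fit 1..K_max classes; choose the smallest K whose bootstrap LRT vs
    K+1 is non-significant.  The per-K table also reports BIC/aBIC (the
    aBIC minimizer is a second, printed criterion)."""
    rows = []
    chosen = None
    for K in range(1, K_max + 1):
        model = fit_lca(items, K, n_starts, seed + K)
        row = {"K": K, "loglik": model.loglik, "bic": model.bic,
               "abic": model.abic, "boot_p": np.nan}
        if K < K_max and chosen is None:
            p, _ = bootstrap_lrt(items, K, n_starts, B, seed + 100 * K)
            row["boot_p"] = p
            if p > alpha:  # significant means p <= alpha: matters at the
                chosen = K  # resolution floor 1/(B+1)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("K")
    if chosen is None:
        chosen = K_max
    logger.info("selected K=%d (aBIC minimizer K=%d)", chosen,
                int(table["abic"].idxmin()))
    return chosen, table


# ---------------------------------------------------------------------------
# assignment and description
# ---------------------------------------------------------------------------


def assign_profiles(model: LcaModel, items: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Maximum-posterior class per row (ties to the lowest class index) and
    the per-class mean of the maximum posterior."""
    codes, _, index = _encode(items, model.item_levels)
    lw = _loglik_matrix(model.pi, model.rho, _onehots(codes, model.item_levels))
    post = np.exp(lw - logsumexp(lw, axis=1)[:, None])
    hard = np.argmax(post, axis=1)  # argmax returns the first max: lowest index
    maxp = post[np.arange(len(hard)), hard]
    assignments = pd.Series(hard + 1, index=index, name="profile")
    mean_max = pd.Series(
        [float(maxp[hard == c].mean()) if (hard == c).any() else np.nan
         for c in range(model.K)],
        index=[f"class_{c + 1}" for c in range(model.K)],
        name="mean_max_posterior",
    )
    return assignments, mean_max


@dataclass
class ProfileReport:
    class_sizes: pd.Series
    class_shares: pd.Series
    level_tables: dict[str, pd.DataFrame]  # item -> count/% per class x level
    pvalues: pd.DataFrame  # item x (overall + pairwise chi-square p)


def _chi2_p(table: np.ndarray) -> float:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return float("nan")
    return float(stats.chi2_contingency(table, correction=False)[1])


def profile_report(assignments: pd.Series, items: pd.DataFrame) -> ProfileReport:
    """Per-class level counts, column percentages, and overall plus pairwise
    chi-square tests per item (missing rows excluded per item)."""
    assignments = assignments.rename("profile")
    classes = sorted(assignments.unique())
    sizes = assignments.value_counts().reindex(classes).rename("n")
    shares = (sizes / sizes.sum()).rename("share")
    tables = {}
    rows = []
    for item in items.columns:
        joint = pd.concat([assignments, items[item]], axis=1).dropna()
        ct = pd.crosstab(joint[item].astype(str), joint["profile"])
        ct = ct.reindex(columns=classes, fill_value=0)
        pct = 100.0 * ct / ct.sum(axis=0)
        tables[item] = pd.concat({"n": ct, "pct": pct.round(1)}, axis=1)
        row = {"item": item, "overall": _chi2_p(ct.to_numpy().T)}
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                row[f"{a}_vs_{b}"] = _chi2_p(ct[[a, b]].to_numpy().T)
        rows.append(row)
    return ProfileReport(sizes, shares, tables,
                         pd.DataFrame(rows).set_index("item"))


# ---------------------------------------------------------------------------
# measurement invariance
# ---------------------------------------------------------------------------


def _em_grouped(codes, levels, group_ids, K, rng, tol, max_iter):
    """EM with shared response probabilities but group-specific prevalences."""
    n, J = codes.shape
    onehots = _onehots(codes, levels)
    n_groups = group_ids.max() + 1
    pis = rng.dirichlet(np.ones(K), size=n_groups)
    rho = [rng.dirichlet(np.ones(len(levels[j])), size=K) for j in range(J)]
    prev = -np.inf
    for _ in range(max_iter):
        base = np.zeros((n, K))
        for j, oh in enumerate(onehots):
            base += oh @ np.log(np.clip(rho[j], _EPS, None)).T
        lw = base + np.log(np.clip(pis[group_ids], _EPS, None))
        norm = logsumexp(lw, axis=1)
        ll = float(norm.sum())
        resp = np.exp(lw - norm[:, None])
        if abs(ll - prev) < tol:
            break
        prev = ll
        for g in range(n_groups):
            mask = group_ids == g
            pis[g] = resp[mask].sum(axis=0) / mask.sum()
        weight = resp.sum(axis=0)
        rho = [(resp.T @ onehots[j]) / weight[:, None] for j in range(J)]
    return ll


def measurement_invariance(items: pd.DataFrame, grouping: pd.Series, K: int,
                           n_starts: int = 10, seed: int = 0,
                           tol: float = 1e-7, max_iter: int = 500) -> float:
    """LRT p-value for equal item-response probabilities across groups.

    Constrained model: shared rho, group-specific pi.  Free model: separate
    LCA per group.  Chi-square reference with
    df = (G-1) * K * sum_j (L_j - 1).
    """
    joint = pd.concat([items, grouping.rename("__group__")], axis=1).dropna()
    groups = sorted(joint["__group__"].astype(str).unique())
    if len(groups) < 2:
        return 1.0
    codes, levels, _ = _encode(joint[items.columns])
    gid = joint["__group__"].astype(str).map(
        {g: i for i, g in enumerate(groups)}).to_numpy()
    for g in range(len(groups)):
        if (gid == g).sum() < K:
            raise MicrogroveError(f"group {groups[g]!r} too small to fit K={K}")
    rng = stage_rng(seed, "invariance")
    ll_constr = -np.inf
    for _ in range(max(1, n_starts)):
        ll_constr = max(ll_constr,
                        _em_grouped(codes, levels, gid, K, rng, tol, max_iter))
    ll_free = 0.0
    for g in range(len(groups)):
        sub = joint.loc[gid == g, items.columns]
        ll_free += fit_lca(sub, K, n_starts, seed + 7 * (g + 1),
                           tol, max_iter, levels=levels).loglik
    lrt = max(0.0, 2 * (ll_free - ll_constr))
    df = (len(groups) - 1) * K * sum(len(l) - 1 for l in levels)
    return float(stats.chi2.sf(lrt, df))


# ---------------------------------------------------------------------------
# added variance of the profiles in the composition model
# ---------------------------------------------------------------------------


def mmp_added_variance(dist, factors: FactorTable, final_terms: list[str],
                       assignments: pd.Series, n_perm: int = 1000,
                       seed: int = 0) -> tuple[float, float]:
    """PERMANOVA increment of the profile term: ``delta R^2`` of adding the
    class assignment to the final multi-factor model and the marginal
    permutation p of that term."""
    missing = [s for s in dist.sample_ids if s not in assignments.index
               or pd.isna(assignments.get(s))]
    if missing:
        raise InvariantError(f"assignments missing for samples: {missing[:5]}")
    data = factors.data.loc[dist.sample_ids, final_terms].copy()
    data["mmp"] = assignments.loc[dist.sample_ids].astype(str).to_numpy()
    info = {t: factors.info[t] for t in final_terms}
    info["mmp"] = FactorInfo("categorical", "NSV", "mmp")
    augmented = FactorTable(data, info)
    with_mmp = permanova_marginal(dist, augmented, final_terms + ["mmp"],
                                  n_perm=n_perm, seed=seed)
    if final_terms:
        without = permanova_marginal(dist, augmented, final_terms,
                                     n_perm=19, seed=seed)
        base_r2 = without.model_r2
    else:
        base_r2 = 0.0
    delta = with_mmp.model_r2 - base_r2
    return float(delta), float(with_mmp.terms.loc["mmp", "p"])
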