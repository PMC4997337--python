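"""Synthetic birth-cohort generator.

Produces a full analysis-ready dataset — rooted tree, OTU count table with
lineages, covariate table with a factor dictionary, ages, and the latent
truth used by recovery tests — with the statistical structure the pipeline
assumes:

* two age strata (neonates ~1 month, infants ~6 months) with ages drawn
  uniformly within each stratum's observed range;
* K latent maternal classes driving the categorical item frequencies
  (class prevalences and item-response probabilities default to the
  three-profile pattern observed in a large urban birth cohort) and small
  shifts of the continuous factors;
* repeated measurements of single constructs (e.g. BMI at two timepoints,
  tobacco-smoke exposure in pregnancy and at the neonatal visit) with a
  target between-timepoint correlation;
* factor-specific log-fold effects on designated sets of taxa;
* age-dependent expansion/contraction of per-family richness, implemented
  through the structural-zero probability so that expected family richness
  is multiplicative in age;
* zero-inflated negative-binomial counts, optionally resampled to a drawn
  library depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvariantError
from .io import FactorInfo, FactorTable, OtuTable, stage_rng
from .tree import PhyloTree

__all__ = [
    "CohortSpec",
    "FactorEffect",
    "generate_tree",
    "generate_cohort",
    "simulate_zinb_counts",
]

# ---------------------------------------------------------------------------
# taxonomy scaffolding
# ---------------------------------------------------------------------------

_KNOWN_FAMILIES = [
    ("Bifidobacteriaceae", ["Bifidobacterium"]),
    ("Enterobacteriaceae", ["Escherichia", "Klebsiella"]),
    ("Lachnospiraceae", ["Roseburia", "Coprococcus", "Blautia"]),
    ("Staphylococcaceae", ["Staphylococcus"]),
    ("Streptococcaceae", ["Streptococcus", "Lactococcus"]),
    ("Veillonellaceae", ["Veillonella", "Megasphaera"]),
    ("Peptostreptococcaceae", ["Peptostreptococcus"]),
    ("Bacteroidaceae", ["Bacteroides"]),
    ("Lactobacillaceae", ["Lactobacillus"]),
    ("Ruminococcaceae", ["Ruminococcus", "Faecalibacterium"]),
    ("Clostridiaceae", ["Clostridium"]),
    ("Coriobacteriaceae", ["Collinsella"]),
    ("Prevotellaceae", ["Prevotella"]),
    ("Verrucomicrobiaceae", ["Akkermansia"]),
    ("Enterococcaceae", ["Enterococcus"]),
]

# per-month multiplicative richness rates, echoing the strongest observed
# expansions (anaerobic fermenters) and contractions (facultative pioneers)
_DEFAULT_RICHNESS_RATES = {
    "Lachnospiraceae": 1.15,
    "Bifidobacteriaceae": 1.08,
    "Peptostreptococcaceae": 1.10,
    "Veillonellaceae": 1.08,
    "Enterobacteriaceae": 0.90,
    "Staphylococcaceae": 0.85,
    "Streptococcaceae": 0.92,
}

_BASE_LOG_MEAN_BOOST = {
    "Bifidobacteriaceae": 2.5,
    "Enterobacteriaceae": 2.0,
    "Lachnospiraceae": 1.2,
}

# Table-1-style three-class item-response pattern: class 1 all African
# American / low pet-keeping, class 2 mostly married + breastfeeding,
# class 3 smallest, low marriage/breastfeeding, high smoke exposure.
_DEFAULT_ITEMS: dict[str, tuple[tuple[str, ...], tuple[tuple[float, ...], ...]]] = {
    "maternal_race": (
        ("African American", "Caucasian/Other"),
        ((1.00, 0.00), (0.162, 0.838), (0.526, 0.474)),
    ),
    "marital_status": (
        ("married", "not married"),
        ((0.481, 0.519), (0.939, 0.061), (0.20, 0.80)),
    ),
    "mode_of_delivery": (
        ("vaginal", "c-section"),
        ((0.601, 0.399), (0.667, 0.333), (0.61, 0.39)),
    ),
    "breastfeeding_nsv": (
        ("none", "mixed", "exclusive"),
        ((0.590, 0.379, 0.031), (0.215, 0.490, 0.295), (0.967, 0.033, 0.0)),
    ),
    "indoor_pets_nsv": (
        ("yes", "no"),
        ((0.113, 0.887), (0.488, 0.512), (0.44, 0.56)),
    ),
    "ets_nsv": (
        ("yes", "no"),
        ((0.113, 0.887), (0.043, 0.957), (0.867, 0.133)),
    ),
}

_ITEM_KINDS = {
    "maternal_race": "binary",
    "marital_status": "binary",
    "mode_of_delivery": "binary",
    "breastfeeding_nsv": "categorical",
    "indoor_pets_nsv": "binary",
    "ets_nsv": "binary",
}


@dataclass
class FactorEffect:
    """Log-fold effect of one factor on a set of taxa.

    For binary/categorical factors the design value is the indicator of
    membership in ``levels``; for continuous factors it is the standardized
    value and ``levels`` is ignored.
    """

    factor: str
    levels: tuple[str, ...]
    taxa: tuple[int, ...]  # taxon indices
    log_fold: float


def _default_effects(n_taxa: int) -> tuple[FactorEffect, ...]:
    blocks = {
        "breastfeeding_nsv": (("mixed", "exclusive"), range(0, 30), -1.0),
        "mode_of_delivery": (("c-section",), range(30, 50), -1.2),
        "ets_nsv": (("yes",), range(50, 65), 1.0),
        "maternal_race": (("African American",), range(65, 90), 0.8),
    }
    effects = []
    for fac, (levels, taxa, lf) in blocks.items():
        taxa = tuple(t for t in taxa if t < n_taxa)
        if taxa:
            effects.append(FactorEffect(fac, levels, taxa, lf))
    return tuple(effects)


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Desk-scale defaults: 300 samples (150 per age stratum), 400 taxa in 25
    families, 24 covariates, three latent maternal classes.
    """

    n_neonates: int = 150
    n_infants: int = 150
    n_taxa: int = 400
    n_families: int = 25
    class_prevalences: tuple[float, ...] = (0.48, 0.38, 0.14)
    item_levels: dict = field(default_factory=lambda: {
        k: v[0] for k, v in _DEFAULT_ITEMS.items()
    })
    item_response: dict = field(default_factory=lambda: {
        k: np.asarray(v[1], dtype=float) for k, v in _DEFAULT_ITEMS.items()
    })
    factor_effects: tuple[FactorEffect, ...] | None = None  # None -> defaults
    richness_rates: dict = field(
        default_factory=lambda: dict(_DEFAULT_RICHNESS_RATES)
    )
    zero_inflation: float = 0.6  # baseline structural-zero probability
    theta: float = 2.0  # NB dispersion (gamma shape)
    depth_lognormal: tuple[float, float] | None = (np.log(2e4), 0.3)
    repeated_measure_corr: float = 0.7
    continuous_class_shift: float = 1.0  # latent-class shift of maternal age etc.
    age_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (0.5, 4.6), (5.6, 10.6),
    )

    def __post_init__(self):
        prev = np.asarray(self.class_prevalences, float)
        if not np.isclose(prev.sum(), 1.0):
            raise InvariantError("class prevalences must sum to 1")
        if (prev <= 0).any():
            raise InvariantError("class prevalences must be positive")
        for name, probs in self.item_response.items():
            probs = np.asarray(probs, float)
            if probs.shape[0] != len(prev):
                raise InvariantError(f"item {name}: response rows != n classes")
            if probs.shape[1] != len(self.item_levels[name]):
                raise InvariantError(f"item {name}: response cols != n levels")
            if not np.allclose(probs.sum(axis=1), 1.0):
                raise InvariantError(f"item {name}: response rows must sum to 1")
        for fam, rate in self.richness_rates.items():
            if rate <= 0:
                raise InvariantError(f"richness rate for {fam} must be > 0")
        if not -1 <= self.repeated_measure_corr <= 1:
            raise InvariantError("repeated_measure_corr must lie in [-1, 1]")
        if self.factor_effects is None:
            self.factor_effects = _default_effects(self.n_taxa)
        for eff in self.factor_effects:
            if any(t >= self.n_taxa for t in eff.taxa):
                raise InvariantError(f"effect on {eff.factor} references taxa "
                                     f"beyond n_taxa={self.n_taxa}")

    @classmethod
    def null(cls, **kwargs) -> "CohortSpec":
        """Spec with no factor effects, flat richness, no zero inflation."""
        kwargs.setdefault("factor_effects", ())
        kwargs.setdefault("richness_rates", {})
        kwargs.setdefault("zero_inflation", 1e-9)
        return cls(**kwargs)

    @property
    def n_samples(self) -> int:
        return self.n_neonates + self.n_infants

    @property
    def n_classes(self) -> int:
        return len(self.class_prevalences)


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------


def _family_names(n_families: int) -> list[str]:
    names = [f for f, _ in _KNOWN_FAMILIES][:n_families]
    for i in range(len(names), n_families):
        names.append(f"Family{i + 1:02d}")
    return names


def _genus_for(family: str, slot: int) -> str:
    for fam, genera in _KNOWN_FAMILIES:
        if fam == family:
            return genera[slot % len(genera)]
    return f"{family.removesuffix('aceae')}_g{slot % 3 + 1}"


def _random_split_newick(labels: Sequence[str], rng: np.random.Generator,
                         scale: float) -> str:
    """Random bifurcating subtree over ``labels``, preserving label order so
    that contiguous label blocks form (unions of few) clades."""
    if len(labels) == 1:
        return f"{labels[0]}:{rng.exponential(scale):.6f}"
    cut = int(rng.integers(1, len(labels)))
    left = _random_split_newick(labels[:cut], rng, scale)
    right = _random_split_newick(labels[cut:], rng, scale)
    return f"({left},{right}):{rng.exponential(scale):.6f}"


def generate_tree(n_tips: int, seed: int, branch_scale: float = 0.2) -> PhyloTree:
    """Random rooted bifurcating tree with exponential branch lengths."""
    if n_tips < 1:
        raise InvariantError("n_tips must be >= 1")
    rng = stage_rng(seed, "tree")
    labels = [f"OTU_{i + 1:04d}" for i in range(n_tips)]
    if n_tips == 1:
        newick = f"{labels[0]}:{rng.exponential(branch_scale):.6f};"
    else:
        newick = _random_split_newick(labels, rng, branch_scale) + ";"
    return PhyloTree.from_newick(newick)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_correlated_binary(base: np.ndarray, marginal: float, rho: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Second binary measurement: copy of ``base`` w.p. rho, fresh draw
    otherwise — gives correlation ~= rho when marginals match."""
    fresh = rng.random(base.size) < marginal
    keep = rng.random(base.size) < rho
    return np.where(keep, base, fresh)


def _income_levels():
    return ("<$20k", "$20-40k", "$40-80k", "$80-100k", ">$100k")


def _education_levels():
    return ("high school or less", "some college",
            "bachelor's degree", "graduate degree")


def generate_cohort(spec: CohortSpec, seed: int):
    """Generate one synthetic cohort.

    Returns ``(otu_table, factor_table, tree, ages, truth)`` where ``truth``
    records the latent classes, the injected factor effects and the richness
    rates so recovery tests can score the pipeline against the generator.
    """
    n = spec.n_samples
    K = spec.n_classes
    rng = stage_rng(seed, "cohort")
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # ages: uniform within each stratum's range
    (lo_n, hi_n), (lo_i, hi_i) = spec.age_ranges
    ages = np.concatenate([
        rng.uniform(lo_n, hi_n, spec.n_neonates),
        rng.uniform(lo_i, hi_i, spec.n_infants),
    ])
    visit = np.array(["NSV"] * spec.n_neonates + ["ISV"] * spec.n_infants)

    # latent classes and class-driven categorical items
    classes = rng.choice(K, size=n, p=np.asarray(spec.class_prevalences))
    data = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    info: dict[str, FactorInfo] = {}
    for item, levels in spec.item_levels.items():
        probs = np.asarray(spec.item_response[item], float)
        lev_idx = np.array([
            rng.choice(len(levels), p=probs[c]) for c in classes
        ])
        data[item] = np.asarray(levels, object)[lev_idx]
        info[item] = FactorInfo(_ITEM_KINDS.get(item, "categorical"), "NSV", item)

    rho = spec.repeated_measure_corr

    # tobacco smoke in pregnancy: repeated measurement of the NSV item
    if "ets_nsv" in data:
        ets1 = (data["ets_nsv"] == "yes").to_numpy()
        ets_preg = _draw_correlated_binary(ets1, float(ets1.mean() or 0.2), rho, rng)
        data["ets_pregnancy"] = np.where(ets_preg, "yes", "no")
        info["ets_pregnancy"] = FactorInfo("binary", "pregnancy", "ets_nsv")
        info["ets_nsv"] = FactorInfo("binary", "NSV", "ets_nsv")

    shift = spec.continuous_class_shift
    class_shift = (classes - (K - 1) / 2) * shift

    # BMI construct measured twice (repeated-measurement group "bmi")
    bmi1 = rng.normal(27.0 + 0.5 * class_shift, 5.0)
    bmi_delivery = 27.0 + 0.5 * class_shift + rho * (bmi1 - 27.0 - 0.5 * class_shift) \
        + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(0, 5.0, n)
    data["bmi_1st_trimester"] = np.round(bmi1, 1)
    data["bmi_delivery"] = np.round(bmi_delivery, 1)
    info["bmi_1st_trimester"] = FactorInfo("continuous", "pregnancy", "bmi")
    info["bmi_delivery"] = FactorInfo("continuous", "delivery", "bmi")

    simple_cont = {
        "maternal_age": (29.0, 5.0, "pregnancy"),
        "gestational_age": (39.0, 1.5, "delivery"),
        "birth_weight": (3.3, 0.5, "delivery"),
        "endotoxin": (30.0, 10.0, "NSV"),
    }
    for name, (mean, sd, tp) in simple_cont.items():
        data[name] = np.round(rng.normal(mean + 0.3 * class_shift, sd), 2)
        info[name] = FactorInfo("continuous", tp, name)

    data["age_at_stool"] = np.round(ages, 2)
    info["age_at_stool"] = FactorInfo("continuous", "NSV", "age_at_stool")

    simple_bin = {
        "firstborn": (0.4, "delivery"),
        "urban_residence": (0.5, "pregnancy"),
        "air_conditioner": (0.6, "NSV"),
        "air_filter": (0.25, "NSV"),
        "der_f_detected": (0.35, "NSV"),
        "antibiotics_baby": (0.1, "NSV"),
    }
    for name, (p, tp) in simple_bin.items():
        data[name] = np.where(rng.random(n) < p, "yes", "no")
        info[name] = FactorInfo("binary", tp, name)

    inc_levels = _income_levels()
    inc_p = np.array([0.2, 0.25, 0.25, 0.15, 0.15])
    data["income"] = np.asarray(inc_levels, object)[
        rng.choice(len(inc_levels), n, p=inc_p)]
    info["income"] = FactorInfo("categorical", "pregnancy", "income")

    edu_levels = _education_levels()
    edu_p = np.array([0.3, 0.3, 0.25, 0.15])
    data["education"] = np.asarray(edu_levels, object)[
        rng.choice(len(edu_levels), n, p=edu_p)]
    info["education"] = FactorInfo("categorical", "pregnancy", "education")

    seasons = ("winter", "spring", "summer", "fall")
    data["season_of_birth"] = np.asarray(seasons, object)[rng.integers(0, 4, n)]
    info["season_of_birth"] = FactorInfo("categorical", "delivery", "season_of_birth")

    parity_levels = ("0", "1", "2+")
    data["parity"] = np.asarray(parity_levels, object)[
        rng.choice(3, n, p=[0.4, 0.35, 0.25])]
    info["parity"] = FactorInfo("categorical", "pregnancy", "parity")

    factors = FactorTable(data, info)

    # ---- taxa, families, tree -------------------------------------------
    tree = generate_tree(spec.n_taxa, seed)
    taxon_ids = list(tree.tip_labels)
    fam_names = _family_names(spec.n_families)
    fam_blocks = np.array_split(np.arange(spec.n_taxa), spec.n_families)
    family_of = np.empty(spec.n_taxa, dtype=object)
    lineages = [""] * spec.n_taxa
    for f_i, block in enumerate(fam_blocks):
        fam = fam_names[f_i]
        for slot, t in enumerate(block):
            family_of[t] = fam
            genus = _genus_for(fam, slot)
            lineages[t] = (
                f"k__Bacteria;p__P{f_i % 5 + 1};c__C{f_i % 5 + 1};"
                f"o__O{f_i % 5 + 1};f__{fam};g__{genus}"
            )

    # ---- count model ------------------------------------------------------
    base = rng.normal(1.0, 1.0, spec.n_taxa)
    for fam, boost in _BASE_LOG_MEAN_BOOST.items():
        base[family_of == fam] += boost

    # design values for injected effects
    log_mu = np.tile(base, (n, 1))
    effect_x: dict[str, np.ndarray] = {}
    for eff in spec.factor_effects:
        col = data[eff.factor]
        if info[eff.factor].kind == "continuous":
            x = (col.to_numpy(float) - col.mean()) / (col.std() or 1.0)
        else:
            x = col.isin(eff.levels).to_numpy(float)
        effect_x[eff.factor] = x
        log_mu[:, list(eff.taxa)] += eff.log_fold * x[:, None]
    mu = np.exp(log_mu)

    # structural zeros: presence scaled multiplicatively with age per family
    rates = np.array([spec.richness_rates.get(f, 1.0) for f in family_of])
    presence_base = np.clip(1.0 - spec.zero_inflation, 1e-6, 1.0)
    age_centered = ages - ages.mean()
    p_present = np.clip(
        presence_base * rates[None, :] ** age_centered[:, None], 0.002, 0.98
    )

    # ZINB draw: gamma-Poisson mixture gated by presence
    lam = rng.gamma(spec.theta, mu / spec.theta)
    counts = rng.poisson(lam)
    counts[rng.random((n, spec.n_taxa)) >= p_present] = 0

    # library-depth resampling
    if spec.depth_lognormal is not None:
        mlog, sigma = spec.depth_lognormal
        depths = np.maximum(rng.lognormal(mlog, sigma, n), 50).astype(int)
        for i in range(n):
            tot = counts[i].sum()
            if tot == 0:
                counts[i, int(np.argmax(mu[i]))] = 1
                tot = 1
            counts[i] = rng.multinomial(depths[i], counts[i] / tot)

    otu = OtuTable(sample_ids, taxon_ids, counts, lineages)
    ages_s = pd.Series(ages, index=sample_ids, name="age_months")
    truth = {
        "classes": classes,
        "visit": visit,
        "factor_effects": spec.factor_effects,
        "effect_design": effect_x,
        "richness_rates": dict(spec.richness_rates),
        "family_of": family_of,
        "class_prevalences": tuple(spec.class_prevalences),
    }
    return otu, factors, tree, ages_s, truth


# ---------------------------------------------------------------------------
# direct ZINB simulator (for calibration/recovery of the abundance test)
# ---------------------------------------------------------------------------


def simulate_zinb_counts(x: np.ndarray, beta0: float, beta1: float, pi: float,
                         theta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw zero-inflated NB counts with log mean ``beta0 + beta1 * x``."""
    x = np.asarray(x, float)
    mu = np.exp(beta0 + beta1 * x)
    lam = rng.gamma(theta, mu / theta)
    y = rng.poisson(lam)
    y[rng.random(x.size) < pi] = 0
    return y
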