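"""End-to-end orchestration over files.

Each stage reads/writes plain TSV (plus Newick for the tree) inside a
working directory, so the whole analysis is replayable from the shell one
stage at a time or in a single pass.  File names are fixed:

    otu.tsv, tree.nwk, factors.tsv, factor_dictionary.tsv, truth.tsv
    rarefied_otu.tsv, rarefaction_provenance.tsv
    alpha.tsv, alpha_tests_<measure>.tsv, family_composition.tsv,
    family_trends.tsv
    permanova_single.tsv
    multifactor_<metric>.tsv, selection_trace_<metric>.tsv
    difabund_<factor>.tsv, genus_summary_<factor>.tsv
    network_edges.tsv, network_nodes.tsv
    lca_selection.tsv, lca_parameters.tsv, lca_assignments.tsv,
    lca_profile_report.tsv
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import (CohortSpec, RunConfig, alpha_diversity_table,
               alpha_factor_tests, backward_eliminate, build_network,
               family_richness_trend, fit_lca, generate_cohort,
               impute_factors, permanova_single, profile_report,
               read_factor_table, read_otu_table, read_tree,
               representative_rarefy, select_k, assign_profiles,
               summarize_family_composition, test_all_taxa, top_genera,
               unifrac_matrix, vif_prefilter, write_factor_table,
               write_otu_table, write_tree, mmp_added_variance)
from .errors import UntestableError

logger = logging.getLogger("microgrove")

METRICS = ("unweighted_unifrac", "weighted_unifrac")

LCA_ITEMS = ["maternal_race", "marital_status", "mode_of_delivery",
             "breastfeeding_nsv", "indoor_pets_nsv", "ets_nsv"]


def run_simulate(out_dir, seed: int, spec: CohortSpec | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or CohortSpec()
    otu, factors, tree, ages, truth = generate_cohort(spec, seed)
    write_otu_table(otu, out / "otu.tsv")
    write_tree(tree, out / "tree.nwk")
    write_factor_table(factors, out / "factors.tsv", out / "factor_dictionary.tsv")
    truth_df = pd.DataFrame({
        "sample_id": otu.sample_ids,
        "latent_class": truth["classes"] + 1,
        "visit": truth["visit"],
        "age_months": ages.to_numpy(),
    })
    truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    effects = [
        {"factor": e.factor, "levels": "|".join(e.levels),
         "taxa": "|".join(otu.taxon_ids[t] for t in e.taxa),
         "log_fold": e.log_fold}
        for e in truth["factor_effects"]
    ]
    pd.DataFrame(effects).to_csv(out / "true_effects.tsv", sep="\t", index=False)


def run_rarefy(work_dir, cfg: RunConfig, depth: int | str = "min") -> None:
    work = Path(work_dir)
    otu = read_otu_table(work / "otu.tsv")
    if depth == "min":
        depth = int(otu.counts.sum(axis=1).min())
    res = representative_rarefy(otu, int(depth), cfg.draws, cfg.seed)
    write_otu_table(res.table, work / "rarefied_otu.tsv")
    prov = pd.concat([res.chosen_draw, res.mean_distance], axis=1)
    prov.index.name = "sample_id"
    prov.to_csv(work / "rarefaction_provenance.tsv", sep="\t")


def _load_core(work: Path):
    otu = read_otu_table(work / "rarefied_otu.tsv")
    tree = read_tree(work / "tree.nwk")
    factors = read_factor_table(work / "factors.tsv",
                                work / "factor_dictionary.tsv")
    factors = factors.select_samples(otu.sample_ids)
    return otu, tree, factors


def run_diversity(work_dir, cfg: RunConfig) -> None:
    work = Path(work_dir)
    otu, tree, factors = _load_core(work)
    alpha = alpha_diversity_table(otu, tree)
    alpha.to_csv(work / "alpha.tsv", sep="\t")
    for measure in ("richness", "evenness", "pd"):
        tests = alpha_factor_tests(alpha[measure], factors)
        tests.to_csv(work / f"alpha_tests_{measure}.tsv", sep="\t")
    summarize_family_composition(otu).to_csv(
        work / "family_composition.tsv", sep="\t")
    ages = factors.data["age_at_stool"].astype(float)
    family_richness_trend(otu, ages).to_csv(work / "family_trends.tsv", sep="\t")


def run_permanova_single(work_dir, cfg: RunConfig) -> None:
    work = Path(work_dir)
    otu, tree, factors = _load_core(work)
    rows = []
    for metric in METRICS:
        dist = unifrac_matrix(otu, tree, metric)
        for name in factors.factors():
            try:
                res = permanova_single(dist, factors.data[name],
                                       factors.kind(name),
                                       cfg.permutations_single, cfg.seed)
            except UntestableError as exc:
                logger.warning("%s/%s untestable: %s", metric, name, exc)
                continue
            t = res.terms.iloc[0]
            rows.append({"factor": name, "metric": metric, "r2": t["r2"],
                         "F": t["F"], "p": t["p"], "n": res.n})
    pd.DataFrame(rows).to_csv(work / "permanova_single.tsv", sep="\t",
                              index=False)


def run_select(work_dir, cfg: RunConfig, stool_time: float = 1.0) -> None:
    work = Path(work_dir)
    otu, tree, factors = _load_core(work)
    imputed = impute_factors(factors)
    candidates, vif_log = vif_prefilter(imputed, stool_time, cfg.vif_threshold)
    vif_log.to_csv(work / "vif_decisions.tsv", sep="\t", index=False)
    for metric in METRICS:
        dist = unifrac_matrix(otu, tree, metric)
        result, trace = backward_eliminate(dist, imputed, candidates,
                                           cfg.alpha, cfg.permutations_multi,
                                           cfg.seed)
        if result is not None:
            summary = result.terms.copy()
            summary["model_r2"] = result.model_r2
            summary["adj_r2"] = result.adj_r2
            summary.to_csv(work / f"multifactor_{metric}.tsv", sep="\t")
        trace.steps.to_csv(work / f"selection_trace_{metric}.tsv", sep="\t",
                           index=False)


def run_difabund(work_dir, cfg: RunConfig, factor: str,
                 rule: str | None = None) -> pd.DataFrame:
    work = Path(work_dir)
    otu, _, factors = _load_core(work)
    from .diff_abundance import filter_sparse_taxa
    filtered = filter_sparse_taxa(otu, cfg.sparsity_min_total)
    col = factors.data[factor]
    if factors.kind(factor) != "continuous" and rule is None:
        levels = col.dropna().astype(str).unique()
        if len(levels) != 2:
            raise UntestableError(
                f"factor {factor!r} needs a dichotomization rule")
        col = (col.astype(str) == sorted(levels)[1]).astype(float).where(col.notna())
    results = test_all_taxa(filtered, col, rule)
    results.to_csv(work / f"difabund_{factor}.tsv", sep="\t")
    top_genera(results).to_csv(work / f"genus_summary_{factor}.tsv", sep="\t")
    return results


def run_network(work_dir, cfg: RunConfig) -> None:
    """Overlap network over factors significant in the single-factor sweep
    or retained in a multi-factor model."""
    work = Path(work_dir)
    otu, _, factors = _load_core(work)
    single = pd.read_csv(work / "permanova_single.tsv", sep="\t")
    sig = set(single.loc[single["p"] < cfg.alpha, "factor"])
    for metric in METRICS:
        path = work / f"multifactor_{metric}.tsv"
        if path.exists():
            sig |= set(pd.read_csv(path, sep="\t")["term"])
    sig.discard("age_at_stool")
    sets = {}
    kinds = {}
    data = {}
    for name in sorted(sig):
        if name not in factors.factors():
            continue
        try:
            res = run_difabund(work_dir, cfg, name)
        except UntestableError:
            continue
        sets[name] = set(res.index[(res["q"] < cfg.alpha) & res["q"].notna()])
        kinds[name] = factors.kind(name)
        data[name] = factors.data[name]
    net = build_network(sets, pd.DataFrame(data), kinds,
                        cfg.network_percentile, cfg.alpha)
    net.edges.to_csv(work / "network_edges.tsv", sep="\t", index=False)
    pd.DataFrame({"factor": net.nodes}).to_csv(
        work / "network_nodes.tsv", sep="\t", index=False)


def run_lca(work_dir, cfg: RunConfig, items: list[str] | None = None,
            k_max: int = 4, bootstrap_B: int = 19,
            final_terms: list[str] | None = None) -> None:
    work = Path(work_dir)
    otu, tree, factors = _load_core(work)
    items = items or [i for i in LCA_ITEMS if i in factors.factors()]
    item_df = factors.data[items]
    chosen, table = select_k(item_df, K_max=k_max, B=bootstrap_B,
                             seed=cfg.seed)
    table.to_csv(work / "lca_selection.tsv", sep="\t")
    model = fit_lca(item_df, chosen, seed=cfg.seed)
    params = [{"class": c + 1, "prevalence": model.pi[c]} for c in range(model.K)]
    pd.DataFrame(params).to_csv(work / "lca_parameters.tsv", sep="\t",
                                index=False)
    assignments, mean_max = assign_profiles(model, item_df)
    pd.concat([assignments], axis=1).to_csv(work / "lca_assignments.tsv",
                                            sep="\t")
    report = profile_report(assignments, item_df)
    report.pvalues.to_csv(work / "lca_profile_report.tsv", sep="\t")
    if final_terms:
        imputed = impute_factors(factors)
        dist = unifrac_matrix(otu, tree, "unweighted_unifrac")
        dist = dist.select([s for s in dist.sample_ids
                            if s in assignments.index])
        delta, p = mmp_added_variance(dist, imputed, final_terms,
                                      assignments,
                                      cfg.permutations_multi, cfg.seed)
        with open(work / "mmp_added_variance.json", "w") as fh:
            json.dump({"delta_r2": delta, "p": p}, fh)


def run_all(work_dir, cfg: RunConfig, spec: CohortSpec | None = None) -> None:
    run_simulate(work_dir, cfg.seed, spec)
    run_rarefy(work_dir, cfg, depth="min")
    run_diversity(work_dir, cfg)
    run_permanova_single(work_dir, cfg)
    run_select(work_dir, cfg)
    run_network(work_dir, cfg)
    run_lca(work_dir, cfg)
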