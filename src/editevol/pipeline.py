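"""End-to-end orchestration: simulate, discover, quantify, model, report.

Chains the analysis stages over a synthetic dataset and writes every
result table (TSV with the tool version, config hash and seed in a
header comment).  This is the programmatic equivalent of running the
stages one by one, and what the examples build on.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import constraint as _constraint
from . import discovery, evolve, motif, rf, simulate, structure, utr3
from .config import PipelineConfig
from .io import write_result_table
from .simulate import SimConfig, SimTruth

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "site_pair_features"]


def site_pair_features(seqs, truth: SimTruth, other: str,
                       config: PipelineConfig) -> pd.DataFrame:
    """Fold every site in the anchor and one other species and build
    the per-site cross-species feature table consumed by the forests."""
    rows = []
    anchor = truth.anchor
    site_pos = simulate.SITE_OFFSET
    for i, site_id in enumerate(truth.sites["site_id"]):
        rec = {"site_id": site_id,
               "anchor_level": float(truth.levels[anchor].iloc[i]),
               "other_level": float(truth.levels[other].iloc[i])}
        rec["pair_class"] = motif.classify_site_pair(
            [rec["anchor_level"]], [rec["other_level"]],
            config.presence_level, config.absence_level)
        for role, sp in (("anchor", anchor), ("other", other)):
            seq = seqs[sp][site_id]
            trip = seq[site_pos - 1:site_pos + 2]
            rec[f"triplet_{role}"] = trip
            cands = structure.fold_window(seq, site_pos, config.half_window)
            best = structure.find_proximal_ecs(
                cands, site_pos, config.ecs_min_paired, config.ecs_max_bulge)
            rec[f"ecs_pass_{role}"] = best is not None
            candidates = ([best] if best is not None and best.covers(site_pos) else []) \
                + [c for c in cands if c.covers(site_pos)]
            feats = None
            if candidates:
                feats = structure.extract_features(candidates[0], site_pos, seq)
            for name in structure.FEATURE_NAMES:
                rec[f"{name}_{role}"] = getattr(feats, name) if feats else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(sim_config: SimConfig, config: PipelineConfig, outdir,
                 other_species: str | None = None) -> dict:
    """Run every stage on one synthetic dataset; write all output tables.

    Returns a dict of the key in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ---- simulate
    levels, truth = simulate.simulate_levels(sim_config)
    pileup = simulate.simulate_reads(levels, sim_config)
    seqs, site_table = simulate.simulate_sequences(truth, sim_config)
    track = simulate.simulate_conservation(truth, sim_config)
    expression, utrs, mirnas, mirna_expr = simulate.simulate_expression(
        truth, sim_config)
    results["truth"] = truth

    # ---- discovery + quantification
    calls = discovery.call_variants(pileup, config.min_alt_reads)
    lm = discovery.quantify_levels(pileup, config.min_cov_rnaseq)
    results["levels"] = lm
    rep = discovery.representative_level(lm, config.min_cov_rnaseq)
    write_result_table(lm, outdir / "level_matrix.tsv", config)
    write_result_table(rep.reset_index(), outdir / "representative_levels.tsv", config)

    wt_sample = f"{truth.anchor}_male"
    null_sample = f"{truth.anchor}_adar_null"
    wt = pileup[pileup["sample_id"] == wt_sample]
    null = pileup[pileup["sample_id"] == null_sample]
    fdr_table, fdr = discovery.estimate_fdr_with_null(
        wt, null, config.fdr_alpha, config.fdr_min_alt_reads, config.fdr_min_level)
    results["fdr"] = fdr
    write_result_table(fdr_table, outdir / "fdr_report.tsv", config)

    # ---- per-species levels (wide) for evolution analyses
    obs = _observed_species_levels(lm, truth)
    dist = evolve.divergence_matrix(obs)
    results["distance_matrix"] = dist
    write_result_table(dist.reset_index(), outdir / "distance_matrix.tsv", config)
    tree = evolve.build_nj_tree(dist)
    with open(outdir / "nj_tree.nwk", "w") as fh:
        fh.write(str(tree))
    results["nj_tree"] = tree

    times = truth.extras["divergence_times"]
    pairs, ds, ts = [], [], []
    species = list(obs.columns)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            pairs.append((a, b))
            ds.append(dist.loc[a, b])
            ts.append(abs(times[a] - times[b]) if (a == truth.anchor or b == truth.anchor)
                      else np.nan)
    # only anchor pairs have direct divergence times here
    anchor_ok = ~np.isnan(ts)
    if anchor_ok.sum() >= 3:
        slope, intercept, rho = evolve.divergence_time_regression(
            np.array(ds)[anchor_ok], np.array(ts)[anchor_ok])
        results["divergence_time"] = {"slope": slope, "intercept": intercept,
                                      "rho": rho}

    # ---- dating
    ages = _date_sites(obs, truth, config)
    results["ages"] = ages
    write_result_table(ages, outdir / "site_ages.tsv", config)

    # ---- motif
    other = other_species or species[-1]
    pair_table = site_pair_features(seqs, truth, other, config)
    results["pair_table"] = pair_table
    high = truth.levels[truth.anchor] >= config.motif_high_level
    trips = pair_table.loc[high.to_numpy(), "triplet_anchor"]
    mat = motif.build_motif_matrix(list(trips), config.motif_pseudocount)
    scores = motif.score_triplets(mat)
    write_result_table(scores, outdir / "triplet_scores.tsv", config)
    score_of = dict(zip(scores["triplet"], scores["scaled_score"]))
    pa = pair_table[pair_table["pair_class"] == "presence_absence"]
    res = motif.motif_asymmetry_test(
        [score_of.get(t, np.nan) for t in pa["triplet_anchor"]],
        [score_of.get(t, np.nan) for t in pa["triplet_other"]])
    results["motif_asymmetry"] = res
    pair_table = pair_table.assign(
        motif_anchor=[score_of.get(t, np.nan) for t in pair_table["triplet_anchor"]],
        motif_other=[score_of.get(t, np.nan) for t in pair_table["triplet_other"]])
    ecs_cols = (["site_id", "pair_class", "ecs_pass_anchor", "ecs_pass_other"]
                + [f"{n}_anchor" for n in structure.FEATURE_NAMES])
    write_result_table(pair_table[ecs_cols], outdir / "ecs_table.tsv", config)

    # ---- constraint
    site_df = truth.sites.rename(columns={"pos": "pos"})[["site_id", "contig", "pos"]]
    calls_c = _constraint.classify_constraint(
        track, site_df, high_mean=config.high_constraint_mean,
        alpha=config.fdr_alpha, upstream=config.s_region_upstream,
        downstream=config.s_region_downstream, flank_len=config.f_region_len)
    con = pd.DataFrame([(c.site_id, c.constraint_class, c.mean_s, c.mean_f,
                         c.ks_d, c.p_fdr) for c in calls_c],
                       columns=["site_id", "class", "mean_s", "mean_f", "ks_d",
                                "p_fdr"])
    results["constraint"] = con
    write_result_table(con, outdir / "constraint_calls.tsv", config)

    constrained = con["class"].isin(["high", "moderate"])
    rep_levels = rep.reindex(con["site_id"]).to_numpy()
    edited = rep_levels >= config.edited_call_level
    low = rep_levels < config.fdr_min_level
    if edited.sum() and low.sum():
        excess, p = _constraint.functional_fraction(
            int((constrained & edited).sum()), int(edited.sum()),
            int((constrained & low).sum()), int(low.sum()))
        results["functional_fraction"] = {"excess": excess, "p": p}

    # ---- random forests
    try:
        pa_rows = rf.assemble_features(pair_table, "presence_absence")
        report = rf.fit_presence_model(pa_rows, config.rf_ntree, config.rf_mtry,
                                       config.presence_level, config.absence_level,
                                       seed=config.rng_seed)
        results["presence_model"] = report
        imp = pd.DataFrame(sorted(report.importance.items()),
                           columns=["feature", "importance"])
        write_result_table(imp, outdir / "presence_importance.tsv", config)
    except ValueError as exc:
        logger.info("presence model skipped: %s", exc)
    try:
        pp_rows = rf.assemble_features(pair_table, "presence_presence")
        full = rf.fit_level_model(pp_rows, True, config.rf_ntree, config.rf_mtry,
                                  seed=config.rng_seed)
        reduced = rf.fit_level_model(pp_rows, False, config.rf_ntree,
                                     config.rf_mtry, seed=config.rng_seed)
        results["level_models"] = {"full_r2": full.score,
                                   "reduced_r2": reduced.score,
                                   "delta_r2": rf.compare_models(full, reduced)}
        write_result_table(pd.DataFrame([results["level_models"]]),
                           outdir / "model_comparison.tsv", config)
    except ValueError as exc:
        logger.info("level model skipped: %s", exc)

    # ---- 3'UTR
    groups = _gene_groups(expression)
    comp = utr3.group_expression_comparison(groups)
    results["expression_comparison"] = comp
    write_result_table(comp, outdir / "expression_groups.tsv", config)

    mirna_fracs = dict(zip(mirna_expr["mirna_id"], mirna_expr["fraction"]))
    seed_rows = []
    gene_fc = dict(zip(expression["gene"], expression["log2fc"]))
    for gene, utr in utrs.items():
        if abs(gene_fc.get(gene, 0.0)) <= config.gene_min_abs_log2fc:
            continue
        edits = truth.extras["utr_edit_positions"].get(gene, [])
        edits = [p for p in edits if 0 <= p < len(utr) and utr[p] == "A"]
        for m in utr3.scan_mirna_seed_changes(utr, edits, mirnas, mirna_fracs,
                                              config.mirna_min_fraction):
            seed_rows.append((gene, m.mirna_id, m.match_type, m.start, m.end,
                              m.status))
    seed_table = pd.DataFrame(seed_rows, columns=["gene", "mirna_id", "match_type",
                                                  "start", "end", "status"])
    results["seed_changes"] = seed_table
    write_result_table(seed_table, outdir / "mirna_seed_changes.tsv", config)
    return results


def _observed_species_levels(lm: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    """Per-species observed levels (male sample) as a sites x species table."""
    out = {}
    for sp in truth.species:
        sub = lm[lm["sample_id"] == f"{sp}_male"].set_index("site_id")["level"]
        out[sp] = sub.reindex(truth.sites["site_id"])
    return pd.DataFrame(out)


def _date_sites(obs: pd.DataFrame, truth: SimTruth, config: PipelineConfig) -> pd.DataFrame:
    times = truth.extras["divergence_times"]
    order = sorted(truth.species, key=lambda sp: times[sp])
    rows = []
    for site_id, row in obs.iterrows():
        status = {}
        for sp in order:
            lvl = row[sp]
            if np.isnan(lvl):
                status[sp] = "undefined"
            else:
                status[sp] = evolve.call_editing_status(
                    [lvl], [config.min_cov_rnaseq], "A",
                    config.edited_call_level, config.absence_level,
                    config.min_cov_rnaseq)
        if status.get(order[0]) != "edited":
            continue
        age = evolve.assign_age(site_id, status, order, config.min_defined_species)
        rows.append((site_id, age.age_class, age.dated, age.n_defined))
    return pd.DataFrame(rows, columns=["site_id", "age_class", "dated", "n_defined"])


def _gene_groups(expression: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in expression.itertuples(index=False):
        if r.n_utr3_sites == 1:
            grp = "utr3_one_site"
        elif r.n_utr3_sites > 1:
            grp = "utr3_multi_site"
        elif r.other_edited:
            grp = "control"
        else:
            continue
        rows.append((r.gene, grp, r.log2fc))
    return pd.DataFrame(rows, columns=["gene", "group", "log2fc"])
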