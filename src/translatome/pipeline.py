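"""End-to-end composition of the translatome analysis.

``run_pipeline`` ties the stages together: log2 transformation and
quantile normalization, detection calls, translation-state table,
wild-type variance panel and stability classification, the four
prefilter sets, FDR-route and ad hoc DTG calling per mutant with Venn
bookkeeping and a volcano table, fuzzy c-means clustering of the DTG
union with cluster-median heatmap tables, uORF/length feature
association, and hypergeometric category enrichment.  Every output is
a deterministic TSV: rerunning with the same seed yields byte-identical
files.
"""

from __future__ import annotations

import logging
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import core, dtg, enrichment, features, preprocess, stability
from .io import Dataset, PipelineConfig, load_dataset, write_table

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "run_pipeline_on_dataset"]


def _version() -> str:
    try:
        return metadata.version("translatome")
    except metadata.PackageNotFoundError:  # editable/dev tree
        return "unknown"


def run_pipeline(config: PipelineConfig) -> dict:
    """Load the configured dataset and run every stage; see
    :func:`run_pipeline_on_dataset`."""
    return run_pipeline_on_dataset(load_dataset(config), config)


def run_pipeline_on_dataset(data: Dataset, config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        log.info("stage: %s", name)

    # -- normalization -------------------------------------------------
    stage("normalize")
    signals = data.signals
    if not signals.log2:
        signals = signals.log2_transform()
    signals = preprocess.quantile_normalize(signals, na_policy="drop")
    signals.to_tsv(outdir / "normalized_signals.tsv")
    results["normalized"] = signals

    calls = data.calls
    if calls is None:
        calls = preprocess.detection_calls(
            signals, absent_threshold=config.absent_threshold,
            marginal_threshold=config.marginal_threshold)
        calls.to_tsv(outdir / "calls.tsv")
    results["calls"] = calls

    # -- translation states --------------------------------------------
    stage("translation states")
    ts = core.build_translation_state_table(signals,
                                            wild_type=config.wild_type)
    write_table(ts, outdir / "translation_states.tsv")
    results["translation_states"] = ts

    # -- wild-type variance panel --------------------------------------
    stage("stability")
    wt_cols = [c for c in ts.columns
               if c.startswith(f"tl.{config.wild_type}.")]
    panel = ts[wt_cols]
    vp = stability.classify_stability(panel,
                                      top_fraction=config.top_fraction)
    vp.attrs["panel"] = "TL"
    write_table(vp, outdir / "stability_panel.tsv")
    write_table(stability.sd_histogram(vp["sd"]),
                outdir / "sd_histogram_tl.tsv", index=False)
    results["stability"] = vp

    tc = signals.select(genotype=config.wild_type, fraction="TC")
    if tc.shape[1] >= 3:
        vp_tc = stability.classify_stability(
            tc, top_fraction=config.top_fraction)
        write_table(vp_tc, outdir / "stability_panel_tc.tsv")
        write_table(stability.sd_histogram(vp_tc["sd"]),
                    outdir / "sd_histogram_tc.tsv", index=False)
        results["stability_tc"] = vp_tc

    # -- prefilter sets ------------------------------------------------
    stage("prefilter sets")
    sets = dtg.build_prefilter_sets(calls.calls, vp["sd"],
                                    sd_quantile=config.sd_quantile)
    write_table(sets.membership_frame(), outdir / "prefilter_sets.tsv")
    results["prefilter_sets"] = sets

    # -- DTG calling per mutant ----------------------------------------
    mutants = list(config.mutants) if config.mutants else data.mutants
    dtg_tables = {}
    for mut in mutants:
        stage(f"DTG: {mut}")
        table = dtg.identify_dtg(
            ts, sets, mutant=mut, wild_type=config.wild_type,
            fold_cutoff=config.fold_cutoff, alpha=config.alpha,
            adhoc_kwargs={"min_abs_mean": config.adhoc_min_abs_mean})
        dtg_tables[mut] = table
        write_table(table, outdir / f"dtg_{mut}.tsv")
        write_table(dtg.venn_counts(table),
                    outdir / f"venn_counts_{mut}.tsv", index=False)
        volcano = pd.DataFrame(
            {"delta_log2_tl": table["delta_log2_tl"],
             "neg_log10_fdr": -np.log10(table["fdr"])})
        volcano.attrs["fdr_line"] = -np.log10(config.alpha)
        vtab = volcano.copy()
        vtab["fdr_line"] = -np.log10(config.alpha)
        write_table(vtab, outdir / f"volcano_{mut}.tsv")
        results[f"volcano_{mut}"] = volcano
    results["dtg"] = dtg_tables

    # -- clustering of the DTG union -----------------------------------
    union = pd.Index(sorted(set().union(
        *[t.index[t["dtg_union"]] for t in dtg_tables.values()])))
    results["dtg_union_genes"] = union
    profile_cols = [c for c in ts.columns if c.startswith("tl.")
                    and not c.startswith(f"tl.{config.wild_type}.")]
    if len(union) >= max(config.n_clusters, 2) and profile_cols:
        stage("clustering")
        wt_mean = ts[f"mean_tl.{config.wild_type}"]
        profiles = ts.loc[union, profile_cols].sub(wt_mean.loc[union],
                                                  axis=0)
        profiles.columns = [f"delta_{c[3:]}" for c in profile_cols]
        profiles = profiles.dropna()
        k = min(config.n_clusters, len(profiles))
        membership, est = _cluster.fuzzy_kmeans(
            profiles, k=k, m=config.fuzzifier,
            max_iter=config.cluster_max_iter, seed=config.seed)
        write_table(membership, outdir / "cluster_membership.tsv")
        medians = _cluster.cluster_medians(membership["cluster"],
                                           profiles, n_clusters=k)
        write_table(medians, outdir / "cluster_medians.tsv")
        results["clusters"] = membership
        results["cluster_medians"] = medians
    else:
        log.warning("too few DTGs (%d) to cluster; skipping", len(union))

    # -- feature association -------------------------------------------
    ann = data.annotation
    if ann is not None:
        stage("features")
        if data.sequences is not None:
            n_uorfs = pd.Series(
                {g: len(features.scan_uorfs(
                    seq, int(ann.loc[g, "utr5_length"])))
                 for g, seq in data.sequences.items()
                 if g in ann.index}, name="n_uorfs")
            ann = ann.copy()
            ann.loc[n_uorfs.index, "n_uorfs"] = n_uorfs
            ann["has_uorf"] = ann["n_uorfs"] > 0
        for mut in mutants:
            delta = ts[f"delta_tl.{mut}"]
            bins = features.bin_association_analysis(
                delta, ann, long_orf_nt=config.long_orf_nt)
            write_table(bins, outdir / f"bin_association_{mut}.tsv",
                        index=False)
            results[f"bin_association_{mut}"] = bins
            for field_name in ("cds_length", "utr5_length", "utr3_length"):
                if field_name in ann.columns:
                    tab = features.length_bin_analysis(
                        delta, ann[field_name].astype(float))
                    write_table(
                        tab, outdir / f"length_bins_{field_name}_{mut}.tsv",
                        index=False)
        if len(mutants) >= 2:
            a, b = mutants[0], mutants[1]
            da, db = ts[f"delta_tl.{a}"], ts[f"delta_tl.{b}"]
            both = da.dropna().index.intersection(db.dropna().index)
            r2 = features.pearson_r2(da.loc[both], db.loc[both])
            sel = dtg_tables[a].index[
                dtg_tables[a]["dtg_union"]
                & (dtg_tables[a]["delta_log2_tl"] > 0)]
            conc = (features.sign_concordance_test(
                db.loc[sel.intersection(both)], alternative="greater")
                if len(sel.intersection(both)) else
                {"n": 0, "wilcoxon_p": np.nan, "sign_p": np.nan})
            cross = pd.DataFrame([{
                "mutant_a": a, "mutant_b": b, "r2": r2["r2"],
                "r2_n": r2["n"], "concordance_n": conc["n"],
                "wilcoxon_p": conc["wilcoxon_p"],
                "sign_p": conc["sign_p"]}])
            write_table(cross, outdir / "cross_mutant_concordance.tsv",
                        index=False)
            results["cross_mutant"] = cross

    # -- enrichment -----------------------------------------------------
    if ann is not None and "category" in ann.columns:
        stage("enrichment")
        if config.categories is not None:
            cat_map = enrichment.read_category_map(config.categories)
        else:
            cat_map = enrichment.category_map_from_annotation(ann)
        universe = ann.index.intersection(ts.index)
        for mut in mutants:
            genes = dtg_tables[mut].index[dtg_tables[mut]["dtg_union"]]
            genes = genes.intersection(universe)
            if len(genes):
                enr = enrichment.hypergeom_enrichment(genes, cat_map,
                                                      universe)
                write_table(enr, outdir / f"enrichment_dtg_{mut}.tsv",
                            index=False)
                results[f"enrichment_{mut}"] = enr
        if "clusters" in results:
            memb = results["clusters"]
            rows = []
            for v, sub in memb.groupby("cluster"):
                genes = sub.index.intersection(universe)
                if not len(genes):
                    continue
                enr = enrichment.hypergeom_enrichment(genes, cat_map,
                                                      universe)
                enr.insert(0, "cluster", v)
                rows.append(enr.head(5))
            if rows:
                write_table(pd.concat(rows, ignore_index=True),
                            outdir / "enrichment_clusters.tsv",
                            index=False)

    # -- run log ---------------------------------------------------------
    lines = [f"translatome version: {_version()}", "parameters:"]
    for k, v in sorted(config.to_dict().items()):
        lines.append(f"  {k}: {v}")
    lines.append(f"genotypes: {data.signals.genotypes}")
    lines.append(f"n_genes: {data.signals.values.shape[0]}")
    lines.append(f"n_arrays: {data.signals.values.shape[1]}")
    union_counts = {m: int(t["dtg_union"].sum())
                    for m, t in dtg_tables.items()}
    lines.append(f"dtg_union: {union_counts}")
    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
    results["outdir"] = outdir
    return results
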