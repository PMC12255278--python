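"""End-to-end pipeline runner: simulate -> chemotype -> network -> census ->
diversity -> variation partitioning -> qPCR expression -> ordination.

Each stage writes its artifact under the output directory; a manifest records
the configuration hash, seed and stage outputs so a rerun with the same
config reproduces the run byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .asca import AscaModel, pseudo_r2_screen
from .census import census_spectra
from .chemotyping import chemotype_samples
from .config import PipelineConfig
from .core import QPCRDataset
from .diversity import correlate, diversity_table, group_summaries, tic_sg
from .io import (read_feature_table, read_qpcr_dataset, read_spectra,
                 spectra_by_sample, write_feature_table, write_qpcr_dataset,
                 write_spectra)
from .masschem import default_residue_table
from .mdn import annotate_associations, build_mdn, export_graphml, prune_singletons
from .ordination import manhattan_distances, pca, pcoa, permanova, preprocess_features
from .qpcr import QPCRModel
from .simulate import SimulationDesign, simulate_study

ALL_STAGES = ("simulate", "chemotype", "mdn", "census", "diversity", "asca",
              "qpcr", "ordinate")


def design_from_config(cfg: PipelineConfig) -> SimulationDesign:
    return SimulationDesign(
        n_genotypes_s=cfg.n_genotypes_s, n_genotypes_u=cfg.n_genotypes_u,
        replicates=cfg.replicates, intensity_sigma=cfg.intensity_sigma,
        decoy_peaks=cfg.decoy_peaks, n_noise_features=cfg.n_noise_features,
        seed=cfg.seed)


def load_inputs(outdir: Path):
    """Typed objects from a previously written artifact directory."""
    outdir = Path(outdir)
    ft = read_feature_table(outdir / "features.tsv", outdir / "metadata.tsv")
    spectra = read_spectra(outdir / "spectra.mgf")
    qpcr = read_qpcr_dataset(outdir / "qpcr_wells.tsv", outdir / "metadata.tsv",
                             outdir / "qpcr_dilutions.tsv")
    return ft, spectra, ft.metadata, qpcr


def run_pipeline(cfg: PipelineConfig, outdir, stages=None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = {"sgchem_version": __version__, "config": cfg.to_dict(),
                "config_hash": cfg.hash, "stages": {}}
    design = design_from_config(cfg)
    ctx: dict = {}

    def artifact(name):
        return outdir / name

    for stage in ALL_STAGES:
        if stage not in stages and stage != "simulate":
            continue
        try:
            if stage == "simulate":
                lib, spectra, ft, qpcr, truth = simulate_study(design)
                ctx.update(lib=lib, spectra=spectra, ft=ft, qpcr=qpcr,
                           truth=truth)
                if "simulate" in stages:
                    write_feature_table(ft, artifact("features.tsv"),
                                        artifact("metadata.tsv"))
                    write_spectra(spectra, artifact("spectra.mgf"))
                    write_qpcr_dataset(qpcr, artifact("qpcr_wells.tsv"),
                                       artifact("metadata.tsv"),
                                       artifact("qpcr_dilutions.tsv"))
                    truth.sg_counts.to_csv(artifact("truth_sg_counts.tsv"),
                                           sep="\t")
                    manifest["stages"]["simulate"] = {
                        "samples": len(ft.samples),
                        "features": ft.n_features,
                        "scans": len(spectra)}
            elif stage == "chemotype":
                calls = chemotype_samples(spectra_by_sample(ctx["spectra"]),
                                          tol=cfg.chemotype_mz_tol,
                                          presence_threshold=cfg.presence_threshold)
                calls.to_csv(artifact("chemotypes.tsv"), sep="\t")
                leaf = ctx["ft"].metadata.query("organ == 'leaf'")
                agree = (calls.loc[leaf.index, "label"]
                         == leaf["chemotype"]).mean()
                manifest["stages"]["chemotype"] = {
                    "n": len(calls), "leaf_agreement": float(agree)}
            elif stage == "mdn":
                table = default_residue_table().subset(cfg.losses)
                g = build_mdn(ctx["ft"], table, cfg.mdn_mz_tol, cfg.rt_window)
                g = prune_singletons(g)
                for grouping in ("chemotype", "organ", "ontogeny"):
                    g = annotate_associations(g, ctx["ft"], grouping,
                                              cfg.association_threshold)
                export_graphml(g, artifact("mdn.graphml"))
                ctx["graph"] = g
                import networkx as nx
                manifest["stages"]["mdn"] = {
                    "nodes": g.number_of_nodes(),
                    "edges": g.number_of_edges(),
                    "components": nx.number_connected_components(g)}
            elif stage == "census":
                counts = census_spectra(spectra_by_sample(ctx["spectra"]),
                                        tol=cfg.census_mz_tol)
                counts.to_csv(artifact("sg_counts.tsv"), sep="\t")
                ctx["counts"] = counts
                manifest["stages"]["census"] = {
                    "total_sg_count": int(counts.to_numpy().sum())}
            elif stage == "diversity":
                div = diversity_table(ctx["counts"])
                meta = ctx["ft"].metadata
                tic = tic_sg(ctx["ft"], ctx["graph"],
                             exclude_mz=cfg.tic_exclude_mz,
                             tol=cfg.mdn_mz_tol)
                div["TIC_SG"] = tic.reindex(div.index)
                div.to_csv(artifact("diversity.tsv"), sep="\t")
                group_summaries(div, meta).to_csv(
                    artifact("diversity_groups.tsv"), sep="\t", index=False)
                corr = correlate(div["TIC_SG"], div["Dmg"],
                                 meta["organ"].reindex(div.index))
                corr.to_csv(artifact("tic_dmg_correlation.tsv"), sep="\t")
                ctx["diversity"] = div
                manifest["stages"]["diversity"] = {
                    "mean_Dmg": float(div["Dmg"].mean()),
                    "mean_J": float(div["J"].mean())}
            elif stage == "asca":
                meta = ctx["ft"].metadata.loc[ctx["counts"].index].copy()
                meta["sample_type"] = meta["organ"] + "-" + meta["chemotype"]
                # stems exist only in flowering plants, so the sample-type x
                # ontogeny interaction is estimable only for root/leaf samples
                both = meta["organ"].isin(["root", "leaf"])
                specs = {
                    "organ_chemotype": (
                        ["organ", "chemotype", "organ:chemotype"],
                        meta.index),
                    "sampletype_ontogeny": (
                        ["sample_type", "ontogeny", "sample_type:ontogeny"],
                        meta.index[both]),
                }
                summary = {}
                for name, (terms, idx) in specs.items():
                    counts_m = ctx["counts"].loc[idx]
                    meta_m = meta.loc[idx]
                    screen = pseudo_r2_screen(counts_m, meta_m, terms,
                                              n_perm=cfg.n_perm_screen,
                                              seed=cfg.seed)
                    retained = list(screen.index[screen["retained"]])
                    model = AscaModel(counts_m, meta_m, terms)
                    res = model.fit(variables=retained or None)
                    p = model.permutation_validation(cfg.n_perm_asca,
                                                     seed=cfg.seed,
                                                     results=res)
                    for term, dec in res.effects.items():
                        tag = f"{name}.{term}".replace(":", "x")
                        dec.scores.to_csv(
                            artifact(f"asca_scores_{tag}.tsv"), sep="\t")
                        dec.loadings.to_csv(
                            artifact(f"asca_loadings_{tag}.tsv"), sep="\t")
                    screen.to_csv(artifact(f"asca_screen_{name}.tsv"),
                                  sep="\t")
                    summary[name] = {"retained": retained,
                                     "p_values": p.to_dict()}
                manifest["stages"]["asca"] = summary
            elif stage == "qpcr":
                results = {}
                for ontogeny, meta_sub in ctx["qpcr"].metadata.groupby("ontogeny"):
                    wells = ctx["qpcr"].wells
                    sub = QPCRDataset(
                        wells[wells["sample"].isin(meta_sub.index)].copy(),
                        meta_sub, ctx["qpcr"].efficiencies,
                        ctx["qpcr"].reference_genes,
                        ctx["qpcr"].dilution_series)
                    model = QPCRModel.from_dataset(
                        sub, cq1=cfg.cq1, mode=cfg.qpcr_mode,
                        reference_genes=cfg.reference_genes)
                    res = model.fit()
                    res.group_effects.to_csv(
                        artifact(f"qpcr_effects_{ontogeny}.tsv"),
                        sep="\t", index=False)
                    contrasts = res.contrasts()
                    contrasts.to_csv(
                        artifact(f"qpcr_contrasts_{ontogeny}.tsv"),
                        sep="\t", index=False)
                    results[ontogeny] = {
                        "n_significant": int((contrasts["p_adj"] < 0.05).sum())}
                    ctx[f"qpcr_res_{ontogeny}"] = res
                manifest["stages"]["qpcr"] = results
            elif stage == "ordinate":
                pre = preprocess_features(ctx["ft"])
                p1 = pca(pre)
                p1.scores.to_csv(artifact("pca_scores.tsv"), sep="\t")
                # qPCR log2 abundances -> Manhattan PCoA + PERMANOVA
                model = QPCRModel.from_dataset(ctx["qpcr"], cq1=cfg.cq1,
                                               mode="naive")
                counts = model._wells.pivot_table(index="sample",
                                                  columns="gene",
                                                  values="count",
                                                  aggfunc="mean")
                import numpy as np
                log2c = np.log2(counts + 1.0)
                D = manhattan_distances(log2c)
                pc = pcoa(D)
                pc.scores.to_csv(artifact("pcoa_scores.tsv"), sep="\t")
                grouping = ctx["qpcr"].metadata["organ"].reindex(D.index)
                F, pval = permanova(D, grouping, cfg.n_perm_permanova,
                                    seed=cfg.seed)
                manifest["stages"]["ordinate"] = {
                    "pca_pc1_pct": float(p1.explained[0]),
                    "pcoa_pco1_pct": float(pc.explained[0]) if len(pc.explained) else 0.0,
                    "permanova_F": F, "permanova_p": pval}
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc)}
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True, default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
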