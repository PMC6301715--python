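"""End-to-end pipeline: simulate -> feeding -> enhancers -> motifs ->
occupancy -> hormone, with a machine-readable run report.

Every stage writes plain TSV tables under the configured output directory;
reruns with the same config and seed are byte-identical. The report lists
per-stage feature counts, output paths, and sha256 hashes of the simulated
input files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import enhancers as enh
from . import feeding as feed
from . import hormones as horm
from . import motifs as mot
from . import occupancy as occ
from .config import RunConfig
from .countstats import nb_wald_test, write_differential, zscore_rows
from .intervals import PeakSet
from .simulate import simulate_all, tss_table, write_outputs

log = logging.getLogger("prandialreg")
FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path, index_name: str | None = None) -> str:
    if index_name is not None:
        df = df.copy()
        df.index.name = index_name
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    return str(path)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _condition_means(cm, conditions) -> pd.DataFrame:
    from .countstats import size_factors

    sf = size_factors(cm.counts)
    norm = cm.counts / sf
    return pd.DataFrame({
        c: norm[cm.samples_for(c)].mean(axis=1) for c in conditions
    })


def run_pipeline(rc: RunConfig) -> dict:
    """Run all enabled stages in dependency order; return the run report."""
    t0 = time.time()
    outdir = Path(rc.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": rc.seed, "stages": {}, "outputs": {}}

    log.info("stage=simulate start")
    sim = simulate_all(rc.simulation, include_hormone_arms=True, include_obese=True)
    input_paths = write_outputs(sim, outdir / "inputs")
    # report paths relative to outdir so identical runs give identical reports
    report["inputs"] = {
        k: {"path": str(Path(v).relative_to(outdir)), "sha256": _sha256(v)}
        for k, v in sorted(input_paths.items())
    }
    report["stages"]["simulate"] = {
        "n_genes": len(sim.truth.genes),
        "n_dhs": len(sim.truth.dhs),
    }
    log.info("stage=simulate done t=%.1fs", time.time() - t0)

    expr = sim.expression
    tss = tss_table(sim.truth)
    state: dict = {"sim": sim}

    if rc.stages.get("feeding", True):
        diff_fed = nb_wald_test(expr, expr.samples_for("ZT10"), expr.samples_for("ZT14_fed"))
        diff_unfed = nb_wald_test(expr, expr.samples_for("ZT10"), expr.samples_for("ZT14_unfed"))
        write_differential(diff_fed, outdir / "diff_zt10_vs_fed.tsv")
        write_differential(diff_unfed, outdir / "diff_zt10_vs_unfed.tsv")
        quintiles = feed.assign_quintiles(diff_fed, diff_unfed, rc.gene_fdr)
        _write(quintiles, outdir / "quintiles.tsv", "gene")
        phases = feed.assign_phase(sim.circadian)
        _write(phases, outdir / "phases.tsv", "gene")
        zc, _ = zscore_rows(sim.circadian)
        if not quintiles.empty:
            profiles = feed.bin_profile(zc, quintiles["bin"])
            _write(profiles, outdir / "bin_profiles.tsv", "bin")
        induced, repressed = feed.select_regulated(diff_fed, rc.gene_fdr)
        state.update(diff_fed=diff_fed, diff_unfed=diff_unfed,
                     quintiles=quintiles, induced=induced, repressed=repressed)
        report["stages"]["feeding"] = {
            "n_induced": len(induced), "n_repressed": len(repressed),
            "n_rhythmic": int(phases["rhythmic"].sum()),
        }
        log.info("stage=feeding done t=%.1fs", time.time() - t0)

    if rc.stages.get("enhancers", True):
        ac = enh.differential_acetylation(sim.ac_counts, "ZT14_unfed", "ZT14_fed", rc.ac_fdr)
        write_differential(ac["diff"], outdir / "diff_ac_fed_vs_unfed.tsv")
        dn = nb_wald_test(sim.dnase_counts,
                          sim.dnase_counts.samples_for("unfed"),
                          sim.dnase_counts.samples_for("fed"))
        write_differential(dn, outdir / "diff_dnase_fed_vs_unfed.tsv")
        de_set = ac["up"] + ac["down"]
        r_de = enh.fc_correlation(dn["log2fc"], ac["diff"]["log2fc"], subset=de_set)
        r_all = enh.fc_correlation(dn["log2fc"], ac["diff"]["log2fc"])
        repressed_genes = state.get("repressed", [])
        ks = None
        if ac["down"] and repressed_genes:
            names = sim.dhs.df["name"]
            focal = PeakSet(sim.dhs.df[names.isin(ac["down"])])
            ks = enh.tss_distance_enrichment(
                focal, sim.dhs, tss[tss["gene"].isin(repressed_genes)]
            )
            _write(ks["focal_curve"], outdir / "tss_distance_focal.tsv", "i")
            _write(ks["reference_curve"], outdir / "tss_distance_reference.tsv", "i")
        means = _condition_means(sim.ac_counts, ["ZT10", "ZT14_fed", "ZT14_unfed"])
        zac, _ = zscore_rows(np.log2(means + 1))
        clusterable = zac.loc[[d for d in de_set if d in zac.index]]
        clusters = None
        if len(clusterable) >= rc.enhancer_clusters:
            clusters = enh.cluster_enhancers(clusterable, rc.enhancer_clusters)
            _write(clusters.to_frame(), outdir / "enhancer_clusters.tsv", "dhs")
        state.update(ac=ac, dn=dn, enhancer_clusters=clusters)
        report["stages"]["enhancers"] = {
            "n_up": len(ac["up"]), "n_down": len(ac["down"]),
            "r_de": round(r_de["r"], 4), "r_all": round(r_all["r"], 4),
            "ks_p": None if ks is None else ks["ks_p"],
        }
        log.info("stage=enhancers done t=%.1fs", time.time() - t0)

    if rc.stages.get("motifs", True) and state.get("ac") is not None:
        seqs = sim.sequences
        bg_ids = sorted(seqs)
        rng = np.random.default_rng(rc.seed)
        n_bg = min(2000, max(2, len(bg_ids) // 2))
        background = {i: seqs[i] for i in rng.choice(bg_ids, size=n_bg, replace=False)}
        bg_comp = mot.empirical_background(background)
        pwms = [p.with_background(bg_comp) for p in sim.pwms]
        target = {i: seqs[i] for i in state["ac"]["down"] if i in seqs}
        enrich = None
        if target:
            thresholds = {p.motif_id: 0.75 * p.max_score for p in pwms}
            rows = []
            for p in pwms:
                res = mot.motif_enrichment(target, background, [p], thresholds[p.motif_id])
                rows.append(res)
            enrich = pd.concat(rows)
            _write(enrich, outdir / "motif_enrichment.tsv")
        occ_cols = {}
        scores = {}
        for p in pwms:
            s = mot.best_scores(seqs, p)
            scores[p.motif_id] = s
            occ_cols[p.motif_id] = (s >= 0.75 * p.max_score).astype(int)
        occurrence = pd.DataFrame(occ_cols)
        ac_fc = state["ac"]["diff"]["log2fc"].dropna()
        common = occurrence.index.intersection(ac_fc.index)
        activity = mot.motif_activity(ac_fc.loc[common], occurrence.loc[common],
                                      seed=rc.seed)
        _write(activity, outdir / "motif_activity.tsv", "motif")
        kw = None
        if state.get("enhancer_clusters") is not None:
            kw = mot.cluster_motif_scores(scores["GRE"], state["enhancer_clusters"])
            _write(kw["pairwise_p"], outdir / "gre_cluster_pairwise_p.tsv", "cluster")
        state.update(motif_scores=scores, occurrence=occurrence, activity=activity)
        report["stages"]["motifs"] = {
            "n_motifs": len(pwms),
            "gre_kruskal_p": None if kw is None else kw["kruskal_p"],
        }
        log.info("stage=motifs done t=%.1fs", time.time() - t0)

    if rc.stages.get("occupancy", True) and state.get("ac") is not None:
        co = occ.co_occupancy(sim.dhs, sim.tf_peaks)
        _write(co["table"], outdir / "co_occupancy.tsv")
        venn = {"+".join(sorted(k)) or "none": v for k, v in co["venn"].items()}
        truth_cls = sim.truth.dhs["enhancer_class"]
        stable = truth_cls.index[truth_cls == "stable"]
        rocs = {}
        down = [d for d in state["ac"]["down"]]
        labels = pd.Series(
            [1] * len(down) + [0] * len(stable), index=list(down) + list(stable)
        )
        for factor in sim.tf_density.columns:
            sc = sim.tf_density[factor].loc[labels.index]
            rocs[factor] = occ.roc_predict(sc, labels)
            _write(rocs[factor]["curve"], outdir / f"roc_{factor}.tsv", "i")
        universe = list(sim.truth.genes.index)
        prox = occ.proximity_enrichment(
            state.get("repressed", []), sim.tf_peaks, tss, universe,
            window=rc.proximity_bp, n_random=rc.n_random_sets,
            random_size=rc.random_set_size, seed=rc.seed,
        )
        prox_df = pd.DataFrame(
            {f: {"observed": v["observed"], "null_mean": v["null_mean"],
                 "relative_enrichment": v["relative_enrichment"],
                 "t_p": v["t_p"], "perm_p": v["perm_p"]}
             for f, v in prox.items()}
        ).T
        _write(prox_df, outdir / "proximity_enrichment.tsv", "factor")
        diff_dex = nb_wald_test(sim.dex_ac_counts,
                                sim.dex_ac_counts.samples_for("veh_fed"),
                                sim.dex_ac_counts.samples_for("dex_fed"))
        write_differential(diff_dex, outdir / "diff_ac_dex_vs_veh.tsv")
        gr_bound = sim.truth.dhs.index[sim.truth.dhs["GR_occupied"]].tolist()
        bins = occ.dex_response_bins(diff_dex, gr_bound, rc.dex_bins)
        _write(bins.to_frame(), outdir / "dex_response_bins.tsv", "dhs")
        cmp_density = occ.bin_comparisons(sim.tf_density["GR"], bins)
        _write(cmp_density, outdir / "dex_bin_gr_density_tests.tsv", "i")
        state.update(co=co, rocs=rocs, prox=prox, diff_dex=diff_dex, dex_bins=bins)
        report["stages"]["occupancy"] = {
            "venn": venn,
            "auc": {f: round(r["auc"], 4) for f, r in rocs.items()},
            "proximity_relative_enrichment": {
                f: round(v["relative_enrichment"], 4) for f, v in prox.items()
            },
        }
        log.info("stage=occupancy done t=%.1fs", time.time() - t0)

    if rc.stages.get("hormone", True):
        diff_feed = nb_wald_test(expr, expr.samples_for("veh_unfed"),
                                 expr.samples_for("veh_fed"))
        write_differential(diff_feed, outdir / "diff_fed_vs_unfed_vehicle.tsv")
        repressed = horm.identify_feeding_repressed(diff_feed, rc.hormone_fdr)
        contrasts = {}
        for arm in ("dex", "s961", "dex_s961"):
            contrasts[arm] = nb_wald_test(
                expr, expr.samples_for("veh_fed"), expr.samples_for(f"{arm}_fed")
            )
            write_differential(contrasts[arm], outdir / f"diff_{arm}_vs_vehicle.tsv")
        calls = horm.classify_response(
            repressed, contrasts["dex"], contrasts["s961"], contrasts["dex_s961"],
            rc.hormone_fdr,
        )
        _write(calls, outdir / "hormone_clusters.tsv")
        # PCA over feeding-regulated genes, hormone-arm samples
        feeding_reg = diff_feed.index[diff_feed["fdr"] < rc.hormone_fdr].tolist()
        arm_samples = [s for s in expr.counts.columns
                       if expr.conditions[s] in
                       ("veh_fed", "veh_unfed", "dex_fed", "s961_fed", "dex_s961_fed")]
        pca = None
        if len(feeding_reg) >= 3 and arm_samples:
            logx = np.log2(expr.counts.loc[feeding_reg, arm_samples] + 1.0)
            groups = expr.conditions[arm_samples]
            pca = horm.pca_summary(logx, groups)
            _write(pca["scores"].iloc[:, :2], outdir / "pca_scores.tsv", "sample")
        # GR-regulated stand-in: genes whose true hormone cluster responds to dex
        truth_cluster = sim.truth.genes["hormone_cluster"]
        gr_regulated = truth_cluster.index[truth_cluster.isin([2.0, 4.0])].tolist()
        enrich = None
        if not calls.empty and calls["cluster"].notna().any():
            cl = calls["cluster"].dropna().astype(int)
            enrich = horm.cluster_enrichment(
                cl, gr_regulated, feeding_reg or list(expr.counts.index),
                n_random=rc.n_random_sets, seed=rc.seed,
            )
            _write(enrich, outdir / "hormone_cluster_enrichment.tsv")
        # obesity arm: 8-way clustering across lean/obese fed/unfed
        obes = None
        has_obese = "obese_fed" in set(expr.conditions)
        if has_obese and len(feeding_reg) >= rc.obesity_clusters:
            cond4 = ["ZT14_fed", "ZT14_unfed", "obese_fed", "obese_unfed"]
            means = _condition_means(expr, cond4)
            zme, _ = zscore_rows(np.log2(means.loc[feeding_reg] + 1))
            obes = horm.obesity_cluster_analysis(
                zme, pd.Series(cond4, index=cond4),
                ("ZT14_fed", "ZT14_unfed"), ("obese_fed", "obese_unfed"),
                k=rc.obesity_clusters,
            )
            _write(obes["clusters"].to_frame(), outdir / "obesity_clusters.tsv", "gene")
            _write(obes["comparisons"], outdir / "obesity_cluster_tests.tsv", "i")
        state.update(hormone_calls=calls, pca=pca)
        cluster_sizes = (
            calls["cluster"].dropna().astype(int).value_counts().sort_index().to_dict()
            if not calls.empty else {}
        )
        report["stages"]["hormone"] = {
            "n_feeding_repressed": len(repressed),
            "cluster_sizes": {int(k): int(v) for k, v in cluster_sizes.items()},
        }
        log.info("stage=hormone done t=%.1fs", time.time() - t0)

    report["outputs"] = sorted(str(p.relative_to(outdir)) for p in outdir.glob("*.tsv"))
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("pipeline done t=%.1fs", time.time() - t0)
    return report
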