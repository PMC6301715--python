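"""Hormone-response decision table, PCA summaries, cluster enrichment, and
the obesity clustering analysis."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from prandialreg.config import SimulationConfig
from prandialreg import simulate as sim
from prandialreg.countstats import nb_wald_test, zscore_rows
from prandialreg.hormones import (
    classify_response,
    cluster_enrichment,
    identify_feeding_repressed,
    obesity_cluster_analysis,
    pca_summary,
)


def diff_frame(entries):
    """entries: gene -> (log2fc, fdr)"""
    return pd.DataFrame(
        {"log2fc": {g: v[0] for g, v in entries.items()},
         "fdr": {g: v[1] for g, v in entries.items()},
         "pvalue": {g: v[1] for g, v in entries.items()}}
    )


class TestClassifyResponse:
    @pytest.mark.parametrize("dex,s961,combo,expected", [
        ((2.0, 0.01), (0.1, 0.9), (2.0, 0.01), 2),   # dex only -> 2
        ((0.1, 0.9), (2.0, 0.01), (2.0, 0.01), 3),   # S961 only -> 3
        ((2.0, 0.01), (2.0, 0.01), (2.0, 0.01), 4),  # both singles -> 4
        ((0.1, 0.9), (0.1, 0.9), (2.0, 0.01), 5),    # combo only -> 5
        ((0.1, 0.9), (0.1, 0.9), (0.1, 0.9), 1),     # none -> 1
    ])
    def test_decision_table_rows(self, dex, s961, combo, expected):
        calls = classify_response(
            ["g"], diff_frame({"g": dex}), diff_frame({"g": s961}),
            diff_frame({"g": combo}),
        )
        assert calls.loc["g", "cluster"] == expected

    def test_negative_fold_change_not_significant(self):
        # de-repression requires log2fc > 0 even at tiny FDR
        calls = classify_response(
            ["g"], diff_frame({"g": (-2.0, 0.001)}),
            diff_frame({"g": (0.0, 0.9)}), diff_frame({"g": (0.0, 0.9)}),
        )
        assert calls.loc["g", "cluster"] == 1

    def test_missing_contrast_flags_unclassified(self):
        calls = classify_response(
            ["g", "h"], diff_frame({"g": (2.0, 0.01)}),
            diff_frame({"g": (0.1, 0.9)}), diff_frame({"g": (0.1, 0.9)}),
        )
        assert calls.loc["h", "unclassified"]
        assert np.isnan(calls.loc["h", "cluster"])

    def test_gene_order_does_not_change_calls(self):
        entries = {f"g{i}": (float(i % 3), 0.01 if i % 2 else 0.5)
                   for i in range(20)}
        d = diff_frame(entries)
        genes = list(entries)
        a = classify_response(genes, d, d, d)
        b = classify_response(genes[::-1], d, d, d)
        assert a.sort_index()["cluster"].equals(b.sort_index()["cluster"])

    def test_planted_clusters_recovered(self, cohort):
        expr = cohort.expression
        diff_feed = nb_wald_test(expr, expr.samples_for("veh_unfed"),
                                 expr.samples_for("veh_fed"))
        repressed = identify_feeding_repressed(diff_feed, 0.05)
        contrasts = {
            arm: nb_wald_test(expr, expr.samples_for("veh_fed"),
                              expr.samples_for(f"{arm}_fed"))
            for arm in ("dex", "s961", "dex_s961")
        }
        calls = classify_response(repressed, contrasts["dex"],
                                  contrasts["s961"], contrasts["dex_s961"], 0.05)
        truth = cohort.truth.genes["hormone_cluster"]
        joined = pd.DataFrame({"called": calls["cluster"],
                               "true": truth}).dropna()
        for c in (2, 3, 4, 5):
            sub = joined[joined["true"] == c]
            assert (sub["called"] == c).mean() >= 0.7, f"cluster {c}"
        # misses land in cluster 1, not across the dex/S961 axis
        c2 = joined[joined["true"] == 2]
        c3 = joined[joined["true"] == 3]
        cross = ((c2["called"] == 3).sum() + (c3["called"] == 2).sum())
        assert cross <= 0.05 * (len(c2) + len(c3))


class TestPcaSummary:
    def test_reconstruction_to_machine_precision(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 8)),
                         columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=X.columns)
        res = pca_summary(X, groups)
        recon = (res["scores"].to_numpy() @ res["loadings"].to_numpy().T
                 + X.to_numpy().T.mean(axis=0, keepdims=True))
        assert np.allclose(recon, X.to_numpy().T, atol=1e-9)

    def test_duplicated_samples_share_ellipse_center(self, rng):
        base = rng.normal(size=(20, 3))
        X = pd.DataFrame(np.hstack([base, base]),
                         columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=X.columns)
        res = pca_summary(X, groups)
        assert np.allclose(res["ellipses"]["a"]["center"],
                           res["ellipses"]["b"]["center"], atol=1e-9)

    def test_single_axis_variance_on_first_component(self, rng):
        t = rng.normal(size=8)
        X = pd.DataFrame(np.outer(rng.normal(size=20), t),
                         columns=[f"s{i}" for i in range(8)])
        res = pca_summary(X, pd.Series("a", index=X.columns))
        assert res["explained_variance"].iloc[0] > 0.999

    def test_explained_variance_non_increasing(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 10)))
        res = pca_summary(X, pd.Series("a", index=X.columns))
        ev = res["explained_variance"].to_numpy()
        assert (np.diff(ev) <= 1e-12).all() and ev.sum() <= 1 + 1e-9

    def test_combo_arm_centroid_resembles_unfed(self, cohort):
        expr = cohort.expression
        diff_feed = nb_wald_test(expr, expr.samples_for("veh_unfed"),
                                 expr.samples_for("veh_fed"))
        reg = diff_feed.index[diff_feed["fdr"] < 0.05].tolist()
        samples = [s for s in expr.counts.columns
                   if expr.conditions[s] in ("veh_fed", "veh_unfed", "dex_s961_fed")]
        logx = np.log2(expr.counts.loc[reg, samples] + 1.0)
        res = pca_summary(logx, expr.conditions[samples])
        cen = {g: e["center"] for g, e in res["ellipses"].items()}
        d_unfed = np.linalg.norm(cen["dex_s961_fed"] - cen["veh_unfed"])
        d_fed = np.linalg.norm(cen["dex_s961_fed"] - cen["veh_fed"])
        assert d_unfed < d_fed


class TestClusterEnrichment:
    def test_regulated_equals_one_cluster(self, rng):
        clusters = pd.Series([1] * 30 + [2] * 30 + [3] * 30,
                             index=[f"g{i}" for i in range(90)])
        universe = list(clusters.index)
        regulated = list(clusters.index[clusters == 2])
        res = cluster_enrichment(clusters, regulated, universe,
                                 n_random=20, seed=0)
        assert res.loc[2, "relative_enrichment"] == res["relative_enrichment"].max()
        assert res.loc[2, "observed"] == 1.0
        assert (res.loc[[1, 3], "relative_enrichment"] < 1).all()

    def test_null_draw_centered_on_one(self, rng):
        clusters = pd.Series(rng.choice([1, 2, 3], size=300),
                             index=[f"g{i}" for i in range(300)])
        universe = list(clusters.index)
        rels = []
        for rep in range(50):
            regulated = list(rng.choice(universe, size=100, replace=False))
            res = cluster_enrichment(clusters, regulated, universe,
                                     n_random=10, seed=rep)
            rels.extend(res["relative_enrichment"].tolist())
        assert 0.9 <= np.mean(rels) <= 1.1

    def test_empty_cluster_flagged(self):
        clusters = pd.Series([1] * 5, index=[f"g{i}" for i in range(5)]).astype("category")
        clusters = clusters.cat.set_categories([1, 2])
        res = cluster_enrichment(clusters, ["g0"], list(clusters.index),
                                 n_random=3, seed=0)
        assert res.loc[2, "flagged"]


class TestObesityClusterAnalysis:
    def test_k_below_two_errors(self, rng):
        z = pd.DataFrame(rng.normal(size=(10, 4)),
                         columns=["lf", "lu", "of", "ou"])
        cond = pd.Series(["lf", "lu", "of", "ou"], index=z.columns)
        with pytest.raises(ValueError):
            obesity_cluster_analysis(z, cond, ("lf", "lu"), ("of", "ou"), k=1)

    def test_planted_eight_classes_recovered(self, rng):
        centers = rng.normal(0, 3, (8, 4))
        rows, truth = [], []
        for c in range(8):
            rows.append(centers[c] + rng.normal(0, 1, (30, 4)) / 2)
            truth += [c] * 30
        z = pd.DataFrame(np.vstack(rows), columns=["lf", "lu", "of", "ou"])
        cond = pd.Series(["lf", "lu", "of", "ou"], index=z.columns)
        res = obesity_cluster_analysis(z, cond, ("lf", "lu"), ("of", "ou"), k=8)
        assert adjusted_rand_score(truth, res["clusters"]) >= 0.8

    def test_identical_lean_obese_gives_uniformish_p(self, rng):
        base = rng.normal(size=(200, 2))
        z = pd.DataFrame(np.hstack([base, base]),
                         columns=["lf", "lu", "of", "ou"])
        cond = pd.Series(["lf", "lu", "of", "ou"], index=z.columns)
        res = obesity_cluster_analysis(z, cond, ("lf", "lu"), ("of", "ou"), k=4)
        # lean and obese columns are identical: every test is a tie at p = 1
        assert (res["comparisons"]["p"].dropna() > 0.99).all()
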