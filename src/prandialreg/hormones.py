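"""Decomposition of feeding-repressed genes into hormone-response clusters,
PCA summaries with error ellipses, and resampling cluster enrichments.

Feeding-repressed genes (expression falls upon feeding) are classified by
which injection de-represses them relative to fed vehicle: dex only
(cluster 2), S961 only (cluster 3), either alone (cluster 4), only the
combination (cluster 5), or none (cluster 1). "Regulated" requires both
FDR below the cut and a positive log2 fold change (de-repression); the
combination flag matters only when neither single arm is significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enhancers import cluster_enhancers


def identify_feeding_repressed(diff_fed_vs_unfed: pd.DataFrame, fdr_cut: float = 0.05) -> list[str]:
    """Genes suppressed by feeding: fdr < cut and log2fc(fed over unfed) < 0."""
    sel = (diff_fed_vs_unfed["fdr"] < fdr_cut) & (diff_fed_vs_unfed["log2fc"] < 0)
    return diff_fed_vs_unfed.index[sel].tolist()


def classify_response(
    genes: list[str],
    diff_dex: pd.DataFrame,
    diff_s961: pd.DataFrame,
    diff_combo: pd.DataFrame,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Cluster 1-5 call per feeding-repressed gene from three contrasts.

    Each contrast is the arm vs fed-vehicle; significance means fdr < cut
    with log2fc > 0. Genes missing from any contrast are flagged
    unclassified (cluster NaN).
    """
    def _flag(diff: pd.DataFrame, g: str) -> bool | None:
        if g not in diff.index or not np.isfinite(diff.loc[g, "pvalue"]):
            return None
        return bool((diff.loc[g, "fdr"] < fdr_cut) and (diff.loc[g, "log2fc"] > 0))

    rows = []
    for g in genes:
        dex, s961, combo = _flag(diff_dex, g), _flag(diff_s961, g), _flag(diff_combo, g)
        if dex is None or s961 is None or combo is None:
            rows.append({"gene": g, "dex": dex, "s961": s961, "combo": combo,
                         "cluster": np.nan, "unclassified": True})
            continue
        if dex and s961:
            cluster = 4
        elif dex:
            cluster = 2
        elif s961:
            cluster = 3
        elif combo:
            cluster = 5
        else:
            cluster = 1
        rows.append({"gene": g, "dex": dex, "s961": s961, "combo": combo,
                     "cluster": cluster, "unclassified": False})
    return pd.DataFrame(rows).set_index("gene")


def pca_summary(
    log_expression: pd.DataFrame,
    sample_groups: pd.Series,
    ellipse_level: float = 0.9,
) -> dict:
    """Mean-centered PCA of samples (SVD) with per-group error ellipses.

    Rows of ``log_expression`` are genes, columns samples; PCA is over
    samples in gene space. The ellipse for each group is the 2-D score
    covariance in PC1-PC2 scaled by the chi-square ``ellipse_level``
    quantile with 2 df.
    """
    X = log_expression.to_numpy(dtype=float).T   # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    var = s ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    score_df = pd.DataFrame(
        scores, index=log_expression.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    chi2_q = stats.chi2.ppf(ellipse_level, df=2)
    ellipses = {}
    for group, samples in sample_groups.groupby(sample_groups):
        pts = score_df.loc[samples.index, ["PC1", "PC2"]].to_numpy()
        center = pts.mean(axis=0)
        if len(pts) > 1:
            cov = np.cov(pts.T)
            evals, evecs = np.linalg.eigh(cov)
            axes = np.sqrt(np.maximum(evals, 0) * chi2_q)
            angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
        else:
            axes = np.zeros(2)
            angle = 0.0
        ellipses[group] = {"center": center, "axes": axes[::-1], "angle": angle}
    return {
        "scores": score_df,
        "loadings": pd.DataFrame(Vt.T, index=log_expression.index,
                                 columns=score_df.columns),
        "explained_variance": pd.Series(explained, index=score_df.columns),
        "ellipses": ellipses,
    }


def cluster_enrichment(
    clusters: pd.Series,
    regulated: list[str],
    universe: list[str],
    n_random: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster enrichment of a regulated gene set vs random draws.

    Observed: fraction of cluster members in the regulated set. Null: the
    same fraction for seeded random draws of |regulated| genes from the
    feeding-regulated universe. Empty clusters are flagged.
    """
    uni = np.asarray(universe)
    reg = set(regulated)
    if len(uni) < len(reg):
        raise ValueError("universe smaller than the regulated set")
    rng = np.random.default_rng(seed)
    draws = [set(rng.choice(uni, size=len(reg), replace=False)) for _ in range(n_random)]
    rows = []
    for cluster, members in clusters.groupby(clusters):
        ids = members.index
        n = len(ids)
        if n == 0:
            rows.append({"cluster": cluster, "n": 0, "observed": np.nan,
                         "null_mean": np.nan, "null_sem": np.nan,
                         "relative_enrichment": np.nan, "t_p": np.nan,
                         "perm_p": np.nan, "flagged": True})
            continue
        obs = float(np.mean([g in reg for g in ids]))
        null = np.array([np.mean([g in d for g in ids]) for d in draws])
        mean_null = float(null.mean())
        rel = obs / mean_null if mean_null > 0 else float("inf")
        if null.std(ddof=1) > 0:
            t_p = float(stats.ttest_1samp(null, obs).pvalue)
        else:
            t_p = 1.0 if obs == mean_null else 0.0
        perm_p = float((np.sum(np.abs(null - mean_null) >= abs(obs - mean_null)) + 1)
                       / (n_random + 1))
        rows.append({"cluster": cluster, "n": n, "observed": obs,
                     "null_mean": mean_null,
                     "null_sem": float(null.std(ddof=1) / np.sqrt(n_random)),
                     "relative_enrichment": rel, "t_p": t_p, "perm_p": perm_p,
                     "flagged": False})
    return pd.DataFrame(rows).set_index("cluster")


def obesity_cluster_analysis(
    zscores: pd.DataFrame,
    condition_of: pd.Series,
    lean_conditions: tuple[str, str],
    obese_conditions: tuple[str, str],
    k: int = 8,
) -> dict:
    """Hierarchical clustering of gene z-profiles across lean/obese arms.

    Ward clustering (k clusters) of genes; per cluster, a Mann-Whitney test
    compares lean vs obese per-gene mean expression within each feeding
    state.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    clusters = cluster_enhancers(zscores, k)
    lean_fed, lean_unfed = lean_conditions
    obese_fed, obese_unfed = obese_conditions
    rows = []
    for cluster, members in clusters.groupby(clusters):
        sub = zscores.loc[members.index]
        for state, lean_c, obese_c in (("fed", lean_fed, obese_fed),
                                       ("unfed", lean_unfed, obese_unfed)):
            lean_mean = sub[condition_of.index[condition_of == lean_c]].mean(axis=1)
            obese_mean = sub[condition_of.index[condition_of == obese_c]].mean(axis=1)
            if len(sub) >= 2:
                p = float(stats.mannwhitneyu(lean_mean, obese_mean,
                                             alternative="two-sided").pvalue)
            else:
                p = np.nan
            rows.append({"cluster": cluster, "state": state,
                         "lean_mean": float(lean_mean.mean()),
                         "obese_mean": float(obese_mean.mean()), "p": p})
    return {"clusters": clusters, "comparisons": pd.DataFrame(rows)}
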