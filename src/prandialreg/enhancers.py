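"""Enhancer activity: window quantification, differential acetylation,
DNase/H3K27Ac coupling, TSS-distance enrichment, and Ward clustering.

H3K27Ac and DNase signal is quantified in a fixed-width window (default
800 bp) centered on each DNase hypersensitive site; differential
acetylation reuses the NB Wald test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .countstats import CountMatrix, nb_wald_test
from .intervals import (
    GenomicInterval,
    PeakSet,
    distance_to_nearest_tss,
    window_around_center,
)


def quantify_at_dhs(
    tag_positions: dict[str, np.ndarray] | pd.DataFrame,
    dhs: PeakSet,
    width: int = 800,
) -> pd.DataFrame:
    """Tag counts in a width-bp window centered on each DHS.

    ``tag_positions`` maps chrom -> sorted (or unsorted) 1-bp tag positions;
    counting is half-open on the window. A DataFrame of pre-tabulated
    counts (indexed by DHS name) passes through unchanged.
    """
    if isinstance(tag_positions, pd.DataFrame):
        return tag_positions.loc[dhs.df["name"]]
    counts = np.zeros(len(dhs), dtype=int)
    sorted_tags = {c: np.sort(np.asarray(p)) for c, p in tag_positions.items()}
    for i, iv in enumerate(dhs):
        tags = sorted_tags.get(iv.chrom)
        if tags is None:
            continue
        win = window_around_center(iv, width)
        counts[i] = np.searchsorted(tags, win.end, side="left") - np.searchsorted(
            tags, win.start, side="left"
        )
    return pd.DataFrame({"count": counts}, index=pd.Index(dhs.df["name"], name="dhs"))


def differential_acetylation(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    fdr_cut: float = 0.1,
) -> dict:
    """NB Wald test of B over A at DHSs; classify significant DHSs by sign."""
    diff = nb_wald_test(cm, cm.samples_for(condition_a), cm.samples_for(condition_b))
    sig = diff["fdr"] < fdr_cut
    return {
        "diff": diff,
        "up": diff.index[sig & (diff["log2fc"] > 0)].tolist(),
        "down": diff.index[sig & (diff["log2fc"] < 0)].tolist(),
    }


def fc_correlation(x: pd.Series, y: pd.Series, subset=None) -> dict:
    """Pearson r of paired fold changes with a Fisher-z 95% CI."""
    if subset is not None:
        x, y = x.loc[subset], y.loc[subset]
    joined = pd.DataFrame({"x": x, "y": y}).replace([np.inf, -np.inf], np.nan).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need >= 3 finite pairs")
    r, p = stats.pearsonr(joined["x"], joined["y"])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return {"r": float(r), "p": float(p), "ci": (float(lo), float(hi)), "n": n}


def tss_distance_enrichment(
    focal: PeakSet, reference: PeakSet, tss: pd.DataFrame
) -> dict:
    """Cumulative |distance-to-TSS| curves and a two-sample KS test.

    Distances are absolute peak-center-to-nearest-TSS distances; the KS
    p-value is the two-sided asymptotic one.
    """
    d_focal = distance_to_nearest_tss(focal, tss)
    d_ref = distance_to_nearest_tss(reference, tss)
    a = np.abs(d_focal.loc[d_focal["defined"], "distance"].to_numpy())
    b = np.abs(d_ref.loc[d_ref["defined"], "distance"].to_numpy())
    if a.size == 0 or b.size == 0:
        raise ValueError("no defined distances in one of the sets")
    ks = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")

    def _curve(v):
        v = np.sort(v)
        return pd.DataFrame({"distance": v,
                             "cumulative": np.arange(1, v.size + 1) / v.size})

    return {
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "focal_curve": _curve(a),
        "reference_curve": _curve(b),
    }


def cluster_enhancers(zscores: pd.DataFrame, k: int) -> pd.Series:
    """Ward-linkage agglomerative clustering of z-scored profiles, cut at k.

    Euclidean distance, deterministic given the input; cluster labels are
    renumbered 1..k by order of first appearance.
    """
    n = len(zscores)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k ({k}) exceeds the number of rows ({n})")
    Z = hierarchy.linkage(zscores.to_numpy(dtype=float), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # stable renumbering by first appearance
    seen: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen) + 1
        labels[i] = seen[r]
    return pd.Series(labels, index=zscores.index, name="cluster")


def cluster_mean_profiles(zscores: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    return zscores.groupby(clusters).mean()
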