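"""Transcription-factor co-occupancy, ROC prediction of acetylation loss,
dex-response binning, and resampling-null gene-proximity enrichment.

"Occupied" means at least 1 bp of peak overlap with the region; gene
proximity uses the peak center within a window of the TSS. Relative
enrichment is the observed frequency divided by the mean frequency over
seeded random gene sets drawn from the annotated-gene universe.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet, overlap


def co_occupancy(regions: PeakSet, peak_sets: dict[str, PeakSet]) -> dict:
    """Per-region factor occupancy booleans plus Venn-cell counts.

    Venn cells are keyed by frozensets of factor names; the empty set counts
    regions bound by no factor. Cells partition the region set.
    """
    table = pd.DataFrame(index=pd.Index(regions.df["name"], name="region"))
    for factor, peaks in peak_sets.items():
        pairs = overlap(regions, peaks, min_bp=1)
        occ = np.zeros(len(regions), dtype=bool)
        occ[pairs["a_index"].unique()] = True
        table[factor] = occ
        if "tag_density" in peaks.df.columns:
            dens = np.zeros(len(regions))
            for ai, bi in zip(pairs["a_index"], pairs["b_index"]):
                dens[ai] += peaks.df["tag_density"].iloc[bi]
            table[f"{factor}_density"] = dens
    factors = list(peak_sets)
    cells = {}
    bool_mat = table[factors].to_numpy()
    for r in range(len(factors) + 1):
        for combo in combinations(range(len(factors)), r):
            mask = np.ones(len(regions), dtype=bool)
            for i in range(len(factors)):
                mask &= bool_mat[:, i] if i in combo else ~bool_mat[:, i]
            cells[frozenset(factors[i] for i in combo)] = int(mask.sum())
    return {"table": table, "venn": cells}


def roc_predict(scores: pd.Series, labels: pd.Series) -> dict:
    """ROC curve and AUC for a score predicting a binary label.

    AUC is computed as the Mann-Whitney U statistic divided by n1*n0
    (tie-aware), which equals the trapezoidal area under the ROC curve.
    """
    joined = pd.DataFrame({"s": scores, "y": labels}).dropna()
    y = joined["y"].astype(bool).to_numpy()
    s = joined["s"].to_numpy(dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be non-empty")
    u = stats.mannwhitneyu(s[y], s[~y], alternative="two-sided").statistic
    auc = float(u) / (n1 * n0)
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return {"auc": auc, "curve": curve, "n_pos": n1, "n_neg": n0}


def _frequency_with_peak(
    tss: pd.Series, peak_centers: np.ndarray, window: int
) -> float:
    """Fraction of genes with >= 1 peak center within ``window`` of the TSS."""
    if tss.empty:
        return float("nan")
    centers = np.sort(peak_centers)
    pos = tss.to_numpy(dtype=float)
    lo = np.searchsorted(centers, pos - window, side="left")
    hi = np.searchsorted(centers, pos + window, side="right")
    return float((hi > lo).mean())


def proximity_enrichment(
    gene_set: list[str],
    peak_sets: dict[str, PeakSet] | PeakSet,
    tss: pd.DataFrame,
    universe: list[str],
    window: int = 50_000,
    n_random: int = 6,
    random_size: int | None = None,
    seed: int = 0,
) -> dict:
    """Observed vs resampled-null frequency of nearby TF peaks per gene set.

    ``tss`` needs columns (gene, chrom, position). A single PeakSet (or the
    union of several) is evaluated as "any factor"; a dict additionally
    reports each factor on its own. Null gene sets are sampled without
    replacement from the universe; p-values come from a one-sample t-test
    of the null frequencies against the observed value and from a sign
    permutation count (fraction of null frequencies at least as extreme).
    """
    if random_size is None:
        random_size = len(gene_set)
    if len(universe) < random_size:
        raise ValueError("universe smaller than the random set size")
    tss_idx = tss.set_index("gene")["position"]
    if isinstance(peak_sets, PeakSet):
        peak_sets = {"any": peak_sets}
    center_map = {f: ps.centers() for f, ps in peak_sets.items()}
    if len(peak_sets) > 1:
        center_map["any"] = np.concatenate(list(center_map.values()))
    rng = np.random.default_rng(seed)
    uni = np.asarray(universe)
    draws = [rng.choice(uni, size=random_size, replace=False) for _ in range(n_random)]
    out = {}
    for factor, centers in center_map.items():
        obs = _frequency_with_peak(tss_idx.loc[tss_idx.index.intersection(gene_set)], centers, window)
        null = np.array([
            _frequency_with_peak(tss_idx.loc[tss_idx.index.intersection(d)], centers, window)
            for d in draws
        ])
        mean_null = float(null.mean())
        rel = obs / mean_null if mean_null > 0 else float("inf")
        if null.std(ddof=1) > 0:
            t_p = float(stats.ttest_1samp(null, obs).pvalue)
        else:
            t_p = 1.0 if obs == mean_null else 0.0
        perm_p = float(
            (np.sum(np.abs(null - mean_null) >= abs(obs - mean_null)) + 1)
            / (n_random + 1)
        )
        out[factor] = {
            "observed": obs,
            "null_frequencies": null,
            "null_mean": mean_null,
            "null_sem": float(null.std(ddof=1) / np.sqrt(n_random)) if n_random > 1 else float("nan"),
            "relative_enrichment": rel,
            "t_p": t_p,
            "perm_p": perm_p,
        }
    return out


def dex_response_bins(
    diff_dex: pd.DataFrame,
    gr_bound: list[str],
    n_bins: int = 3,
) -> pd.Series:
    """Tertiles of GR-bound DHSs by dex-induced acetylation change.

    Ranked by dex log2fc descending; bin "high" holds the strongest
    inducers. Remainder rows go to the higher-response bins. Returns labels
    high/medium/low (or bin1..binN for other n_bins).
    """
    sub = diff_dex.loc[[g for g in gr_bound if g in diff_dex.index]]
    sub = sub.dropna(subset=["log2fc"])
    if len(sub) < n_bins:
        raise ValueError("fewer bound DHSs than bins")
    order = sub.sort_values(
        ["log2fc"], ascending=False, kind="mergesort"
    ).index
    n = len(order)
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    names = ["high", "medium", "low"] if n_bins == 3 else [f"bin{i+1}" for i in range(n_bins)]
    labels = np.repeat(names, sizes)
    return pd.Series(labels, index=order, name="dex_bin")


def bin_comparisons(values: pd.Series, bins: pd.Series) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests of a per-region quantity between bins."""
    joined = pd.DataFrame({"v": values, "b": bins}).dropna()
    names = joined["b"].unique().tolist()
    rows = []
    for a, b in combinations(names, 2):
        va = joined.loc[joined["b"] == a, "v"]
        vb = joined.loc[joined["b"] == b, "v"]
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append({"bin_a": a, "bin_b": b,
                     "median_a": float(va.median()), "median_b": float(vb.median()),
                     "p": float(res.pvalue)})
    return pd.DataFrame(rows)
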