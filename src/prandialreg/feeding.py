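"""Classification of circadian genes by feeding dependence (quintiles, phases).

Genes differentially expressed across the ZT10 -> ZT14-fed transition are
ranked by how much of that change persists without food (the ZT10 vs
ZT14-unfed fold change): a change that survives fasting is
feeding-independent (clock-driven), one that vanishes is feeding-driven.
Q1 holds the most feeding-independent fifth, Q5 the most feeding-dependent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def select_regulated(diff: pd.DataFrame, fdr_cut: float = 0.01) -> tuple[list[str], list[str]]:
    """Split significantly regulated features by fold-change sign.

    ``diff`` is an nb_wald_test result (log2fc of ZT14-fed over ZT10 for the
    feeding analysis). Induced: fdr < cut and log2fc > 0; repressed:
    fdr < cut and log2fc < 0. Exact-zero fold changes are excluded.
    """
    ok = diff["fdr"] < fdr_cut
    induced = diff.index[ok & (diff["log2fc"] > 0)].tolist()
    repressed = diff.index[ok & (diff["log2fc"] < 0)].tolist()
    return induced, repressed


def quintile_bin(
    stats: pd.Series,
    n_bins: int = 5,
    most_affected_low_stat: bool = True,
) -> pd.Series:
    """Equal-size bins of genes by |ranking statistic|.

    With ``most_affected_low_stat`` (the feeding analysis), Q1 takes the
    genes whose ZT10-vs-unfed change is largest (feeding-independent) and
    Q5 the genes whose change disappears without food (feeding-dependent).
    Bin sizes differ by at most one; the remainder goes to the lower-index
    bins. Ties in |stat| break lexicographically by gene id.
    """
    if len(stats) < n_bins:
        raise ValueError(f"need >= {n_bins} genes, got {len(stats)}")
    absval = stats.abs()
    order = pd.DataFrame({"a": absval, "g": absval.index.astype(str)})
    order = order.sort_values(["a", "g"], ascending=[not most_affected_low_stat, True])
    n = len(order)
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if i < rem else 0) for i in range(n_bins)]
    labels = np.repeat([f"Q{i + 1}" for i in range(n_bins)], sizes)
    return pd.Series(labels, index=order.index, name="bin").loc[stats.index]


def assign_quintiles(
    diff_fed: pd.DataFrame,
    diff_unfed: pd.DataFrame,
    fdr_cut: float = 0.01,
) -> pd.DataFrame:
    """Full quintile table for feeding-regulated genes.

    ``diff_fed``: ZT14-fed over ZT10; ``diff_unfed``: ZT14-unfed over ZT10
    (the ranking statistic). Direction is relative to the ZT10 -> ZT14-fed
    transition.
    """
    induced, repressed = select_regulated(diff_fed, fdr_cut)
    frames = []
    for direction, genes in (("induced", induced), ("repressed", repressed)):
        if len(genes) < 5:
            continue
        stat = diff_unfed.loc[genes, "log2fc"]
        bins = quintile_bin(stat)
        frames.append(pd.DataFrame({
            "direction": direction, "bin": bins, "stat": stat,
        }))
    if not frames:
        return pd.DataFrame(columns=["direction", "bin", "stat"])
    out = pd.concat(frames)
    out.index.name = "gene"
    return out


def assign_phase(
    series: pd.DataFrame,
    timepoints: np.ndarray | None = None,
    period: float = 24.0,
    amplitude_threshold: float = 2.0,
) -> pd.DataFrame:
    """Least-squares cosinor fit per gene: y = m + a*cos(2*pi*(t - phi)/T).

    ``series`` is genes x timepoints; ``timepoints`` in hours (parsed from
    column names like CT04 when omitted). A gene is called rhythmic when its
    fitted amplitude exceeds ``amplitude_threshold`` times the residual sd;
    non-rhythmic genes get phase NaN.
    """
    if timepoints is None:
        timepoints = np.array([float(c.lstrip("CTZT")) for c in series.columns])
    t = np.asarray(timepoints, dtype=float)
    if t.size < 4 or (t.max() - t.min()) < 12:
        raise ValueError("need >= 4 timepoints spanning >= 12 h")
    w = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    Y = series.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    mesor, bc, bs = coef
    amplitude = np.hypot(bc, bs)
    phase = (np.arctan2(bs, bc) / w) % period
    resid = Y - (X @ coef).T
    dof = max(t.size - 3, 1)
    resid_sd = np.sqrt((resid ** 2).sum(axis=1) / dof)
    rhythmic = amplitude > amplitude_threshold * resid_sd
    # a numerically-zero amplitude (constant series) is never rhythmic
    rhythmic &= amplitude > 1e-9 * np.maximum(np.abs(mesor), 1.0)
    out = pd.DataFrame({
        "mesor": mesor,
        "amplitude": amplitude,
        "phase": np.where(rhythmic, phase, np.nan),
        "rhythmic": rhythmic,
    }, index=series.index)
    return out


def bin_profile(
    zscores: pd.DataFrame, bins: pd.Series
) -> pd.DataFrame:
    """Mean z-score per bin per timepoint (rows: bins, columns: timepoints)."""
    common = zscores.index.intersection(bins.index)
    grouped = zscores.loc[common].groupby(bins.loc[common])
    return grouped.mean()
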