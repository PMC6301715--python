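"""Normalization and negative-binomial differential testing for count data.

The differential test is a two-group NB comparison in the spirit of the
standard RNA-seq tools: median-of-ratios size factors, per-feature
method-of-moments dispersion shrunk toward a log-linear mean-dispersion
trend, and a Wald test on the log2 fold change with BH correction.
The NB variance model is ``var = mu + alpha * mu**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts with condition labels.

    ``samples`` maps sample id -> condition; replicate structure is implied
    by repeated conditions. Feature ids must be unique.
    """

    counts: pd.DataFrame          # index: feature ids, columns: sample ids
    conditions: pd.Series         # index: sample ids, values: condition names

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.counts.columns if c not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        self.conditions = self.conditions.loc[self.counts.columns]

    def samples_for(self, condition: str) -> list[str]:
        sel = self.conditions[self.conditions == condition]
        if sel.empty:
            raise ValueError(f"no samples for condition {condition!r}")
        return list(sel.index)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, conditions: pd.Series | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if conditions is None:
            # column convention: <condition>_rep<N>
            conditions = pd.Series(
                {c: c.rsplit("_rep", 1)[0] for c in df.columns}
            )
        return cls(df, conditions)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric mean reference).

    Computed over features with all-positive counts; errors if none exist.
    """
    mat = counts.to_numpy(dtype=float)
    pos = (mat > 0).all(axis=1)
    if not pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "consider a pseudo-reference"
        )
    sub = mat[pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def rpkm(counts: pd.DataFrame, lengths: pd.Series, libsize: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads."""
    lengths = lengths.loc[counts.index]
    libsize = libsize.loc[counts.columns]
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if (libsize <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e9 / np.outer(lengths.to_numpy(), libsize.to_numpy())


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-row z-scores (sample sd, n-1). Constant rows become 0 and are flagged."""
    mat = matrix.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (mat - mean) / safe_sd
    z[constant, :] = 0.0
    zdf = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return zdf, pd.Series(constant, index=matrix.index, name="constant_row")


def _dispersion_trend(mean: np.ndarray, alpha_raw: np.ndarray) -> np.ndarray:
    """Log-linear fit of dispersion on mean; falls back to the global mean."""
    ok = (alpha_raw > 1e-8) & (mean > 0)
    if ok.sum() < 10:
        fallback = float(np.mean(alpha_raw[alpha_raw > 0])) if (alpha_raw > 0).any() else 0.01
        return np.full_like(mean, max(fallback, 1e-8))
    x = np.log(mean[ok])
    y = np.log(alpha_raw[ok])
    slope, intercept = np.polyfit(x, y, 1)
    trend = np.exp(intercept + slope * np.log(np.maximum(mean, 1e-8)))
    return np.clip(trend, 1e-8, 100.0)


def nb_wald_test(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test, log2 fold change of B over A.

    Per-feature dispersion is a 50/50 blend of the (floored) method-of-moments
    estimate with the fitted mean-dispersion trend. The Wald statistic
    ``log2fc / SE`` is referred to a t distribution with ``nA + nB - 2``
    degrees of freedom (small-sample correction for plug-in variances).
    Features with zero counts in every sample are excluded and flagged
    (``tested = False``); their statistics are NaN.

    Returns a DataFrame with columns
    ``baseMean, log2fc, se, stat, pvalue, fdr, tested``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    # unique columns only; the same sample may appear in both groups
    cols = list(dict.fromkeys(list(group_a) + list(group_b)))
    counts = cm.counts[cols]
    sf = size_factors(counts)
    norm = (counts / sf).to_numpy(dtype=float)
    pos = {c: i for i, c in enumerate(cols)}
    na, nb = len(group_a), len(group_b)

    arr_a = norm[:, [pos[c] for c in group_a]]
    arr_b = norm[:, [pos[c] for c in group_b]]
    mean_a = arr_a.mean(axis=1)
    mean_b = arr_b.mean(axis=1)
    base_mean = norm.mean(axis=1)
    tested = base_mean > 0

    # pooled within-group method-of-moments dispersion
    df_w = max(na - 1, 0) + max(nb - 1, 0)
    if df_w > 0:
        ss = arr_a.var(axis=1, ddof=1) * (na - 1) if na > 1 else np.zeros_like(mean_a)
        ss = ss + (arr_b.var(axis=1, ddof=1) * (nb - 1) if nb > 1 else 0.0)
        s2 = ss / df_w
    else:
        s2 = np.zeros_like(mean_a)
    grand = (na * mean_a + nb * mean_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (s2 - grand) / np.square(grand)
    alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, 0.0)
    alpha_raw = np.maximum(alpha_raw, 0.0)
    trend = _dispersion_trend(grand[tested], alpha_raw[tested]) if tested.any() else np.array([])
    alpha = np.zeros_like(grand)
    alpha[tested] = 0.5 * alpha_raw[tested] + 0.5 * trend

    # log2 fold change; +0.5 pseudocount only when a group mean is zero
    zero_grp = (mean_a == 0) | (mean_b == 0)
    la = np.where(zero_grp, mean_a + 0.5, mean_a)
    lb = np.where(zero_grp, mean_b + 0.5, mean_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(lb / la)

    # delta-method SE of log2 mean per group: Var(norm count_j) = mu/sf_j + alpha*mu^2
    inv_sf_a = np.sum(1.0 / sf[group_a].to_numpy())
    inv_sf_b = np.sum(1.0 / sf[group_b].to_numpy())

    def _var_log2_mean(mu, n, inv_sf_sum):
        var_mean = (mu * inv_sf_sum / n + alpha * mu * mu) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            return var_mean / np.square(mu * np.log(2.0))

    va = _var_log2_mean(la, na, inv_sf_a)
    vb = _var_log2_mean(lb, nb, inv_sf_b)
    se = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = log2fc / se
    # moderated-t reference: the 50/50 shrinkage toward the trend contributes
    # prior degrees of freedom equal to the residual df (equal-weight blend),
    # so the plug-in variance behaves like one estimated at twice the df
    resid_df = max(na + nb - 2, 1)
    dof = 2 * resid_df
    pvalue = 2.0 * stats.t.sf(np.abs(stat), df=dof)
    pvalue = np.where(np.isfinite(stat), pvalue, 1.0)
    # identical groups: zero fold change, no evidence
    pvalue = np.where(log2fc == 0.0, 1.0, pvalue)

    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "fdr": np.nan,
            "tested": tested,
        },
        index=counts.index,
    )
    out.loc[~tested, ["log2fc", "se", "stat", "pvalue"]] = np.nan
    mask = tested & out["pvalue"].notna()
    out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "pvalue"].to_numpy())
    return out


def write_differential(result: pd.DataFrame, path) -> None:
    out = result[["baseMean", "log2fc", "pvalue", "fdr"]].copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", float_format="%.6g")
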