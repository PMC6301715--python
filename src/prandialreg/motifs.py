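"""PWM log-odds scoring, motif enrichment, and motif-activity regression.

A region's motif score is the best log2-odds window score over both strands
(``sum log2(p_base / bg_base)`` across positions). Motif activity is a
ridge regression of per-region differential acetylation on binary motif
occurrence; the coefficient plays the role of an activity: negative
activity means regions carrying the motif lose signal in the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .countstats import bh_fdr

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}
UNIFORM_BG = np.array([0.25, 0.25, 0.25, 0.25])


@dataclass
class PWM:
    """Position weight matrix over A/C/G/T with background and pseudocount."""

    motif_id: str
    probs: np.ndarray                      # shape (length, 4)
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (length, 4)")
        if (self.probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def regularized(self) -> np.ndarray:
        """Row-normalized probabilities after adding the pseudocount."""
        p = self.probs + self.pseudocount
        return p / p.sum(axis=1, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.regularized / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def with_background(self, background: np.ndarray) -> "PWM":
        return PWM(self.motif_id, self.probs.copy(), np.asarray(background, float),
                   self.pseudocount)


def read_jaspar(path) -> list[PWM]:
    """Read a JASPAR-style matrix file (A/C/G/T count rows in brackets)."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            totals = counts.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            out.append(PWM(motif_id=m.name or m.matrix_id, probs=counts / totals))
    return out


def write_jaspar(pwms: list[PWM], path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\t{pwm.motif_id}\n")
            counts = np.round(pwm.probs * scale).astype(int)
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{c:4d}" for c in counts[:, bi])
                fh.write(f"{base}  [ {row} ]\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _encode(sequence: str) -> np.ndarray:
    return np.array([_CODE.get(b, -1) for b in sequence.upper()], dtype=np.int8)


def pwm_log_odds_scan(sequence: str, pwm: PWM, threshold: float = 0.0) -> dict:
    """Scan both strands; report windows scoring >= threshold and the best.

    Windows containing an ambiguous base (N) are skipped. Returns
    ``{"hits": DataFrame(offset, strand, score), "best_score": float|None,
    "flagged": bool}``; flagged means the sequence was shorter than the
    motif and no window existed.
    """
    codes = _encode(sequence)
    L = len(pwm)
    n_win = codes.size - L + 1
    if n_win <= 0:
        return {"hits": pd.DataFrame(columns=["offset", "strand", "score"]),
                "best_score": None, "flagged": True}
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    lo = pwm.log_odds
    # reverse-complement log-odds applied to the forward window
    lo_rc = lo[::-1][:, [3, 2, 1, 0]]
    pos_idx = np.arange(L)
    safe = np.where(windows >= 0, windows, 0)
    fwd = lo[pos_idx[None, :], safe].sum(axis=1)
    rev = lo_rc[pos_idx[None, :], safe].sum(axis=1)
    fwd[~valid] = -np.inf
    rev[~valid] = -np.inf
    rows = []
    for strand, scores in (("+", fwd), ("-", rev)):
        keep = np.flatnonzero(valid & (scores >= threshold))
        for off in keep:
            rows.append((int(off), strand, float(scores[off])))
    hits = pd.DataFrame(rows, columns=["offset", "strand", "score"])
    best = max(fwd.max(), rev.max())
    best_score = float(best) if np.isfinite(best) else None  # all-N: no window
    return {"hits": hits, "best_score": best_score, "flagged": best_score is None}


def best_scores(sequences: dict[str, str], pwm: PWM) -> pd.Series:
    """Best log-odds score per sequence (NaN when shorter than the motif)."""
    vals = {}
    for sid, seq in sequences.items():
        res = pwm_log_odds_scan(seq, pwm, threshold=np.inf)
        vals[sid] = np.nan if res["best_score"] is None else res["best_score"]
    return pd.Series(vals, name=pwm.motif_id)


def empirical_background(sequences: dict[str, str]) -> np.ndarray:
    """Base composition of a sequence collection (ACGT fractions)."""
    counts = np.zeros(4)
    for seq in sequences.values():
        codes = _encode(seq)
        codes = codes[codes >= 0]
        counts += np.bincount(codes, minlength=4)
    if counts.sum() == 0:
        return UNIFORM_BG.copy()
    return counts / counts.sum()


def motif_enrichment(
    target: dict[str, str],
    background: dict[str, str],
    pwms: list[PWM],
    score_threshold: float,
) -> pd.DataFrame:
    """Fraction of target vs background sequences with >= 1 hit per motif.

    One-sided binomial test of the target hit count against the background
    hit fraction (floored at half a pseudo-hit to avoid a degenerate null).
    """
    if not pwms:
        return pd.DataFrame(
            columns=["percent_target", "percent_background", "pvalue"],
            index=pd.Index([], name="motif"),
        )
    rows = []
    for pwm in pwms:
        t_hits = int((best_scores(target, pwm) >= score_threshold).sum())
        b_hits = int((best_scores(background, pwm) >= score_threshold).sum())
        n_t, n_b = len(target), len(background)
        bg_frac = b_hits / n_b if n_b else 0.0
        p0 = min(max(bg_frac, 0.5 / max(n_b, 1)), 1 - 1e-12)
        pval = stats.binomtest(t_hits, n_t, p=p0, alternative="greater").pvalue
        rows.append({
            "motif": pwm.motif_id,
            "percent_target": 100.0 * t_hits / n_t if n_t else np.nan,
            "percent_background": 100.0 * bg_frac,
            "pvalue": pval,
        })
    return pd.DataFrame(rows).set_index("motif")


def cluster_motif_scores(
    scores: pd.Series, clusters: pd.Series, gate_p: float = 0.05
) -> dict:
    """Kruskal-Wallis omnibus + BH-adjusted pairwise Mann-Whitney tests.

    Pairwise tests run only when the omnibus p is below ``gate_p``.
    """
    joined = pd.DataFrame({"score": scores, "cluster": clusters}).dropna()
    groups = [g["score"].to_numpy() for _, g in joined.groupby("cluster")]
    labels = sorted(joined["cluster"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 clusters")
    kw_stat, kw_p = stats.kruskal(*groups)
    pair = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    if kw_p < gate_p:
        raw = []
        pairs = list(combinations(labels, 2))
        for a, b in pairs:
            xa = joined.loc[joined["cluster"] == a, "score"]
            xb = joined.loc[joined["cluster"] == b, "score"]
            raw.append(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        adj = bh_fdr(raw)
        for (a, b), p in zip(pairs, adj):
            pair.loc[a, b] = p
            pair.loc[b, a] = p
    return {"kruskal_stat": float(kw_stat), "kruskal_p": float(kw_p),
            "pairwise_p": pair}


def motif_activity(
    log2fc: pd.Series,
    occurrence: pd.DataFrame,
    ridge_lambda: float = 1.0,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Ridge regression of differential signal on binary motif occurrence.

    The intercept is unpenalized (data are centered before the solve).
    Standard errors and p-values come from a seeded residual bootstrap.
    Constant occurrence columns (all 0 or all 1) carry no information and
    are flagged with NaN activity.
    """
    occurrence = occurrence.loc[log2fc.index]
    X = occurrence.to_numpy(dtype=float)
    y = log2fc.to_numpy(dtype=float)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("occurrence matrix must be binary")
    const = (X == X[0]).all(axis=0)
    keep = ~const
    Xk = X[:, keep]
    n, k = Xk.shape
    xm = Xk.mean(axis=0)
    ym = y.mean()
    Xc = Xk - xm
    yc = y - ym

    gram = Xc.T @ Xc + ridge_lambda * np.eye(k)
    gram_inv = np.linalg.inv(gram)
    solve = gram_inv @ Xc.T
    beta = solve @ yc
    fitted = Xc @ beta + ym
    resid = y - fitted

    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, k))
    for b in range(n_bootstrap):
        ystar = fitted + rng.choice(resid, size=n, replace=True)
        boots[b] = solve @ (ystar - ystar.mean())
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    ci_low = np.quantile(boots, 0.025, axis=0)
    ci_high = np.quantile(boots, 0.975, axis=0)

    out = pd.DataFrame(
        {"activity": np.nan, "se": np.nan, "pvalue": np.nan,
         "ci_low": np.nan, "ci_high": np.nan, "flagged": const},
        index=occurrence.columns,
    )
    cols = occurrence.columns[keep]
    out.loc[cols, "activity"] = beta
    out.loc[cols, "se"] = se
    out.loc[cols, "pvalue"] = pvalue
    out.loc[cols, "ci_low"] = ci_low
    out.loc[cols, "ci_high"] = ci_high
    return out
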