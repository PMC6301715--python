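"""Synthetic liver cohort generator.

Emulates the statistical structure of a night-restricted-feeding study:
RNA-seq counts at ZT10 / ZT14-fed / ZT14-unfed, circadian reference
profiles, an enhancer landscape with coupled DNase and H3K27Ac changes,
transcription-factor peak sets whose tag density predicts acetylation loss,
enhancer sequences with planted motifs, and hormone (dex / S961) arms that
de-repress specific clusters of feeding-repressed genes. Ground-truth class
labels are returned alongside every output so downstream stages can be
tested as parameter-recovery problems.

Counts are negative binomial with variance ``m + dispersion * m**2``.
Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    ENHANCER_CLASSES,
    GENE_CLASSES,
    HORMONE_CLUSTERS,
    SimulationConfig,
)
from .countstats import CountMatrix
from .intervals import PeakSet

MAIN_CONDITIONS = ("ZT10", "ZT14_fed", "ZT14_unfed")
HORMONE_ARMS = ("veh", "dex", "s961", "dex_s961")
# which hormone clusters are de-repressed (restored to unfed level) per arm
ARM_RESPONSIVE_CLUSTERS = {
    "veh": frozenset(),
    "dex": frozenset({2, 4}),
    "s961": frozenset({3, 4}),
    "dex_s961": frozenset({2, 3, 4, 5}),
}
TF_FACTORS = ("GR", "FOXO1", "CREB")
CIRCADIAN_TIMEPOINTS = tuple(range(0, 24, 2))

BASES = np.array(list("ACGT"))


@dataclass
class GroundTruth:
    """Latent per-gene and per-DHS labels behind the simulated cohort."""

    genes: pd.DataFrame            # index: gene id
    dhs: pd.DataFrame | None = None        # index: dhs id
    planted_motif_hits: pd.DataFrame | None = None

    @property
    def hormone_cluster(self) -> pd.Series:
        return self.genes.loc[self.genes["hormone_cluster"].notna(), "hormone_cluster"].astype(int)

    def to_json(self, path) -> None:
        payload = {"genes": self.genes.reset_index().to_dict(orient="list")}
        if self.dhs is not None:
            payload["dhs"] = self.dhs.reset_index().to_dict(orient="list")
        if self.planted_motif_hits is not None:
            payload["planted_motif_hits"] = self.planted_motif_hits.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def _exact_counts(n: int, proportions: dict) -> dict:
    """Largest-remainder apportionment so label counts are exact."""
    keys = list(proportions)
    raw = np.array([proportions[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return dict(zip(keys, base))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = m + dispersion*m^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _lognormal_means(rng: np.random.Generator, n: int, mean: float, sdlog: float = 0.5) -> np.ndarray:
    """Per-feature baselines, lognormal with the requested arithmetic mean."""
    mu = np.log(mean) - sdlog**2 / 2.0
    return rng.lognormal(mu, sdlog, size=n)


# ---------------------------------------------------------------------------
# annotation and gene classes

def generate_annotation(config: SimulationConfig) -> tuple[PeakSet, GroundTruth]:
    """Non-overlapping genes on one chromosome with strand-aware TSSs.

    Each gene sits in its own genome slot; TSS is the interval start on the
    plus strand and ``end - 1`` on the minus strand. Gene classes, circadian
    phases, feeding directions and hormone clusters are assigned here.
    """
    n = config.n_genes
    slot = config.genome_length // n
    if slot < 10_000:
        raise ValueError(
            f"genome too small: need genome_length >= n_genes x 10 kb, "
            f"slot is {slot} bp"
        )
    rng = config.rng("annotation")
    starts = np.arange(n) * slot + rng.integers(1000, slot - 6000, size=n)
    lengths = rng.integers(2000, 5001, size=n)
    strands = rng.choice(["+", "-"], size=n)
    ids = [f"gene_{i:05d}" for i in range(n)]
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + lengths,
            "name": ids,
            "score": 0.0,
            "strand": strands,
        }
    )
    tss = np.where(strands == "+", starts, starts + lengths - 1)

    crng = config.rng("classes")
    counts = _exact_counts(n, config.class_proportions)
    labels = np.concatenate([np.full(c, k) for k, c in counts.items()])
    crng.shuffle(labels)
    zt10_high = crng.random(n) < 0.5
    phase = np.where(labels == "null", np.nan, crng.uniform(0, 24, size=n))

    truth_genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
            "tss": tss,
            "gene_class": labels,
            "zt10_high": zt10_high,
            "gene_phase": phase,
        },
        index=pd.Index(ids, name="gene"),
    )
    # feeding-repressed = expression falls upon feeding (fed < unfed)
    repressed = truth_genes["gene_class"].isin(["feeding_driven", "mixed"]) & truth_genes["zt10_high"]
    truth_genes["feeding_repressed"] = repressed
    cluster = np.full(n, np.nan)
    idx = np.flatnonzero(repressed.to_numpy())
    ccounts = _exact_counts(len(idx), config.hormone_cluster_proportions)
    clabels = np.concatenate([np.full(c, k) for k, c in ccounts.items()])
    crng.shuffle(clabels)
    cluster[idx] = clabels
    truth_genes["hormone_cluster"] = cluster
    # obesity arm: a fraction of feeding-responsive genes lose their response
    responsive = truth_genes["gene_class"].isin(["feeding_driven", "mixed"]).to_numpy()
    blunted = responsive & (crng.random(n) < config.obese_blunted_fraction)
    truth_genes["obese_blunted"] = blunted
    return PeakSet(genes), GroundTruth(genes=truth_genes)


def tss_table(truth: GroundTruth) -> pd.DataFrame:
    """(chrom, position, gene) table of TSSs for the simulated genes."""
    out = truth.genes[["chrom", "tss"]].rename(columns={"tss": "position"})
    return out.reset_index()


# ---------------------------------------------------------------------------
# expression counts

def _condition_means(config: SimulationConfig, truth: GroundTruth,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene expected counts for ZT10 / ZT14-fed / ZT14-unfed."""
    g = truth.genes
    n = len(g)
    base = _lognormal_means(rng, n, config.baseline_mean)
    s = np.where(g["zt10_high"].to_numpy(), 1.0, -1.0)
    e = config.effect_size_log2fc
    cls = g["gene_class"].to_numpy()

    zt10 = base.copy()
    fed = base.copy()
    unfed = base.copy()
    is_clock = cls == "clock_driven"
    is_feed = cls == "feeding_driven"
    is_mixed = cls == "mixed"
    # clock: ZT10 differs from both ZT14 arms equally
    zt10[is_clock] = base[is_clock] * 2.0 ** (s[is_clock] * e)
    # feeding: only the fed arm moves; unfed stays at the ZT10 level
    fed[is_feed] = base[is_feed] * 2.0 ** (-s[is_feed] * e)
    # mixed: full clock effect at ZT10, partial persistence unfed, none fed
    zt10[is_mixed] = base[is_mixed] * 2.0 ** (s[is_mixed] * e)
    unfed[is_mixed] = base[is_mixed] * 2.0 ** (s[is_mixed] * e / 2.0)
    return pd.DataFrame(
        {"ZT10": zt10, "ZT14_fed": fed, "ZT14_unfed": unfed}, index=g.index
    )


def generate_expression_counts(
    config: SimulationConfig,
    truth: GroundTruth,
    include_hormone_arms: bool = False,
    include_obese: bool = False,
) -> CountMatrix:
    """NB expression counts for the main time-course and optional arms.

    Hormone arms follow the de-repression decision table: within the fed
    state, a feeding-repressed gene returns to its unfed-level mean when its
    hormone cluster responds to the injected arm (cluster 2 to dex, 3 to
    S961, 4 to either alone, 5 only to the combination, 1 to none). Unfed
    arms always sit at the unfed mean. The optional obese arm removes the
    feeding response of the genes flagged ``obese_blunted``.
    """
    rng = config.rng("expression")
    means = _condition_means(config, truth, rng)
    blocks: dict[str, np.ndarray] = {}
    for cond in MAIN_CONDITIONS:
        blocks[cond] = np.column_stack([
            _nb_draw(rng, means[cond].to_numpy(), config.dispersion)
            for _ in range(config.n_replicates)
        ])
    if include_hormone_arms:
        cluster = truth.genes["hormone_cluster"]
        # feeding-induced genes depend on insulin signaling: blocking the
        # insulin receptor (any S961-containing arm) keeps them at the
        # unfed level in the fed state
        induced = (
            truth.genes["gene_class"].isin(["feeding_driven", "mixed"])
            & ~truth.genes["zt10_high"]
        ).to_numpy()
        for arm in HORMONE_ARMS:
            responsive = cluster.isin(ARM_RESPONSIVE_CLUSTERS[arm]).to_numpy()
            if "s961" in arm:
                responsive = responsive | induced
            fed_mean = np.where(responsive, means["ZT14_unfed"], means["ZT14_fed"])
            for state, mean in (("fed", fed_mean), ("unfed", means["ZT14_unfed"].to_numpy())):
                blocks[f"{arm}_{state}"] = np.column_stack([
                    _nb_draw(rng, mean, config.dispersion)
                    for _ in range(config.hormone_replicates)
                ])
    if include_obese:
        orng = config.rng("obese")
        blunted = truth.genes["obese_blunted"].to_numpy()
        obese_fed = np.where(blunted, means["ZT14_unfed"], means["ZT14_fed"])
        obese_unfed = means["ZT14_unfed"].to_numpy()
        for cond, mean in (("obese_fed", obese_fed), ("obese_unfed", obese_unfed)):
            blocks[cond] = np.column_stack([
                _nb_draw(orng, mean, config.dispersion)
                for _ in range(config.n_replicates)
            ])
    cols, data, conds = [], [], {}
    for cond, mat in blocks.items():
        for r in range(mat.shape[1]):
            name = f"{cond}_rep{r + 1}"
            cols.append(name)
            conds[name] = cond
            data.append(mat[:, r])
    counts = pd.DataFrame(
        np.column_stack(data), index=truth.genes.index, columns=cols
    )
    return CountMatrix(counts, pd.Series(conds))


def generate_circadian_series(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Cosine circadian reference profiles sampled every 2 h over 24 h.

    Non-null genes oscillate with the configured relative amplitude around
    their baseline, peaking at their true phase; multiplicative lognormal
    noise with the configured CV is applied. Null genes are flat plus noise.
    """
    rng = config.rng("circadian")
    g = truth.genes
    n = len(g)
    t = np.array(CIRCADIAN_TIMEPOINTS, dtype=float)
    base = _lognormal_means(rng, n, config.baseline_mean)
    amp = np.where(g["gene_class"] == "null", 0.0, config.circadian_amplitude)
    phase = np.nan_to_num(g["gene_phase"].to_numpy())
    clean = base[:, None] * (
        1.0 + amp[:, None] * np.cos(2 * np.pi * (t[None, :] - phase[:, None]) / 24.0)
    )
    cv = config.circadian_cv
    sdlog = np.sqrt(np.log(1 + cv * cv))
    noise = rng.lognormal(-sdlog**2 / 2, sdlog, size=clean.shape)
    out = pd.DataFrame(clean * noise, index=g.index,
                       columns=[f"CT{int(x):02d}" for x in t])
    return out


# ---------------------------------------------------------------------------
# enhancer landscape

def generate_enhancer_landscape(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[PeakSet, CountMatrix, CountMatrix]:
    """DHS intervals plus H3K27Ac and DNase count matrices.

    Non-stable DHSs are placed within ``coupling_distance`` of a linked
    gene's TSS (feeding_down near feeding-repressed genes, feeding_up near
    feeding-induced genes, clock near clock/mixed genes); stable DHSs are
    uniform over the genome. Planted DNase log2 fold changes are coupled to
    the H3K27Ac ones with Pearson correlation ``dnase_ac_coupling`` over
    the non-stable set; stable DHSs carry no planted change.
    """
    rng = config.rng("enhancers")
    n = config.n_dhs
    counts = _exact_counts(n, config.enhancer_class_proportions)
    labels = np.concatenate([np.full(c, k) for k, c in counts.items()])
    rng.shuffle(labels)
    g = truth.genes
    pools = {
        "feeding_down": g.index[g["feeding_repressed"]].to_numpy(),
        "feeding_up": g.index[
            g["gene_class"].isin(["feeding_driven", "mixed"]) & ~g["zt10_high"]
        ].to_numpy(),
        "clock": g.index[g["gene_class"].isin(["clock_driven", "mixed"])].to_numpy(),
    }
    for cls, pool in pools.items():
        if counts.get(cls, 0) > 0 and pool.size == 0:
            raise ValueError(f"no eligible genes to link {cls} DHSs to")

    half = config.dhs_width // 2
    centers = np.empty(n, dtype=int)
    linked = np.full(n, None, dtype=object)
    tss = g["tss"]
    for i, cls in enumerate(labels):
        if cls == "stable":
            centers[i] = rng.integers(half, config.genome_length - half)
        else:
            gid = pools[cls][rng.integers(pools[cls].size)]
            linked[i] = gid
            offset = rng.integers(-config.coupling_distance, config.coupling_distance + 1)
            centers[i] = int(np.clip(tss.loc[gid] + offset, half,
                                     config.genome_length - half))
    ids = [f"dhs_{i:05d}" for i in range(n)]
    dhs = PeakSet(pd.DataFrame({
        "chrom": "chr1",
        "start": centers - half,
        "end": centers + half,
        "name": ids,
        "score": 0.0,
        "strand": ".",
    }))

    e = config.enhancer_effect_log2fc
    jit = config.enhancer_effect_jitter_sd
    nonstable = labels != "stable"
    ac_fc = np.zeros(n)       # fed over unfed
    clock_fc = np.zeros(n)    # ZT10 over unfed
    sign = rng.choice([-1.0, 1.0], size=n)
    ac_fc[labels == "feeding_down"] = -e + rng.normal(0, jit, (labels == "feeding_down").sum())
    ac_fc[labels == "feeding_up"] = e + rng.normal(0, jit, (labels == "feeding_up").sum())
    is_clock = labels == "clock"
    ac_fc[is_clock] = rng.normal(0, jit, is_clock.sum())
    clock_fc[is_clock] = sign[is_clock] * e
    # couple DNase to acetylation at exactly the configured correlation
    rho = config.dnase_ac_coupling
    dn_fc = np.zeros(n)
    if nonstable.any():
        a = ac_fc[nonstable]
        sd = a.std() if a.std() > 0 else 1.0
        w = rng.normal(0, 1, nonstable.sum())
        dn_fc[nonstable] = rho * a + np.sqrt(max(0.0, 1 - rho * rho)) * sd * w

    idx = pd.Index(ids, name="dhs")
    truth.dhs = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": centers - half,
            "end": centers + half,
            "center": centers,
            "enhancer_class": labels,
            "linked_gene": linked,
            "ac_log2fc": ac_fc,
            "clock_log2fc": clock_fc,
            "dnase_log2fc": dn_fc,
        },
        index=idx,
    )

    ac_base = _lognormal_means(rng, n, config.baseline_mean)
    dn_base = _lognormal_means(rng, n, config.baseline_mean)
    ac_means = {
        "ZT10": ac_base * 2.0 ** clock_fc,
        "ZT14_fed": ac_base * 2.0 ** ac_fc,
        "ZT14_unfed": ac_base,
    }
    dn_means = {"fed": dn_base * 2.0 ** dn_fc, "unfed": dn_base}

    def _matrix(means: dict) -> CountMatrix:
        cols, data, conds = [], [], {}
        for cond, mean in means.items():
            for r in range(config.n_replicates):
                name = f"{cond}_rep{r + 1}"
                cols.append(name)
                conds[name] = cond
                data.append(_nb_draw(rng, mean, config.dispersion))
        return CountMatrix(
            pd.DataFrame(np.column_stack(data), index=idx, columns=cols),
            pd.Series(conds),
        )

    return dhs, _matrix(ac_means), _matrix(dn_means)


# ---------------------------------------------------------------------------
# transcription-factor peaks

def generate_tf_peaks(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, PeakSet], pd.DataFrame]:
    """Peak sets for GR/FOXO1/CREB analogs plus per-DHS tag densities.

    Log tag density at each DHS is normal with unit sd, shifted upward by
    ``tf_separation`` sd at feeding_down DHSs (so occupancy predicts
    acetylation loss). Peak membership is density-weighted; the GR and
    FOXO1 sets share ``tf_overlap_fraction`` of the smaller set's sites
    exactly, with the remainders disjoint.
    """
    if truth.dhs is None:
        raise ValueError("generate_enhancer_landscape must run first")
    rng = config.rng("tf_peaks")
    n = len(truth.dhs)
    down = (truth.dhs["enhancer_class"] == "feeding_down").to_numpy()
    densities = {}
    for factor in TF_FACTORS:
        logd = rng.normal(0, 1, n) + config.tf_separation * down
        densities[factor] = 10.0 * np.exp(logd)
    density_df = pd.DataFrame(densities, index=truth.dhs.index)

    n_gr = int(round(0.35 * n))
    n_foxo = int(round(0.25 * n))
    n_creb = int(round(0.30 * n))
    small = min(n_gr, n_foxo)
    shared = int(round(config.tf_overlap_fraction * small))

    w = density_df["GR"].to_numpy() + density_df["FOXO1"].to_numpy()
    order = np.arange(n)
    shared_idx = rng.choice(order, size=shared, replace=False, p=w / w.sum())
    remaining = np.setdiff1d(order, shared_idx)
    extra = rng.choice(remaining, size=(n_gr - shared) + (n_foxo - shared), replace=False)
    gr_idx = np.concatenate([shared_idx, extra[: n_gr - shared]])
    foxo_idx = np.concatenate([shared_idx, extra[n_gr - shared:]])
    wc = density_df["CREB"].to_numpy()
    creb_idx = rng.choice(order, size=n_creb, replace=False, p=wc / wc.sum())

    members = {"GR": gr_idx, "FOXO1": foxo_idx, "CREB": creb_idx}
    centers = truth.dhs["center"].to_numpy()
    half = config.dhs_width // 2
    peaks = {}
    occupied = {}
    for factor, idx in members.items():
        idx = np.sort(idx)
        df = pd.DataFrame({
            "chrom": "chr1",
            "start": centers[idx] - half,
            "end": centers[idx] + half,
            "name": [f"{factor}_peak_{j}" for j in range(idx.size)],
            "score": 0.0,
            "strand": ".",
            "tag_density": density_df[factor].to_numpy()[idx],
        })
        peaks[factor] = PeakSet(df)
        occ = np.zeros(n, dtype=bool)
        occ[idx] = True
        occupied[factor] = occ
    for factor in TF_FACTORS:
        truth.dhs[f"{factor}_occupied"] = occupied[factor]
        truth.dhs[f"{factor}_density"] = density_df[factor]
    return peaks, density_df


def generate_dex_acetylation(
    config: SimulationConfig, truth: GroundTruth, slope: float = 0.5
) -> CountMatrix:
    """H3K27Ac counts under vehicle vs dexamethasone in the fed state.

    The planted dex log2 fold change at GR-occupied DHSs is proportional to
    the standardized log GR tag density (plus noise); unoccupied DHSs do
    not respond. Stored in ``truth.dhs['dex_log2fc']``.
    """
    if truth.dhs is None or "GR_density" not in truth.dhs:
        raise ValueError("generate_tf_peaks must run first")
    rng = config.rng("hormone")
    n = len(truth.dhs)
    logd = np.log(truth.dhs["GR_density"].to_numpy())
    z = (logd - logd.mean()) / logd.std()
    occ = truth.dhs["GR_occupied"].to_numpy()
    fc = np.where(occ, slope * z + rng.normal(0, 0.2, n), 0.0)
    truth.dhs["dex_log2fc"] = fc
    base = _lognormal_means(rng, n, config.baseline_mean)
    means = {"veh_fed": base, "dex_fed": base * 2.0 ** fc}
    cols, data, conds = [], [], {}
    for cond, mean in means.items():
        for r in range(config.n_replicates):
            name = f"{cond}_rep{r + 1}"
            cols.append(name)
            conds[name] = cond
            data.append(_nb_draw(rng, mean, config.dispersion))
    return CountMatrix(
        pd.DataFrame(np.column_stack(data), index=truth.dhs.index, columns=cols),
        pd.Series(conds),
    )


# ---------------------------------------------------------------------------
# sequences and motifs

DRIVER_CONSENSUS = {
    "GRE": "AGAACATTCTGTTCT",
    "FOXO": "TTGTTTAC",
    "CREB": "TGACGTCA",
}


def _pwm_from_consensus(motif_id: str, consensus: str, match_p: float = 0.85):
    from .motifs import PWM  # local import to avoid a cycle

    probs = np.full((len(consensus), 4), (1 - match_p) / 3)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = match_p
    return PWM(motif_id=motif_id, probs=probs)


def default_pwm_set(config: SimulationConfig, n_decoys: int = 8) -> list:
    """Driver PWMs (GRE/FOXO/CREB analogs) plus random decoy PWMs."""
    rng = config.rng("sequences")
    pwms = [_pwm_from_consensus(k, v) for k, v in DRIVER_CONSENSUS.items()]
    for j in range(n_decoys):
        cons = "".join(rng.choice(BASES, size=8))
        pwms.append(_pwm_from_consensus(f"DECOY{j + 1:02d}", cons))
    return pwms


def generate_sequences_with_motifs(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[dict[str, str], list, pd.DataFrame]:
    """Per-DHS sequences with i.i.d. background at the configured GC.

    Driver-motif consensus sequences are planted at ``motif_planting_rate``
    in feeding_down DHSs and at a quarter of that rate elsewhere (decoys at
    the background rate everywhere); each planted occurrence is recorded as
    (dhs, motif, offset). Without ground truth, all motifs are planted
    uniformly at the configured rate.
    """
    rng = config.rng("sequences")
    # burn the decoy-consensus draws so sequences match default_pwm_set output
    pwms = [_pwm_from_consensus(k, v) for k, v in DRIVER_CONSENSUS.items()]
    for j in range(8):
        cons = "".join(rng.choice(BASES, size=8))
        pwms.append(_pwm_from_consensus(f"DECOY{j + 1:02d}", cons))

    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if truth is not None and truth.dhs is not None:
        ids = list(truth.dhs.index)
        down = (truth.dhs["enhancer_class"] == "feeding_down").to_numpy()
    else:
        ids = [f"dhs_{i:05d}" for i in range(config.n_dhs)]
        down = np.zeros(len(ids), dtype=bool)
    L = config.dhs_seq_length
    seqs: dict[str, str] = {}
    hits = {"dhs": [], "motif": [], "offset": []}
    for i, did in enumerate(ids):
        seq = rng.choice(BASES, size=L, p=probs)
        for pwm in pwms:
            cons = pwm.consensus
            is_driver = pwm.motif_id in DRIVER_CONSENSUS
            if truth is None:
                rate = config.motif_planting_rate
            elif is_driver:
                rate = config.motif_planting_rate if down[i] else config.motif_planting_rate / 4
            else:
                rate = config.motif_planting_rate / 4
            if rng.random() < rate:
                off = int(rng.integers(0, L - len(cons) + 1))
                seq[off: off + len(cons)] = list(cons)
                hits["dhs"].append(did)
                hits["motif"].append(pwm.motif_id)
                hits["offset"].append(off)
        seqs[did] = "".join(seq)
    return seqs, pwms, pd.DataFrame(hits)


def generate_motif_activity_dataset(
    config: SimulationConfig,
    n_dhs: int = 2000,
    n_decoys: int = 20,
    activities: dict[str, float] | None = None,
    occurrence_rate: float = 0.3,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Binary motif-occurrence matrix with planted per-motif activities.

    The response is ``log2fc = occurrence @ activity + noise``; decoy motifs
    have activity 0. This is the parameter-recovery benchmark for the
    motif-activity regression.
    """
    if activities is None:
        activities = {"DRIVER_NEG": -1.0, "DRIVER_POS": 0.5}
    rng = config.rng("activity")
    motifs = list(activities) + [f"DECOY{j + 1:02d}" for j in range(n_decoys)]
    occ = rng.random((n_dhs, len(motifs))) < occurrence_rate
    beta = np.array([activities.get(m, 0.0) for m in motifs])
    y = occ @ beta + rng.normal(0, noise_sd, n_dhs)
    idx = pd.Index([f"dhs_{i:05d}" for i in range(n_dhs)], name="dhs")
    occ_df = pd.DataFrame(occ.astype(int), index=idx, columns=motifs)
    return occ_df, pd.Series(y, index=idx, name="log2fc"), dict(zip(motifs, beta))


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SimulationResult:
    config: SimulationConfig
    truth: GroundTruth
    genes: PeakSet
    expression: CountMatrix
    circadian: pd.DataFrame
    dhs: PeakSet
    ac_counts: CountMatrix
    dnase_counts: CountMatrix
    tf_peaks: dict
    tf_density: pd.DataFrame
    dex_ac_counts: CountMatrix
    sequences: dict
    pwms: list
    planted_hits: pd.DataFrame


def simulate_all(
    config: SimulationConfig,
    include_hormone_arms: bool = True,
    include_obese: bool = False,
) -> SimulationResult:
    """Run every generator stage in dependency order."""
    genes, truth = generate_annotation(config)
    expression = generate_expression_counts(
        config, truth,
        include_hormone_arms=include_hormone_arms,
        include_obese=include_obese,
    )
    circadian = generate_circadian_series(config, truth)
    dhs, ac_counts, dnase_counts = generate_enhancer_landscape(config, truth)
    tf_peaks, tf_density = generate_tf_peaks(config, truth)
    dex_ac = generate_dex_acetylation(config, truth)
    seqs, pwms, hits = generate_sequences_with_motifs(config, truth)
    truth.planted_motif_hits = hits
    return SimulationResult(
        config=config, truth=truth, genes=genes, expression=expression,
        circadian=circadian, dhs=dhs, ac_counts=ac_counts,
        dnase_counts=dnase_counts, tf_peaks=tf_peaks, tf_density=tf_density,
        dex_ac_counts=dex_ac, sequences=seqs, pwms=pwms, planted_hits=hits,
    )


def write_outputs(result: SimulationResult, outdir) -> dict[str, str]:
    """Write all simulated inputs as plain-text files (BED/TSV/FASTA/JSON)."""
    from .intervals import write_bed
    from .motifs import write_jaspar

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = str(outdir / name)
        return outdir / name

    write_bed(result.genes, _p("genes.bed"))
    write_bed(result.dhs, _p("dhs.bed"))
    result.expression.to_tsv(_p("expression_counts.tsv"))
    result.ac_counts.to_tsv(_p("h3k27ac_counts.tsv"))
    result.dnase_counts.to_tsv(_p("dnase_counts.tsv"))
    result.dex_ac_counts.to_tsv(_p("h3k27ac_dex_counts.tsv"))
    circ = result.circadian.copy()
    circ.index.name = "gene"
    circ.to_csv(_p("circadian_series.tsv"), sep="\t", float_format="%.6g")
    for factor, ps in result.tf_peaks.items():
        df = ps.df.copy()
        path = _p(f"peaks_{factor}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    with open(_p("sequences.fa"), "w") as fh:
        for did, seq in result.sequences.items():
            fh.write(f">{did}\n{seq}\n")
    write_jaspar(result.pwms, _p("motifs.jaspar"))
    result.truth.to_json(_p("ground_truth.json"))
    result.config.to_yaml(_p("sim_config.yaml"))
    return paths
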