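"""Ground-truth bookkeeping, NB moment checks, coupling structure, and
determinism of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prandialreg.config import SimulationConfig
from prandialreg import simulate as sim
from prandialreg.motifs import pwm_log_odds_scan


def cfg(**kw):
    base = dict(seed=7, n_genes=400, n_dhs=500)
    base.update(kw)
    return SimulationConfig(**base)


class TestAnnotation:
    def test_tss_strand_convention(self):
        _, truth = sim.generate_annotation(cfg())
        g = truth.genes
        plus = g[g["strand"] == "+"]
        minus = g[g["strand"] == "-"]
        assert (plus["tss"] == plus["start"]).all()
        assert (minus["tss"] == minus["end"] - 1).all()

    def test_genes_do_not_overlap(self):
        genes, _ = sim.generate_annotation(cfg())
        df = genes.df
        assert (df["start"].to_numpy()[1:] >= df["end"].to_numpy()[:-1]).all()

    def test_genome_too_small_raises_sizing_error(self):
        with pytest.raises(ValueError, match="10 kb"):
            SimulationConfig(seed=1, n_genes=1000, genome_length=5_000_000)

    def test_class_counts_exact(self):
        _, truth = sim.generate_annotation(cfg(n_genes=400))
        counts = truth.genes["gene_class"].value_counts()
        assert counts["clock_driven"] == 60 and counts["feeding_driven"] == 60
        assert counts["mixed"] == 40 and counts["null"] == 240

    def test_phase_only_for_non_null_genes(self):
        _, truth = sim.generate_annotation(cfg())
        g = truth.genes
        assert g.loc[g["gene_class"] == "null", "gene_phase"].isna().all()
        assert g.loc[g["gene_class"] != "null", "gene_phase"].notna().all()


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        for d in ("run1", "run2"):
            res = sim.simulate_all(cfg(), include_hormone_arms=True)
            sim.write_outputs(res, tmp_path / d)
        files1 = sorted((tmp_path / "run1").iterdir())
        for f1 in files1:
            f2 = tmp_path / "run2" / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_different_seed_changes_counts(self):
        a = sim.simulate_all(cfg(seed=7), include_hormone_arms=False)
        b = sim.simulate_all(cfg(seed=8), include_hormone_arms=False)
        assert not a.expression.counts.equals(b.expression.counts)


class TestExpressionMoments:
    def test_null_class_mean_matches_baseline(self):
        config = SimulationConfig(
            seed=5, n_genes=5000, baseline_mean=100.0,
            genome_length=5000 * 12_000,
            class_proportions={"clock_driven": 0, "feeding_driven": 0,
                               "mixed": 0, "null": 1.0},
        )
        _, truth = sim.generate_annotation(config)
        cm = sim.generate_expression_counts(config, truth)
        vals = cm.counts.to_numpy(dtype=float).ravel()
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 100.0) <= 3 * se

    def test_feeding_effect_size_recovered(self):
        config = cfg(n_genes=800, effect_size_log2fc=2.0,
                     genome_length=800 * 12_000)
        _, truth = sim.generate_annotation(config)
        cm = sim.generate_expression_counts(config, truth)
        g = truth.genes
        feed = g.index[g["gene_class"] == "feeding_driven"]
        zt10 = cm.counts.loc[feed, cm.samples_for("ZT10")].mean(axis=1)
        fed = cm.counts.loc[feed, cm.samples_for("ZT14_fed")].mean(axis=1)
        s = np.where(g.loc[feed, "zt10_high"], 1.0, -1.0)
        lfc = s * np.log2((zt10 + 0.5) / (fed + 0.5))
        assert abs(lfc.mean() - 2.0) < 0.2

    def test_unfed_tracks_zt10_for_feeding_genes(self):
        config = cfg()
        _, truth = sim.generate_annotation(config)
        cm = sim.generate_expression_counts(config, truth)
        feed = truth.genes.index[truth.genes["gene_class"] == "feeding_driven"]
        zt10 = cm.counts.loc[feed, cm.samples_for("ZT10")].mean(axis=1)
        unfed = cm.counts.loc[feed, cm.samples_for("ZT14_unfed")].mean(axis=1)
        lfc = np.log2((zt10 + 0.5) / (unfed + 0.5))
        assert abs(lfc.mean()) < 0.15

    def test_nb_goodness_of_fit_not_rejected(self):
        """Chi-square GOF of the NB sampler against NB(mean, dispersion)."""
        dispersion, mean, n = 0.1, 50.0, 5000
        rng = np.random.default_rng(9)
        draw = sim._nb_draw(rng, np.full(n, mean), dispersion)
        size = 1 / dispersion
        dist = stats.nbinom(size, size / (size + mean))
        edges = np.unique(dist.ppf(np.linspace(0.0, 1.0, 21))[:-1])
        obs, _ = np.histogram(draw, bins=np.append(edges, np.inf))
        upper = np.append(edges[1:] - 1, np.inf)
        expected = (dist.cdf(upper) - dist.cdf(edges - 1)) * n
        keep = expected > 5
        chi2 = ((obs[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, df=keep.sum() - 1)
        assert p > 0.01


class TestHormoneArms:
    def test_decision_table_restores_unfed_means(self):
        config = cfg(n_genes=1000, genome_length=1000 * 12_000,
                     hormone_replicates=20)
        _, truth = sim.generate_annotation(config)
        cm = sim.generate_expression_counts(config, truth, include_hormone_arms=True)
        g = truth.genes
        for arm, responsive in (("dex", {2, 4}), ("s961", {3, 4}),
                                ("dex_s961", {2, 3, 4, 5})):
            resp = g.index[g["hormone_cluster"].isin(responsive)]
            nonresp = g.index[g["hormone_cluster"].notna()
                              & ~g["hormone_cluster"].isin(responsive)]
            arm_fed = cm.counts.loc[:, cm.samples_for(f"{arm}_fed")].mean(axis=1)
            unfed = cm.counts.loc[:, cm.samples_for("veh_unfed")].mean(axis=1)
            veh_fed = cm.counts.loc[:, cm.samples_for("veh_fed")].mean(axis=1)
            # responders move to the unfed level, non-responders stay fed-low
            d_resp = np.log2((arm_fed.loc[resp] + 0.5) / (unfed.loc[resp] + 0.5))
            d_non = np.log2((arm_fed.loc[nonresp] + 0.5) / (veh_fed.loc[nonresp] + 0.5))
            assert abs(d_resp.mean()) < 0.2, arm
            assert abs(d_non.mean()) < 0.2, arm


class TestEnhancerLandscape:
    def test_class_bookkeeping_exact(self):
        config = cfg(n_dhs=500)
        _, truth = sim.generate_annotation(config)
        sim.generate_enhancer_landscape(config, truth)
        assert (truth.dhs["enhancer_class"] == "feeding_down").sum() == 40
        assert (truth.dhs["enhancer_class"] == "stable").sum() == 400

    def test_nonstable_within_coupling_distance(self):
        config = cfg(coupling_distance=10_000)
        _, truth = sim.generate_annotation(config)
        sim.generate_enhancer_landscape(config, truth)
        nz = truth.dhs[truth.dhs["enhancer_class"] != "stable"]
        tss = truth.genes["tss"]
        d = (nz["center"] - nz["linked_gene"].map(tss)).abs()
        assert (d <= 10_000).all()

    def test_feeding_down_links_to_feeding_or_mixed_gene(self):
        config = cfg()
        _, truth = sim.generate_annotation(config)
        sim.generate_enhancer_landscape(config, truth)
        down = truth.dhs[truth.dhs["enhancer_class"] == "feeding_down"]
        classes = truth.genes.loc[down["linked_gene"], "gene_class"]
        assert classes.isin(["feeding_driven", "mixed"]).all()

    def test_all_stable_landscape_has_no_fc_correlation(self):
        config = SimulationConfig(
            seed=3, n_genes=200, n_dhs=2000, genome_length=200 * 12_000,
            enhancer_class_proportions={"feeding_up": 0, "feeding_down": 0,
                                        "clock": 0, "stable": 1.0},
        )
        _, truth = sim.generate_annotation(config)
        _, ac, dn = sim.generate_enhancer_landscape(config, truth)
        a = np.log2(ac.counts[ac.samples_for("ZT14_fed")].mean(axis=1) + 0.5) - \
            np.log2(ac.counts[ac.samples_for("ZT14_unfed")].mean(axis=1) + 0.5)
        d = np.log2(dn.counts[dn.samples_for("fed")].mean(axis=1) + 0.5) - \
            np.log2(dn.counts[dn.samples_for("unfed")].mean(axis=1) + 0.5)
        assert abs(np.corrcoef(a, d)[0, 1]) < 0.1

    def test_planted_coupling_correlation(self):
        config = cfg(n_dhs=2000, dnase_ac_coupling=0.8)
        _, truth = sim.generate_annotation(config)
        sim.generate_enhancer_landscape(config, truth)
        ns = truth.dhs["enhancer_class"] != "stable"
        r = np.corrcoef(truth.dhs.loc[ns, "ac_log2fc"],
                        truth.dhs.loc[ns, "dnase_log2fc"])[0, 1]
        assert 0.75 < r < 0.85


class TestTfPeaks:
    @pytest.mark.parametrize("frac,expected", [(1.0, "min"), (0.0, 0)])
    def test_overlap_fraction_limit_cases(self, frac, expected):
        config = cfg(tf_overlap_fraction=frac)
        _, truth = sim.generate_annotation(config)
        sim.generate_enhancer_landscape(config, truth)
        peaks, _ = sim.generate_tf_peaks(config, truth)
        n_gr = len(peaks["GR"])
        n_foxo = len(peaks["FOXO1"])
        both = truth.dhs["GR_occupied"] & truth.dhs["FOXO1_occupied"]
        if expected == "min":
            assert both.sum() == min(n_gr, n_foxo)
        else:
            assert both.sum() == 0

    def test_zero_separation_gives_chance_level_density_split(self):
        config = cfg(n_dhs=2000, tf_separation=0.0)
        _, truth = sim.generate_annotation(config)
        sim.generate_enhancer_landscape(config, truth)
        _, density = sim.generate_tf_peaks(config, truth)
        down = truth.dhs["enhancer_class"] == "feeding_down"
        stable = truth.dhs["enhancer_class"] == "stable"
        u = stats.mannwhitneyu(density.loc[down.to_numpy(), "GR"],
                               density.loc[stable.to_numpy(), "GR"]).statistic
        auc = u / (down.sum() * stable.sum())
        assert 0.45 < auc < 0.55


class TestSequences:
    def test_zero_planting_rate_gives_empty_hits(self):
        config = cfg(motif_planting_rate=0.0)
        seqs, pwms, hits = sim.generate_sequences_with_motifs(config)
        assert hits.empty and len(seqs) == config.n_dhs

    def test_planted_consensus_is_max_scoring_hit(self):
        config = cfg(n_dhs=50, motif_planting_rate=1.0)
        seqs, pwms, hits = sim.generate_sequences_with_motifs(config)
        pwm = pwms[0]
        planted = hits[hits["motif"] == pwm.motif_id].iloc[0]
        res = pwm_log_odds_scan(seqs[planted["dhs"]], pwm,
                                threshold=pwm.max_score - 1e-9)
        assert (res["hits"]["offset"] == planted["offset"]).any()
        assert res["best_score"] == pytest.approx(pwm.max_score)

    def test_gc_content_matches_config(self):
        config = SimulationConfig(seed=2, n_genes=200, n_dhs=2000,
                                  genome_length=200 * 12_000,
                                  gc_content=0.48, motif_planting_rate=0.0)
        seqs, _, _ = sim.generate_sequences_with_motifs(config)
        joined = "".join(seqs.values())
        gc = (joined.count("G") + joined.count("C")) / len(joined)
        assert abs(gc - 0.48) < 0.01


class TestMotifActivityDataset:
    def test_response_is_occurrence_times_activity_plus_noise(self):
        config = cfg()
        occ, y, beta = sim.generate_motif_activity_dataset(
            config, n_dhs=3000, noise_sd=0.3)
        fitted = occ.to_numpy() @ np.array([beta[m] for m in occ.columns])
        resid = y.to_numpy() - fitted
        assert abs(resid.mean()) < 0.05
        assert abs(resid.std() - 0.3) < 0.05
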