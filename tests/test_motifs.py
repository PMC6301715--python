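"""PWM scanning against a brute-force oracle, enrichment, per-cluster score
tests, and motif-activity regression recovery."""

import numpy as np
import pandas as pd
import pytest

from prandialreg.config import SimulationConfig
from prandialreg import simulate as sim
from prandialreg.motifs import (
    PWM,
    best_scores,
    cluster_motif_scores,
    empirical_background,
    motif_activity,
    motif_enrichment,
    pwm_log_odds_scan,
    read_jaspar,
    write_jaspar,
)

COMP = str.maketrans("ACGT", "TGCA")


def make_pwm(consensus="TGACGTCA", match_p=0.85, motif_id="M1"):
    probs = np.full((len(consensus), 4), (1 - match_p) / 3)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = match_p
    return PWM(motif_id=motif_id, probs=probs)


def brute_force_scan(seq, pwm, threshold):
    """Literal per-window log-odds computation, both strands."""
    lo = pwm.log_odds
    L = len(pwm)
    hits = []
    best = None
    for off in range(len(seq) - L + 1):
        win = seq[off: off + L]
        if "N" in win:
            continue
        fwd = sum(lo[i, "ACGT".index(b)] for i, b in enumerate(win))
        rc = win.translate(COMP)[::-1]
        rev = sum(lo[i, "ACGT".index(b)] for i, b in enumerate(rc))
        for strand, s in (("+", fwd), ("-", rev)):
            if s >= threshold:
                hits.append((off, strand, s))
            best = s if best is None else max(best, s)
    return hits, best


class TestPwmScan:
    def test_consensus_attains_max_score(self):
        pwm = make_pwm("TGACGTCA")
        res = pwm_log_odds_scan("TGACGTCA", pwm, threshold=-np.inf)
        assert res["best_score"] == pytest.approx(pwm.max_score)
        # hand computation including the pseudocount regularization
        p = (0.85 + pwm.pseudocount) / (1 + 4 * pwm.pseudocount)
        assert res["best_score"] == pytest.approx(8 * np.log2(p / 0.25))

    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PWM("U", np.full((6, 4), 0.25), pseudocount=0.0)
        res = pwm_log_odds_scan("ACGTACGTACGT", pwm, threshold=-np.inf)
        assert np.allclose(res["hits"]["score"], 0.0)

    def test_sequence_shorter_than_motif_flagged(self):
        res = pwm_log_odds_scan("ACG", make_pwm("TGACGTCA"), 0.0)
        assert res["flagged"] and res["best_score"] is None and res["hits"].empty

    def test_reverse_complement_hit_found(self):
        pwm = make_pwm("TGACGTCA")
        seq = "AAAA" + "TGACGTCA".translate(COMP)[::-1] + "AAAA"
        res = pwm_log_odds_scan(seq, pwm, threshold=pwm.max_score - 1e-9)
        assert ((res["hits"]["offset"] == 4) & (res["hits"]["strand"] == "-")).any()

    def test_windows_with_n_skipped(self):
        pwm = make_pwm("ACGT")
        res = pwm_log_odds_scan("ACNGT", pwm, threshold=-np.inf)
        assert (res["hits"]["offset"] == 1).sum() == 0

    @pytest.mark.parametrize("threshold", [-np.inf, 0.0, 5.0])
    def test_matches_brute_force_on_random_sequences(self, rng, threshold):
        pwm = make_pwm("TTGTTTAC")
        bases = np.array(list("ACGT"))
        for _ in range(20):
            seq = "".join(rng.choice(bases, size=200))
            got = pwm_log_odds_scan(seq, pwm, threshold)
            want_hits, want_best = brute_force_scan(seq, pwm, threshold)
            got_set = {(o, s, round(v, 9)) for o, s, v in
                       got["hits"].itertuples(index=False)}
            want_set = {(o, s, round(v, 9)) for o, s, v in want_hits}
            assert got_set == want_set
            assert got["best_score"] == pytest.approx(want_best)


class TestJasparIO:
    def test_round_trip_preserves_consensus_and_length(self, tmp_path):
        pwms = [make_pwm("TGACGTCA", motif_id="CREB"),
                make_pwm("TTGTTTAC", motif_id="FOXO")]
        path = tmp_path / "m.jaspar"
        write_jaspar(pwms, path)
        back = read_jaspar(path)
        assert [p.motif_id for p in back] == ["CREB", "FOXO"]
        for a, b in zip(pwms, back):
            assert a.consensus == b.consensus and len(a) == len(b)

    def test_empirical_background_composition(self):
        seqs = {"a": "AACC", "b": "GGTT"}
        assert np.allclose(empirical_background(seqs), 0.25)


class TestMotifEnrichment:
    def test_fully_planted_motif_is_extreme(self, rng):
        pwm = make_pwm("TGACGTCA")
        bases = np.array(list("ACGT"))

        def bg():
            return "".join(rng.choice(bases, size=100))

        target = {f"t{i}": bg()[:40] + "TGACGTCA" + bg()[:40] for i in range(100)}
        background = {f"b{i}": bg() for i in range(100)}
        res = motif_enrichment(target, background, [pwm], 0.9 * pwm.max_score)
        assert res.loc["M1", "pvalue"] < 1e-6
        assert res.loc["M1", "percent_target"] == 100.0

    def test_empty_pwm_set_gives_empty_result(self):
        assert motif_enrichment({"a": "ACGT"}, {"b": "ACGT"}, [], 0.0).empty


class TestClusterMotifScores:
    def test_shifted_cluster_detected(self, rng):
        scores = pd.Series(np.concatenate([
            rng.normal(0, 1, 200), rng.normal(0, 1, 200), rng.normal(5, 1, 200),
        ]), index=[f"d{i}" for i in range(600)])
        clusters = pd.Series([1] * 200 + [2] * 200 + [3] * 200, index=scores.index)
        res = cluster_motif_scores(scores, clusters)
        assert res["kruskal_p"] < 1e-6
        assert res["pairwise_p"].loc[3, 1] < 1e-4
        assert res["pairwise_p"].loc[3, 2] < 1e-4

    def test_identical_clusters_not_separated(self, rng):
        base = rng.normal(0, 1, 200)
        scores = pd.Series(np.concatenate([base, base, rng.normal(5, 1, 200)]),
                           index=[f"d{i}" for i in range(600)])
        clusters = pd.Series([1] * 200 + [2] * 200 + [3] * 200, index=scores.index)
        res = cluster_motif_scores(scores, clusters)
        assert res["pairwise_p"].loc[1, 2] > 0.9

    def test_pairwise_gated_by_omnibus(self, rng):
        scores = pd.Series(rng.normal(0, 1, 300), index=[f"d{i}" for i in range(300)])
        clusters = pd.Series(rng.choice([1, 2, 3], size=300), index=scores.index)
        res = cluster_motif_scores(scores, clusters)
        if res["kruskal_p"] >= 0.05:
            assert res["pairwise_p"].isna().all().all()


class TestMotifActivity:
    def test_perfect_single_motif_recovers_coefficient(self, rng):
        occ = pd.DataFrame({"M": rng.integers(0, 2, 500)},
                           index=[f"d{i}" for i in range(500)])
        y = pd.Series(-1.0 * occ["M"], index=occ.index)
        res = motif_activity(y, occ, ridge_lambda=1e-9, n_bootstrap=50)
        assert res.loc["M", "activity"] == pytest.approx(-1.0, abs=1e-6)

    def test_constant_column_flagged(self, rng):
        occ = pd.DataFrame({"M": rng.integers(0, 2, 100),
                            "C": np.ones(100, dtype=int)},
                           index=[f"d{i}" for i in range(100)])
        y = pd.Series(rng.normal(size=100), index=occ.index)
        res = motif_activity(y, occ, n_bootstrap=20)
        assert res.loc["C", "flagged"] and np.isnan(res.loc["C", "activity"])

    def test_null_motif_ci_covers_zero(self):
        covered = 0
        reps = 20
        for r in range(reps):
            config = SimulationConfig(seed=100 + r, n_genes=200,
                                      genome_length=200 * 12_000)
            occ, y, _ = sim.generate_motif_activity_dataset(
                config, n_dhs=400, n_decoys=3,
                activities={"NULLM": 0.0}, noise_sd=0.5)
            res = motif_activity(y, occ, n_bootstrap=100, seed=r)
            if res.loc["NULLM", "ci_low"] <= 0 <= res.loc["NULLM", "ci_high"]:
                covered += 1
        assert covered >= 0.9 * reps

    def test_planted_drivers_recovered_among_decoys(self):
        config = SimulationConfig(seed=42, n_genes=200,
                                  genome_length=200 * 12_000)
        occ, y, beta = sim.generate_motif_activity_dataset(
            config, n_dhs=2000, n_decoys=20,
            activities={"DRIVER_NEG": -1.0, "DRIVER_POS": 0.5})
        res = motif_activity(y, occ, n_bootstrap=100, seed=1)
        acts = res["activity"]
        assert acts["DRIVER_NEG"] < 0 < acts["DRIVER_POS"]
        assert acts.idxmin() == "DRIVER_NEG"
        assert acts.idxmax() == "DRIVER_POS"
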