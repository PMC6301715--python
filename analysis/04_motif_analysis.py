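#!/usr/bin/env python
"""Which transcription-factor motifs explain feeding-regulated enhancers?

Scores every DHS sequence with each PWM (best log2-odds window over both
strands, background = base composition of randomly sampled DHSs), tests
motif enrichment in feeding-reduced DHSs against that sampled background,
compares GRE scores across the four enhancer clusters (Kruskal-Wallis +
pairwise Mann-Whitney), and fits the motif-activity ridge regression of
acetylation change on motif occurrence.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from prandialreg.config import SimulationConfig
from prandialreg.enhancers import differential_acetylation
from prandialreg.motifs import (
    best_scores,
    cluster_motif_scores,
    empirical_background,
    motif_activity,
    motif_enrichment,
)
from prandialreg.simulate import simulate_all

OUT = Path("results/motifs")
SCORE_FRACTION = 0.75  # hit threshold as a fraction of each PWM's max score


def main() -> None:
    config = SimulationConfig.from_yaml("results/sim/sim_config.yaml")
    cohort = simulate_all(config, include_hormone_arms=True, include_obese=True)
    OUT.mkdir(parents=True, exist_ok=True)

    ac = differential_acetylation(cohort.ac_counts, "ZT14_unfed", "ZT14_fed", 0.1)
    seqs = cohort.sequences
    rng = np.random.default_rng(config.seed)
    bg_ids = rng.choice(sorted(seqs), size=min(2000, len(seqs) // 2), replace=False)
    background = {i: seqs[i] for i in bg_ids}
    comp = empirical_background(background)
    print(f"background: {len(background)} sampled DHSs, "
          f"GC {100 * (comp[1] + comp[2]):.1f}%")
    pwms = [p.with_background(comp) for p in cohort.pwms]

    target = {i: seqs[i] for i in ac["down"] if i in seqs}
    rows = [motif_enrichment(target, background, [p], SCORE_FRACTION * p.max_score)
            for p in pwms]
    enrich = pd.concat(rows).sort_values("pvalue")
    enrich.to_csv(OUT / "motif_enrichment.tsv", sep="\t", float_format="%.6g")
    print("top motifs in feeding-reduced DHSs (percent target / background, p):")
    for m, r in enrich.head(4).iterrows():
        print(f"  {m:8s} {r['percent_target']:5.1f}% / "
              f"{r['percent_background']:5.1f}%  p={r['pvalue']:.2e}")

    scores = pd.DataFrame({p.motif_id: best_scores(seqs, p) for p in pwms})
    scores.to_csv(OUT / "best_scores.tsv", sep="\t", float_format="%.6g")
    truth_cls = cohort.truth.dhs["enhancer_class"]
    kw = cluster_motif_scores(scores["GRE"], truth_cls)
    print(f"GRE score across enhancer classes: Kruskal-Wallis p={kw['kruskal_p']:.2e}")
    kw["pairwise_p"].to_csv(OUT / "gre_class_pairwise_p.tsv", sep="\t",
                            float_format="%.6g")

    occurrence = pd.DataFrame({
        p.motif_id: (scores[p.motif_id] >= SCORE_FRACTION * p.max_score).astype(int)
        for p in pwms
    })
    fc = ac["diff"]["log2fc"].dropna()
    common = occurrence.index.intersection(fc.index)
    act = motif_activity(fc.loc[common], occurrence.loc[common], seed=config.seed)
    act.to_csv(OUT / "motif_activity.tsv", sep="\t", float_format="%.6g")
    ranked = act.dropna(subset=["activity"]).sort_values("activity")
    print("most negative motif activities (motif, activity, p):")
    for m, r in ranked.head(3).iterrows():
        print(f"  {m:8s} {r['activity']:+.3f}  p={r['pvalue']:.3f}")
    print(f"wrote tables to {OUT}/")


if __name__ == "__main__":
    main()
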