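#!/usr/bin/env python
"""Generate the synthetic liver cohort that every downstream analysis uses.

Writes all pipeline inputs (gene annotation, RNA-seq / H3K27Ac / DNase
counts, TF peak sets, enhancer sequences, PWMs, ground truth) as plain-text
files under results/sim/. The config written alongside lets every later
script regenerate the identical cohort from the same seed.
"""

from pathlib import Path

from prandialreg.config import SimulationConfig
from prandialreg.simulate import simulate_all, write_outputs

SEED = 20180712  # cohort seed shared by all analysis scripts


def main() -> None:
    config = SimulationConfig(seed=SEED, n_genes=2000, n_dhs=3000)
    cohort = simulate_all(config, include_hormone_arms=True, include_obese=True)
    outdir = Path("results/sim")
    paths = write_outputs(cohort, outdir)
    truth = cohort.truth
    print(f"simulated {len(truth.genes)} genes and {len(truth.dhs)} DHSs")
    print("gene classes:", truth.genes["gene_class"].value_counts().to_dict())
    print("enhancer classes:", truth.dhs["enhancer_class"].value_counts().to_dict())
    print(f"wrote {len(paths)} input files to {outdir}/")


if __name__ == "__main__":
    main()
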