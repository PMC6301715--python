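"""Simulation and pipeline run configuration.

All randomness flows from one master seed; each stage draws from a named
substream (``numpy.random.SeedSequence(seed).spawn`` keyed by stage name)
so toggling one stage never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

GENE_CLASSES = ("clock_driven", "feeding_driven", "mixed", "null")
ENHANCER_CLASSES = ("feeding_up", "feeding_down", "clock", "stable")
HORMONE_CLUSTERS = (1, 2, 3, 4, 5)

# substream ids, fixed so every stage is reproducible in isolation
_STREAMS = (
    "annotation", "classes", "expression", "circadian", "enhancers",
    "tf_peaks", "sequences", "hormone", "obese", "activity",
)


def _check_fractions(name: str, mapping: dict) -> None:
    total = float(sum(mapping.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} fractions must sum to 1, got {total}")
    if any(v < 0 for v in mapping.values()):
        raise ValueError(f"{name} fractions must be non-negative")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic liver cohort.

    Defaults encode the experimental design being emulated: three conditions
    (ZT10, ZT14-fed, ZT14-unfed) with 3 replicates, hormone arms with 4
    replicates, 4-fold planted feeding/clock effects on genes
    (``effect_size_log2fc`` = 2), 2-fold effects on enhancer acetylation,
    NB dispersion 0.05, and 48% GC enhancer sequences.
    """

    seed: int = 0
    n_genes: int = 2000
    n_dhs: int = 3000
    n_replicates: int = 3
    hormone_replicates: int = 4
    genome_length: int = 100_000_000
    class_proportions: dict = field(default_factory=lambda: {
        "clock_driven": 0.15, "feeding_driven": 0.15, "mixed": 0.10, "null": 0.60,
    })
    enhancer_class_proportions: dict = field(default_factory=lambda: {
        "feeding_up": 0.06, "feeding_down": 0.08, "clock": 0.06, "stable": 0.80,
    })
    effect_size_log2fc: float = 2.0
    enhancer_effect_log2fc: float = 1.0
    enhancer_effect_jitter_sd: float = 0.3
    dispersion: float = 0.05
    baseline_mean: float = 200.0
    coupling_distance: int = 50_000
    motif_planting_rate: float = 0.30
    hormone_cluster_proportions: dict = field(default_factory=lambda: {
        1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2, 5: 0.2,
    })
    dnase_ac_coupling: float = 0.8
    tf_separation: float = 2.0       # log-sd units between feeding_down and stable
    tf_overlap_fraction: float = 0.6  # fraction of factor-B sites co-bound by A
    gc_content: float = 0.48
    dhs_seq_length: int = 400
    dhs_width: int = 200
    circadian_amplitude: float = 0.5  # relative cosine amplitude of rhythmic genes
    circadian_cv: float = 0.2         # lognormal noise CV on the circadian series
    obese_blunted_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("n_genes", "n_dhs", "n_replicates", "hormone_replicates",
                     "genome_length", "coupling_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if not 0 <= self.motif_planting_rate <= 1:
            raise ValueError("motif_planting_rate must be a fraction")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        self.class_proportions = {k: float(v) for k, v in self.class_proportions.items()}
        self.hormone_cluster_proportions = {
            int(k): float(v) for k, v in self.hormone_cluster_proportions.items()
        }
        _check_fractions("class_proportions", self.class_proportions)
        _check_fractions("enhancer_class_proportions", self.enhancer_class_proportions)
        _check_fractions("hormone_cluster_proportions", self.hormone_cluster_proportions)
        if set(self.class_proportions) != set(GENE_CLASSES):
            raise ValueError(f"class_proportions must have keys {GENE_CLASSES}")
        if set(self.enhancer_class_proportions) != set(ENHANCER_CLASSES):
            raise ValueError(f"enhancer_class_proportions must have keys {ENHANCER_CLASSES}")
        if set(self.hormone_cluster_proportions) != set(HORMONE_CLUSTERS):
            raise ValueError("hormone_cluster_proportions must have keys 1..5")
        if self.genome_length < self.n_genes * 10_000:
            raise ValueError(
                f"genome_length ({self.genome_length}) must be at least "
                f"n_genes x 10 kb ({self.n_genes * 10_000})"
            )

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream of the master seed."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown stream {stream!r}; known: {_STREAMS}")
        idx = _STREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence((self.seed, idx)))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunConfig:
    """Thresholds and paths for an end-to-end pipeline run."""

    outdir: str = "results/pipeline"
    seed: int = 0
    gene_fdr: float = 0.01
    ac_fdr: float = 0.1
    hormone_fdr: float = 0.05
    window_bp: int = 800
    proximity_bp: int = 50_000
    enhancer_clusters: int = 4
    hormone_clusters: int = 5
    dex_bins: int = 3
    obesity_clusters: int = 8
    n_random_sets: int = 6
    random_set_size: int = 300
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict = field(default_factory=lambda: {
        "feeding": True, "enhancers": True, "motifs": True,
        "occupancy": True, "hormone": True,
    })

    def __post_init__(self) -> None:
        for name in ("gene_fdr", "ac_fdr", "hormone_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("window_bp", "proximity_bp", "enhancer_clusters",
                     "hormone_clusters", "dex_bins", "obesity_clusters",
                     "n_random_sets", "random_set_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if self.simulation.seed != self.seed:
            self.simulation.seed = self.seed
            self.simulation.__post_init__()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
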