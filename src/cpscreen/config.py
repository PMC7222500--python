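"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    The defaults describe the simulated analogue of the real screen: two
    three-vs-three microarray contrasts with a pool of "plasticity brake"
    genes downregulated in both, a chemical--gene interaction table in which
    a minority of chemicals preferentially up-regulate those brake genes,
    pathway gene sets overlapping the disruptors' genes, an activated
    microglia set, and exposure-risk labels biased toward one planted
    cluster.

    Parameters
    ----------
    n_genes : int
        Size of the gene universe.
    n_samples_per_group : int
        Replicates per group in each expression contrast.
    n_brake_genes : int
        Genes shifted down in the test group of both contrasts.
    effect_size : float
        Mean log2 shift of planted differentially expressed genes.
    noise_sd : float
        Within-group Gaussian standard deviation.
    n_chemicals : int
        Chemicals in the interaction table.
    n_planted_disruptors : int
        Chemicals whose up-regulated genes are drawn preferentially
        from the brake pool.
    disruptor_overlap_frac : float
        Fraction of a planted chemical's up-genes taken from brake genes.
    chem_set_size_range : (int, int)
        Inclusive bounds on genes per chemical per direction.
    n_pathways : int
        Pathway gene sets emitted.
    n_planted_pathways : int
        Pathways built to overlap the disruptors' up-genes.
    exposure_bias : float
        Probability a planted cluster-B chemical is labeled medium/high.
    microglia_set_size : int
        Size of the activated-microglia gene set.
    seed : int
        Master seed; each artifact derives its own stream (seed + offset).
    """

    n_genes: int = 2000
    n_samples_per_group: int = 3
    n_brake_genes: int = 200
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_chemicals: int = 300
    n_planted_disruptors: int = 30
    disruptor_overlap_frac: float = 0.6
    chem_set_size_range: Tuple[int, int] = (5, 100)
    n_pathways: int = 250
    n_planted_pathways: int = 15
    exposure_bias: float = 0.7
    microglia_set_size: int = 72
    seed: int = 0

    # Secondary shape parameters (fixed design choices, see docs/methods.md).
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    pathway_size_range: Tuple[int, int] = (10, 60)
    planted_pathway_size_range: Tuple[int, int] = (40, 80)
    planted_pathway_overlap_frac: float = 0.8
    cluster_b_frac: float = 0.6
    background_exposure_rate: float = 0.35
    distractor_frac: float = 0.02
    noref_frac: float = 0.02
    microglia_planted_frac: float = 0.7

    def __post_init__(self) -> None:
        positive = {
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_brake_genes": self.n_brake_genes,
            "n_chemicals": self.n_chemicals,
            "n_planted_disruptors": self.n_planted_disruptors,
            "n_pathways": self.n_pathways,
            "n_planted_pathways": self.n_planted_pathways,
            "microglia_set_size": self.microglia_set_size,
        }
        for name, value in positive.items():
            if int(value) != value or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        for name, value in (
            ("disruptor_overlap_frac", self.disruptor_overlap_frac),
            ("exposure_bias", self.exposure_bias),
            ("planted_pathway_overlap_frac", self.planted_pathway_overlap_frac),
            ("cluster_b_frac", self.cluster_b_frac),
            ("background_exposure_rate", self.background_exposure_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        if self.n_planted_disruptors >= self.n_chemicals:
            raise ConfigError("n_planted_disruptors must be < n_chemicals")
        if self.n_brake_genes >= self.n_genes:
            raise ConfigError("n_brake_genes must be < n_genes")
        if self.n_planted_pathways > self.n_pathways:
            raise ConfigError("n_planted_pathways must be <= n_pathways")
        lo, hi = self.chem_set_size_range
        if lo < 3:
            raise ConfigError(
                "chem_set_size_range lower bound must be >= 3 so planted sets "
                "survive the minimum-size library filter"
            )
        if lo > hi:
            raise ConfigError("chem_set_size_range must be (low, high) with low <= high")
        if hi >= self.n_genes:
            raise ConfigError("chemical set sizes must be smaller than the gene universe")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.n_samples_per_group < 2:
            raise ConfigError("each group needs at least 2 samples")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("chem_set_size_range", "pathway_size_range", "planted_pathway_size_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunConfig:
    """One end-to-end pipeline run: thresholds, toggles, seeds and paths."""

    out_dir: Path = Path("cpscreen_run")
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    simulate: bool = True

    # Significance thresholds (screening defaults).
    p_threshold: float = 0.05
    fdr_threshold: float = 0.25
    alpha: float = 0.05
    min_set_size: int = 3
    n_perm: int = 1000

    # Design-decision toggles.
    ranking_statistic: str = "t"          # "t" (pooled, floored) or "diff"
    weight_exponent: float = 1.0          # GSEA weighting; 0 for classic KS
    updown_null: str = "library"          # "library" or "half"
    linkage: str = "ward_d"               # "ward_d" or "ward_d2"
    n_clusters: int = 2
    bh_scope: str = "global"              # "global" or "per_chemical"
    microglia_universe_size: Optional[int] = None  # default: signature universe

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name, value in (
            ("p_threshold", self.p_threshold),
            ("fdr_threshold", self.fdr_threshold),
            ("alpha", self.alpha),
        ):
            if not 0.0 < value <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1], got {value!r}")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.min_set_size < 1:
            raise ConfigError("min_set_size must be >= 1")
        if self.ranking_statistic not in ("t", "diff"):
            raise ConfigError("ranking_statistic must be 't' or 'diff'")
        if self.updown_null not in ("library", "half"):
            raise ConfigError("updown_null must be 'library' or 'half'")
        if self.linkage not in ("ward_d", "ward_d2"):
            raise ConfigError("linkage must be 'ward_d' or 'ward_d2'")
        if self.bh_scope not in ("global", "per_chemical"):
            raise ConfigError("bh_scope must be 'global' or 'per_chemical'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)
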