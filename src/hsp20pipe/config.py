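"""Parameter containers: simulation settings and the pipeline-wide config.

Every numeric threshold used by the stages lives in :class:`PipelineConfig`
so a run is fully described by one serializable object plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SimulationParams:
    """Settings of the synthetic genome/expression generator.

    The defaults describe the study conditions exercised throughout the test
    suite: a 40-member family among 60 decoys, nine tandem and six
    segmental duplicate pairs, half the promoters carrying a heat-shock
    element with an odds ratio of 8 towards up-regulation, and three
    expression archetypes.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length_bp: int = 200_000
    n_family_genes: int = 40
    n_decoy_genes: int = 60
    n_tandem_pairs: int = 9
    n_segmental_pairs: int = 6
    domain_length_aa: int = 90
    domain_mutation_rate: float = 0.1
    hse_planting_rate: float = 0.5
    hse_upregulation_odds_ratio: float = 8.0
    # baseline probability that a promoter WITHOUT an HSE is up-regulated;
    # with an HSE the odds are multiplied by hse_upregulation_odds_ratio
    upregulation_base_rate: float = 0.25
    expression_noise_sd: float = 0.1
    group_proportions: tuple = (0.60, 0.25, 0.15)

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length_bp": self.chromosome_length_bp,
            "n_family_genes": self.n_family_genes,
            "n_decoy_genes": self.n_decoy_genes,
            "n_tandem_pairs": self.n_tandem_pairs,
            "n_segmental_pairs": self.n_segmental_pairs,
            "domain_length_aa": self.domain_length_aa,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in (
            "domain_mutation_rate",
            "hse_planting_rate",
            "upregulation_base_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.hse_upregulation_odds_ratio <= 0:
            raise ValueError("hse_upregulation_odds_ratio must be positive")
        if self.expression_noise_sd < 0:
            raise ValueError("expression_noise_sd must be >= 0")
        self.group_proportions = tuple(float(p) for p in self.group_proportions)
        if len(self.group_proportions) != 3:
            raise ValueError("group_proportions needs exactly 3 fractions")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if 2 * (self.n_tandem_pairs + self.n_segmental_pairs) > self.n_family_genes:
            raise ValueError(
                "tandem and segmental pairs need "
                f"{2 * (self.n_tandem_pairs + self.n_segmental_pairs)} family genes "
                f"but n_family_genes={self.n_family_genes}"
            )


@dataclass
class PipelineConfig:
    """All stage thresholds plus paths; round-trips losslessly through YAML."""

    seed: int = 0
    outdir: str = "pipeline_out"
    # identification
    e_value_first_pass: float = 0.01
    e_value_strict: float = 1e-20
    mw_min_kda: float = 12.0
    mw_max_kda: float = 42.0
    family_name_prefix: str = "HSP20"
    calibration_n: int = 500
    seed_alignment_path: str = ""  # empty: use the built-in synthetic seed
    # duplication / synteny
    blast_e_value: float = 1e-10
    min_anchors: int = 5
    max_rank_gap: int = 25
    cscore_min: float = 0.70
    # phylogeny
    bootstrap_replicates: int = 1000
    # promoters / expression
    promoter_window: int = 1500
    n_expression_groups: int = 3
    upregulation_z_threshold: float = 1.0
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def __post_init__(self) -> None:
        for name in (
            "e_value_first_pass",
            "e_value_strict",
            "blast_e_value",
            "mw_min_kda",
            "mw_max_kda",
            "cscore_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_anchors", "max_rank_gap", "bootstrap_replicates",
                     "promoter_window", "n_expression_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mw_min_kda > self.mw_max_kda:
            raise ValueError("mw_min_kda must not exceed mw_max_kda")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationParams(**self.simulation)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["simulation"]["group_proportions"] = list(
            d["simulation"]["group_proportions"]
        )
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)
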