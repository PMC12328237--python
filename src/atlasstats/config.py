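"""Analysis configuration: every stage threshold with its atlas default."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """All tunable thresholds, defaulting to the published atlas settings.

    splicing_*:    cell-type/junction/gene filters and the corrected-P call
                   threshold of the differential-splicing stage.
    chemokine_*:   absolute (fraction, mean) filter, ceiling percentile and
                   relative receptor/ligand thresholds.
    nmd_*:         qualifying-cell-type filters and the regime tolerance.
    de_*:          the three marker criteria.
    conservation_*: E_max filter levels and the expression-homologue
                   correlation threshold.
    """

    seed: int = 0
    out_dir: str = "results"
    # only droplet cells enter quantitative stages unless flagged
    include_plate_cells: bool = False
    remove_doublets: bool = False

    splicing_min_cells_per_type: int = 10
    splicing_min_cells_per_junction: int = 2
    splicing_min_gene_reads_per_type: int = 2
    splicing_alpha: float = 1e-16
    splicing_statistic: str = "pillai"  # or "wilks"

    chemokine_min_fraction: float = 0.05
    chemokine_min_mean: float = 0.5
    chemokine_ceiling_percentile: float = 99.0
    chemokine_receptor_rel: float = 0.05
    chemokine_ligand_rel: float = 0.20

    nmd_min_cells_per_type: int = 35
    nmd_min_wt_mean: float = 0.3
    nmd_regime_tol: float = 0.10
    nmd_last_exon_escape_max_depletion: float = 0.5
    nmd_ratio_scale: str = "linear"  # or "log"

    de_alpha: float = 0.05
    de_min_fraction: float = 0.25
    de_min_ratio: float = math.exp(0.5)  # 1.6487: e^0.5-fold over rest of tissue
    de_ratio_scale: str = "log"  # or "linear"

    conservation_emax_each: float = 0.5
    conservation_emax_floor: float = 0.1
    conservation_emax_high: float = 1.5
    conservation_corr_threshold: float = 0.3

    def validate(self) -> "AnalysisConfig":
        for key, value in asdict(self).items():
            if isinstance(value, float) and not math.isfinite(value):
                raise ValueError(f"config field {key} is not finite")
        if self.splicing_statistic not in {"pillai", "wilks"}:
            raise ValueError("splicing_statistic must be 'pillai' or 'wilks'")
        if self.de_ratio_scale not in {"log", "linear"}:
            raise ValueError("de_ratio_scale must be 'log' or 'linear'")
        if self.nmd_ratio_scale not in {"log", "linear"}:
            raise ValueError("nmd_ratio_scale must be 'log' or 'linear'")
        return self

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
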