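"""Run configuration: every pipeline threshold with its default value.

Defaults mirror the published analysis settings: 2,500-bp downstream-of-gene
(DoG) window, log2(1.25) zone cutoff, input minimum of 5 reads per 1-kb bin,
moving-average half-width m = 10, +/-10 background band, 60-kb / 70%-reduction
wave filters.  A config round-trips losslessly through YAML.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results"

    # coverage geometry
    bin_width: int = 25
    rate_bin_width: int = 1000

    # termination / pausing / metagene
    dog_length: int = 2500
    pause_window: int = 300
    delta_ti_threshold: float = 0.5
    library_norm_per: float = 1e8
    ei_bins: int = 40
    metagene_body_bins: int = 400
    metagene_flank_bin_width: int = 10
    metagene_up_bins: int = 250
    metagene_down_bins: int = 250

    # gene universe filters
    min_expression: float = 1.0
    min_separation: int = 2500
    min_gene_length: int = 2000
    min_density: float = 50.0

    # replication-initiation zones
    pa_cutoff_log2: float = math.log2(1.25)
    ri_score_min: float = 10.0
    ri_fold_min: float = 2.0

    # elongation rate
    wave_min_length: int = 60000
    wave_proximal_start: int = 1000
    wave_proximal_end: int = 20000
    wave_min_reduction: float = 0.70
    replicate_max_discrepancy: int = 2000

    # BrdU replication pipeline
    brdu_bin_width: int = 1000
    brdu_min_input: int = 5
    brdu_smooth_m: int = 10
    brdu_background: float = 10.0
    brdu_dog_start: int = 2500
    brdu_dog_end: int = 5000

    # synthetic scenario overrides (merged into SimulationScenario defaults)
    scenario: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        for name in ("bin_width", "rate_bin_width", "brdu_bin_width",
                     "dog_length", "pause_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")
        if not 0 <= self.wave_min_reduction <= 1:
            raise ValueError("config: wave_min_reduction must be in [0, 1]")
        if self.brdu_min_input < 0 or self.brdu_smooth_m < 0:
            raise ValueError("config: BrdU parameters must be non-negative")
        return self

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data).validate()
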