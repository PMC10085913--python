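"""Pipeline configuration.

Every numeric constant used by the genotyping, MLPA, census and
expression stages lives here, so a run is fully described by one
config object plus one seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Tunable parameters of the copy-number pipeline.

    Attributes
    ----------
    flank:
        Extension (bp) added to each side of a genotyping region's core
        span before depth is collected. Default 300 bp.
    k, step:
        Window length and stride of the genome uniqueness mask.
        Positions covered by any ``k``-mer occurring at least twice
        genome-wide (either strand) are excluded from depth estimation.
    loss_threshold, gain_threshold:
        Unrounded copy-number cut-offs: ``cn < loss_threshold`` is a
        loss, ``cn >= gain_threshold`` a gain (diploid baseline 2.0).
    ref_cn_bounds, pop_mean_bounds, iqr_max:
        Region filters: the reference accession's CN and the population
        mean CN must fall inside their bounds, and the across-accession
        interquartile range must not exceed ``iqr_max``.
    min_callable_bp:
        Minimum unmasked span for a region to be genotyped at all;
        below it the region is reported as failed.
    mlpa_del, mlpa_dup:
        Normalized MLPA ratio thresholds: ``ratio < mlpa_del`` is a
        deletion, ``ratio > mlpa_dup`` a duplication.
    mlpa_noise_floor:
        Fraction of a sample's mean control signal below which a raw
        probe signal is reported as ``no_signal``.
    mlpa_rescale:
        Divide each probe column by its across-sample median after
        control normalization so the two-copy state sits at 1.0.
    r_threshold:
        |Pearson r| at or above which a CN-expression pair is flagged.
    min_pair_n:
        Minimum number of pairwise-complete accessions for a reported r.
    census_min_identity, census_min_coverage, census_seed_k:
        Homology-census thresholds: identity floor, query-coverage
        floor, and exact-seed length for the seed-and-extend scan.
    per_chromosome_norm:
        Normalize accession depth per chromosome instead of genome-wide.
    seed:
        Seed for every random component of a run.
    """

    flank: int = 300
    k: int = 40
    step: int = 1
    loss_threshold: float = 0.3
    gain_threshold: float = 4.0
    ref_cn_bounds: tuple[float, float] = (1.0, 3.0)
    pop_mean_bounds: tuple[float, float] = (1.0, 3.0)
    iqr_max: float = 1.0
    min_callable_bp: int = 100
    mlpa_del: float = 0.5
    mlpa_dup: float = 2.0
    mlpa_noise_floor: float = 0.02
    mlpa_rescale: bool = True
    r_threshold: float = 0.3
    min_pair_n: int = 30
    census_min_identity: float = 0.97
    census_min_coverage: float = 1.0
    census_seed_k: int = 12
    per_chromosome_norm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss_threshold <= 0 or self.gain_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (self.loss_threshold < 2.0 < self.gain_threshold):
            raise ValueError(
                "loss_threshold must be below and gain_threshold above the "
                "diploid baseline of 2.0"
            )
        self.ref_cn_bounds = tuple(self.ref_cn_bounds)
        self.pop_mean_bounds = tuple(self.pop_mean_bounds)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ref_cn_bounds"] = list(self.ref_cn_bounds)
        d["pop_mean_bounds"] = list(self.pop_mean_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
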