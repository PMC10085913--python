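"""End-to-end drivers tying the stages together.

``run_genotyping`` runs mask -> CN estimation -> filters -> calls ->
variability on a synthetic study (or any equivalent bundle of inputs)
and returns every intermediate, so analysis scripts, tests and the
acceptance checks all execute the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genotyping, mask as mask_mod
from .annotation import MirLocus
from .config import PipelineConfig
from .genotyping import CopyNumberMatrix, GenotypeRegion
from .mask import UniquenessMask
from .synthetic import SyntheticStudy


@dataclass
class GenotypingResult:
    mask: UniquenessMask
    regions: list[GenotypeRegion]
    cn_raw: CopyNumberMatrix
    cn: CopyNumberMatrix          # after population filters
    calls: pd.DataFrame
    variability: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    tallies: dict

    def concordance_with(self, expected_states: pd.DataFrame) -> float:
        """Fraction of calls matching a truth state table."""
        merged = self.calls.merge(
            expected_states.stack().rename("expected").rename_axis(
                ["region_id", "accession_id"]).reset_index(),
            on=["region_id", "accession_id"], how="inner",
        )
        if merged.empty:
            raise ValueError("no overlapping region/accession pairs")
        return float((merged["state"] == merged["expected"]).mean())


def run_genotyping(
    study: SyntheticStudy,
    config: PipelineConfig | None = None,
    accession_groups: Mapping[str, str] | None = None,
) -> GenotypingResult:
    config = config or study.config
    genome_mask = mask_mod.build_uniqueness_mask(study.genome, k=config.k,
                                                 step=config.step)
    cn_raw = genotyping.genotype_cohort(
        study.regions, genome_mask, study.depth_source(),
        accessions=list(study.cn_truth.columns),
        reference_accession=study.reference_accession, config=config,
    )
    cn = genotyping.filter_regions(cn_raw, config)
    calls = genotyping.call_genotypes(cn, config)
    variability = genotyping.classify_variability(calls, study.regions, cn)
    groups = dict(accession_groups or study.groups)
    summaries = genotyping.summarize(calls, study.mirs, study.regions,
                                     variability, groups)
    tallies = genotyping.filter_tallies(cn, study.regions)
    return GenotypingResult(
        mask=genome_mask, regions=study.regions, cn_raw=cn_raw, cn=cn,
        calls=calls, variability=variability, summaries=summaries,
        tallies=tallies,
    )
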