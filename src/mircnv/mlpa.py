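"""MLPA signal normalization, CNV calling and read-depth concordance.

Multiplex ligation-dependent probe amplification reads copy number
from probe signal ratios. Each sample's probe signals are normalized
to the mean of its three control probes; by default each probe column
is then divided by its across-sample median so the two-copy state
sits at 1.0 (a per-sample control normalization alone leaves probe-
specific amplification efficiency in the ratio). Ratios below 0.5
call deletions, above 2.0 duplications; raw signals below a noise
floor (default 2% of the sample's mean control signal) are reported
as ``no_signal`` — a fully deleted or diverged probe site produces no
ligation product at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig

MLPA_STATES = ("deletion", "normal", "duplication", "no_signal")


@dataclass
class MlpaRun:
    """One MLPA experiment.

    ``raw`` is samples x probes signal intensity; ``probe_design`` has
    one row per probe with ``probe``, ``target_mir`` and ``is_control``
    columns (exactly three control probes).
    """

    raw: pd.DataFrame
    probe_design: pd.DataFrame
    normalized: pd.DataFrame | None = None
    calls: pd.DataFrame | None = None
    invalid_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        design = self.probe_design.set_index("probe") \
            if self.probe_design.index.name != "probe" else self.probe_design
        self.probe_design = design
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("raw signals must be nonnegative")
        controls = self.control_probes
        if len(controls) != 3:
            raise ValueError(f"expected exactly 3 control probes, got {len(controls)}")
        missing = set(self.probe_design.index) - set(self.raw.columns)
        if missing:
            raise ValueError(f"probes missing from signal table: {sorted(missing)}")

    @property
    def control_probes(self) -> list[str]:
        return list(self.probe_design.index[self.probe_design["is_control"].astype(bool)])

    @property
    def target_probes(self) -> list[str]:
        return list(self.probe_design.index[~self.probe_design["is_control"].astype(bool)])


def normalize_mlpa(run: MlpaRun, rescale: bool = True) -> MlpaRun:
    """Normalize raw signals to per-sample control means.

    normalized[s, p] = raw[s, p] / mean(controls of sample s); with
    ``rescale`` each probe column is then divided by its across-sample
    median. Samples with zero mean control signal are flagged invalid
    and excluded from calling.
    """
    control_mean = run.raw[run.control_probes].mean(axis=1)
    invalid = list(control_mean.index[control_mean <= 0])
    valid = control_mean.index.difference(invalid, sort=False)
    normalized = run.raw.loc[valid].div(control_mean.loc[valid], axis=0)
    if rescale:
        medians = normalized.median(axis=0)
        # a probe dead in every sample (median 0) cannot be rescaled
        medians = medians.replace(0.0, np.nan)
        normalized = normalized.div(medians, axis=1)
    run.normalized = normalized
    run.invalid_samples = invalid
    return run


def call_mlpa(run: MlpaRun, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Threshold normalized ratios into MLPA calls.

    deletion if ratio < ``mlpa_del``; duplication if ratio >
    ``mlpa_dup``; ``no_signal`` if the raw signal falls below
    ``mlpa_noise_floor`` x the sample's mean control signal; else
    normal. Control probes are never called. Returns long-format rows
    ``sample, probe, target_mir, ratio, call``.
    """
    config = config or PipelineConfig()
    if run.normalized is None:
        raise ValueError("run must be normalized before calling")
    control_mean = run.raw[run.control_probes].mean(axis=1)
    rows = []
    for sample in run.normalized.index:
        floor = config.mlpa_noise_floor * control_mean[sample]
        for probe in run.target_probes:
            raw = run.raw.loc[sample, probe]
            ratio = run.normalized.loc[sample, probe]
            if raw < floor or np.isnan(ratio):
                call = "no_signal"
            elif ratio < config.mlpa_del:
                call = "deletion"
            elif ratio > config.mlpa_dup:
                call = "duplication"
            else:
                call = "normal"
            rows.append({
                "sample": sample, "probe": probe,
                "target_mir": run.probe_design.loc[probe, "target_mir"],
                "ratio": ratio, "call": call,
            })
    calls = pd.DataFrame(rows)
    run.calls = calls
    return calls


GENOTYPE_STATES = ("loss", "normal", "gain")
_CONCORDANT = {("loss", "deletion"), ("normal", "normal"), ("gain", "duplication")}


def concordance(
    mlpa_calls: pd.DataFrame,
    genotype_calls: pd.DataFrame,
    mir_to_region: dict[str, str],
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate MLPA against read-depth genotype calls.

    ``mir_to_region`` maps each probe's target MIR to the genotyping
    region carrying the read-depth call. Returns the 3x4 confusion
    table (genotype state x MLPA call) and the agreement rate: the
    fraction of concordant pairs among samples with MLPA signal.
    """
    geno = genotype_calls.set_index(["region_id", "accession_id"])["state"]
    pairs = []
    for _, row in mlpa_calls.iterrows():
        region = mir_to_region.get(row["target_mir"])
        if region is None:
            continue
        key = (region, row["sample"])
        if key in geno.index:
            pairs.append((geno.loc[key], row["call"]))
    if not pairs:
        raise ValueError("no shared accessions between MLPA and genotype calls")
    table = pd.DataFrame(0, index=list(GENOTYPE_STATES), columns=list(MLPA_STATES))
    for g, m in pairs:
        table.loc[g, m] += 1
    with_signal = [(g, m) for g, m in pairs if m != "no_signal"]
    agree = sum((g, m) in _CONCORDANT for g, m in with_signal)
    rate = agree / len(with_signal) if with_signal else float("nan")
    return table, rate
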