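"""Population read-depth copy-number genotyping.

The pipeline estimates an unrounded copy number (CN, diploid baseline
2.0) for each genotyping region in each accession from per-base read
depth over unmasked positions, removes regions with untrustworthy
population distributions, and thresholds the surviving estimates into
loss / normal / gain calls.

Genotyping regions are the connected components of the pairwise
overlap graph of stem-loop loci (overlapping precursors share depth
signal and cannot be separated), with the union span extended by a
flank (default 300 bp) on each side for better short-read coverage.

The CN estimator is a deliberately simple normalized mean-depth
ratio: CN = 2 * mean(depth over unmasked region positions) /
accession mean depth. Downstream filtering and calling depend only on
unrounded estimates, not on how they were produced, so any external
estimator's matrix can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import MirLocus
from .config import PipelineConfig
from .mask import UniquenessMask

STATUS_OK = "ok"
STATUS_FAILED = "failed"


@dataclass
class GenotypeRegion:
    """One genotyping unit: a maximal group of mutually overlapping loci."""

    region_id: str
    member_mir_ids: list[str]
    chrom: str
    core_start: int
    core_end: int
    ext_start: int
    ext_end: int
    flank: int

    def __post_init__(self) -> None:
        if not (self.ext_start <= self.core_start < self.core_end <= self.ext_end):
            raise ValueError(f"{self.region_id}: inconsistent core/extended spans")


def group_and_define_regions(
    mirs: Sequence[MirLocus],
    flank: int = 300,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenotypeRegion]:
    """Group overlapping loci and extend the union span by ``flank``.

    Grouping uses the unextended stem-loop coordinates: two loci land
    in one region iff they share at least one base pair, transitively.
    Because interval-overlap components are contiguous, a per-
    chromosome sweep over start-sorted loci yields the components.
    Extended spans are clipped to [0, chromosome length].
    """
    if chrom_lengths is not None:
        for m in mirs:
            if m.chrom not in chrom_lengths:
                raise ValueError(f"{m.id}: unknown chromosome {m.chrom!r}")
            if m.end > chrom_lengths[m.chrom]:
                raise ValueError(
                    f"{m.id}: locus end {m.end} beyond chromosome "
                    f"{m.chrom} length {chrom_lengths[m.chrom]}"
                )
    regions: list[GenotypeRegion] = []
    by_chrom: dict[str, list[MirLocus]] = {}
    for m in mirs:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom in sorted(by_chrom):
        loci = sorted(by_chrom[chrom], key=lambda m: (m.start, m.end, m.id))
        component: list[MirLocus] = []
        comp_end = -1
        for locus in loci:
            if component and locus.start < comp_end:  # strict overlap, not adjacency
                component.append(locus)
                comp_end = max(comp_end, locus.end)
            else:
                if component:
                    regions.append(_make_region(component, flank, chrom_lengths))
                component = [locus]
                comp_end = locus.end
        if component:
            regions.append(_make_region(component, flank, chrom_lengths))
    for i, region in enumerate(regions):
        region.region_id = f"region_{i:04d}"
    return regions


def _make_region(
    component: list[MirLocus], flank: int, chrom_lengths: Mapping[str, int] | None
) -> GenotypeRegion:
    chrom = component[0].chrom
    core_start = min(m.start for m in component)
    core_end = max(m.end for m in component)
    chrom_len = chrom_lengths[chrom] if chrom_lengths is not None else None
    ext_start = max(0, core_start - flank)
    ext_end = core_end + flank if chrom_len is None else min(core_end + flank, chrom_len)
    return GenotypeRegion(
        region_id="", member_mir_ids=[m.id for m in component], chrom=chrom,
        core_start=core_start, core_end=core_end,
        ext_start=ext_start, ext_end=ext_end, flank=flank,
    )


@dataclass
class CopyNumberMatrix:
    """Unrounded CN estimates, regions x accessions.

    ``status`` holds ``ok``, ``failed`` (too little callable sequence,
    no estimates) or ``filtered(<criterion>)`` for regions removed by
    the population filters; filtered regions keep their estimates.
    """

    values: pd.DataFrame  # index: region_id, columns: accession ids
    reference_accession: str
    status: pd.Series = None
    callable_bp: pd.Series = None

    def __post_init__(self) -> None:
        if self.status is None:
            self.status = pd.Series(STATUS_OK, index=self.values.index)
        if self.callable_bp is None:
            self.callable_bp = pd.Series(np.nan, index=self.values.index)
        if self.reference_accession not in self.values.columns:
            raise ValueError(
                f"reference accession {self.reference_accession!r} absent from matrix"
            )

    @property
    def ok_regions(self) -> pd.Index:
        return self.status.index[self.status == STATUS_OK]

    def to_tsv(self, path) -> None:
        out = self.values.round(3).copy()
        out.insert(0, "status", self.status)
        out.insert(1, "callable_bp", self.callable_bp)
        out.index.name = "region_id"
        out.to_csv(path, sep="\t")


def estimate_copy_number(
    depth: np.ndarray, callable_idx: np.ndarray, accession_mean_depth: float
) -> float:
    """Normalized mean-depth CN estimate over callable positions.

    ``depth`` is the per-base depth over the extended region span and
    ``callable_idx`` the offsets of unmasked positions within it.
    """
    if accession_mean_depth <= 0:
        raise ValueError("accession mean depth must be positive")
    if len(callable_idx) == 0:
        return float("nan")
    return 2.0 * float(np.mean(depth[callable_idx])) / accession_mean_depth


DepthSource = Callable[[str], Mapping[str, np.ndarray]]


def genotype_cohort(
    regions: Sequence[GenotypeRegion],
    mask: UniquenessMask,
    depth_source: DepthSource,
    accessions: Sequence[str],
    reference_accession: str,
    config: PipelineConfig | None = None,
) -> CopyNumberMatrix:
    """Estimate the CN matrix for a cohort.

    ``depth_source`` maps an accession id to per-chromosome per-base
    depth arrays; accessions are processed one at a time so the full
    depth tensor never needs to be in memory. The accession
    normalization factor is the mean depth over unmasked positions,
    genome-wide by default or per chromosome when configured.
    Regions with fewer than ``min_callable_bp`` unmasked positions are
    marked failed and carry no estimates.
    """
    config = config or PipelineConfig()
    region_callable: dict[str, np.ndarray] = {}
    for region in regions:
        idx = mask.callable_positions(region.chrom, region.ext_start, region.ext_end)
        region_callable[region.region_id] = idx - region.ext_start

    callable_bp = pd.Series(
        {r.region_id: len(region_callable[r.region_id]) for r in regions}
    )
    values = pd.DataFrame(
        np.nan, index=[r.region_id for r in regions], columns=list(accessions)
    )
    for accession in accessions:
        depth = depth_source(accession)
        if config.per_chromosome_norm:
            norm = {
                chrom: float(np.mean(arr[~mask[chrom]]))
                for chrom, arr in depth.items()
            }
        else:
            total = sum(float(arr[~mask[chrom]].sum()) for chrom, arr in depth.items())
            n = sum(int((~mask[chrom]).sum()) for chrom in depth)
            mean_depth = total / n if n else 0.0
            norm = {chrom: mean_depth for chrom in depth}
        for region in regions:
            idx = region_callable[region.region_id]
            if len(idx) < config.min_callable_bp:
                continue
            local = depth[region.chrom][region.ext_start : region.ext_end]
            values.loc[region.region_id, accession] = estimate_copy_number(
                local, idx, norm[region.chrom]
            )

    status = pd.Series(STATUS_OK, index=values.index)
    failed = callable_bp < config.min_callable_bp
    status[failed[failed].index] = STATUS_FAILED
    values.loc[status == STATUS_FAILED, :] = np.nan
    return CopyNumberMatrix(
        values=values, reference_accession=reference_accession,
        status=status, callable_bp=callable_bp.astype(float),
    )


def filter_regions(
    cn: CopyNumberMatrix, config: PipelineConfig | None = None
) -> CopyNumberMatrix:
    """Remove regions with untypical population CN distributions.

    Criteria, evaluated in order with the first failing one recorded:

    (i)   reference-accession CN outside ``ref_cn_bounds``;
    (ii)  population mean CN outside ``pop_mean_bounds``;
    (iii) across-accession interquartile range above ``iqr_max``.

    Quartiles use linear interpolation between order statistics
    (numpy's default). The operation is idempotent: already-filtered
    and failed regions are left untouched.
    """
    config = config or PipelineConfig()
    status = cn.status.copy()
    lo_ref, hi_ref = config.ref_cn_bounds
    lo_pop, hi_pop = config.pop_mean_bounds
    for region_id in cn.ok_regions:
        row = cn.values.loc[region_id]
        ref_cn = row[cn.reference_accession]
        if ref_cn < lo_ref or ref_cn > hi_ref:
            status[region_id] = "filtered(i)"
            continue
        pop_mean = row.mean()
        if pop_mean < lo_pop or pop_mean > hi_pop:
            status[region_id] = "filtered(ii)"
            continue
        q1, q3 = np.quantile(row.to_numpy(dtype=float), [0.25, 0.75])
        if q3 - q1 > config.iqr_max:
            status[region_id] = "filtered(iii)"
    return CopyNumberMatrix(
        values=cn.values, reference_accession=cn.reference_accession,
        status=status, callable_bp=cn.callable_bp,
    )


def call_genotypes(
    cn: CopyNumberMatrix, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Threshold CN estimates of surviving regions into genotype calls.

    loss if cn < loss_threshold, gain if cn >= gain_threshold, else
    normal. Returns one row per (region, accession) with columns
    ``region_id, accession_id, cn, state``.
    """
    config = config or PipelineConfig()
    ok = cn.values.loc[cn.ok_regions]
    long = ok.stack().rename("cn").reset_index()
    long.columns = ["region_id", "accession_id", "cn"]
    state = np.where(
        long["cn"] < config.loss_threshold, "loss",
        np.where(long["cn"] >= config.gain_threshold, "gain", "normal"),
    )
    long["state"] = state
    return long


def call_state(cn_value: float, config: PipelineConfig | None = None) -> str:
    """Genotype state of a single unrounded CN estimate."""
    config = config or PipelineConfig()
    if cn_value < config.loss_threshold:
        return "loss"
    if cn_value >= config.gain_threshold:
        return "gain"
    return "normal"


def classify_variability(
    calls: pd.DataFrame,
    regions: Sequence[GenotypeRegion],
    cn: CopyNumberMatrix,
) -> pd.DataFrame:
    """Per-MIR variability classification.

    A region is variable iff at least one accession carries a loss or
    gain call; every member MIR of a grouped region inherits the
    region classification. MIRs in failed or filtered regions are
    ``not_genotyped``.
    """
    nondefault = calls[calls["state"] != "normal"]
    variable_regions = set(nondefault["region_id"].unique())
    rows = []
    for region in regions:
        if cn.status[region.region_id] != STATUS_OK:
            cls = "not_genotyped"
        elif region.region_id in variable_regions:
            cls = "variable"
        else:
            cls = "nonvariable"
        for mir_id in region.member_mir_ids:
            rows.append({
                "mir_id": mir_id, "region_id": region.region_id,
                "variability": cls,
            })
    return pd.DataFrame(rows)


def summarize(
    calls: pd.DataFrame,
    mirs: Sequence[MirLocus],
    regions: Sequence[GenotypeRegion],
    variability: pd.DataFrame,
    accession_groups: Mapping[str, str],
) -> dict[str, pd.DataFrame]:
    """Family, genetic-group and per-accession call summaries.

    Returns three tables:

    ``family``      per family: variable / nonvariable member counts
                    (genotyped members only);
    ``group_loss``  per genetic group: fraction of its accessions with
                    at least one loss call in a region containing a
                    nonconserved MIR (nonconserved families plus
                    singletons);
    ``accession``   per accession: gain and loss counts split by
                    conservation class of the affected MIRs.

    Accessions absent from ``accession_groups`` are assigned to group
    "unknown" with a warning.
    """
    mir_by_id = {m.id: m for m in mirs}
    region_members = {r.region_id: r.member_mir_ids for r in regions}

    # (a) family summary over genotyped MIRs
    var_by_mir = variability.set_index("mir_id")["variability"]
    fam_rows = []
    families = sorted({m.family for m in mirs})
    for family in families:
        members = [m.id for m in mirs if m.family == family]
        states = [var_by_mir.get(mid, "not_genotyped") for mid in members]
        fam_rows.append({
            "family": family,
            "conservation": mir_by_id[members[0]].conservation,
            "n_members": len(members),
            "n_variable": states.count("variable"),
            "n_nonvariable": states.count("nonvariable"),
            "n_not_genotyped": states.count("not_genotyped"),
        })
    family_table = pd.DataFrame(fam_rows)

    accessions = sorted(calls["accession_id"].unique())
    groups = {}
    for acc in accessions:
        if acc in accession_groups:
            groups[acc] = accession_groups[acc]
        else:
            warnings.warn(f"accession {acc!r} has no genetic-group assignment")
            groups[acc] = "unknown"

    def region_conservations(region_id: str) -> set[str]:
        return {
            mir_by_id[mid].conservation
            for mid in region_members.get(region_id, [])
            if mir_by_id[mid].conservation is not None
        }

    # (b) per-group rate of accessions with >=1 nonconserved loss
    nonconserved = {"nonconserved_family", "singleton"}
    losses = calls[calls["state"] == "loss"]
    loss_carriers: set[str] = set()
    for _, row in losses.iterrows():
        if region_conservations(row["region_id"]) & nonconserved:
            loss_carriers.add(row["accession_id"])
    group_rows = []
    for group in sorted(set(groups.values())):
        members = [a for a in accessions if groups[a] == group]
        n_with_loss = sum(1 for a in members if a in loss_carriers)
        group_rows.append({
            "group": group, "n_accessions": len(members),
            "n_with_nonconserved_loss": n_with_loss,
            "loss_rate": n_with_loss / len(members) if members else float("nan"),
        })
    group_table = pd.DataFrame(group_rows)

    # (c) per-accession gain/loss counts by conservation class (MIR-level)
    acc_rows = []
    nondefault = calls[calls["state"] != "normal"]
    per_acc = {a: {"gain_conserved": 0, "loss_conserved": 0,
                   "gain_nonconserved": 0, "loss_nonconserved": 0}
               for a in accessions}
    for _, row in nondefault.iterrows():
        for mid in region_members.get(row["region_id"], []):
            cons = mir_by_id[mid].conservation
            bucket = "conserved" if cons == "conserved" else "nonconserved"
            per_acc[row["accession_id"]][f"{row['state']}_{bucket}"] += 1
    for acc in accessions:
        acc_rows.append({"accession_id": acc, "group": groups[acc], **per_acc[acc]})
    accession_table = pd.DataFrame(acc_rows)

    return {"family": family_table, "group_loss": group_table,
            "accession": accession_table}


def filter_tallies(cn: CopyNumberMatrix, regions: Sequence[GenotypeRegion]) -> dict:
    """Region- and MIR-level tallies of failed/filtered/genotyped units."""
    members = {r.region_id: r.member_mir_ids for r in regions}
    tally = {"regions": {}, "mirs": {}}
    for level in ("regions", "mirs"):
        counts: dict[str, int] = {}
        for region_id, status in cn.status.items():
            key = status.split("(")[0]
            weight = 1 if level == "regions" else len(members.get(region_id, []))
            counts[key] = counts.get(key, 0) + weight
        tally[level] = counts
    return tally
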