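"""Copy-number / expression association.

Screens every (variable MIR region, protein-coding gene) pair for a
dosage effect: the Pearson correlation of the region's unrounded copy
numbers with the gene's normalized expression across shared
accessions. Pairs with |r| >= 0.3 (inclusive) are flagged. By default
the screen is restricted to same-chromosome pairs within a 1 Mb
window plus any externally predicted miRNA-target pairs; an
exhaustive all-pairs mode is available. A shared-CNV diagnostic marks
pairs where the MIR and the gene overlap the same CNV region, since
genomic proximity inside one CNV produces correlations that are not
regulatory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel, MirLocus, _build_trees, _query
from .config import PipelineConfig
from .genotyping import CopyNumberMatrix, GenotypeRegion


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes (or mature miRNAs) x accessions."""

    values: pd.DataFrame
    unit: str = "normalized_counts"

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("expression values must be nonnegative")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Plain covariance / (sigma_x sigma_y) Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def correlate_cn_expression(
    cn: CopyNumberMatrix,
    expr: ExpressionMatrix,
    regions: Sequence[GenotypeRegion],
    variability: pd.DataFrame,
    config: PipelineConfig | None = None,
    gene_positions: Mapping[str, tuple[str, int, int]] | None = None,
    predicted_targets: pd.DataFrame | None = None,
    cnv_regions: Sequence[tuple[str, int, int]] = (),
    all_pairs: bool = False,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Pearson screen of variable-MIR copy number against expression.

    Only MIRs classified ``variable`` are tested. Candidate genes are
    either every expression row (``all_pairs`` or no coordinates
    given) or genes within ``window_bp`` of the MIR on the same
    chromosome plus pairs listed in ``predicted_targets`` (columns
    ``mir_id``, ``gene_id``). r is computed over pairwise-complete
    accessions and reported only when at least ``min_pair_n`` remain;
    zero-variance vectors yield a skipped pair with a reason. A pair
    is flagged when |r| >= ``r_threshold``.
    """
    config = config or PipelineConfig()
    region_by_mir = {
        mid: r for r in regions for mid in r.member_mir_ids
    }
    variable_mirs = variability.loc[
        variability["variability"] == "variable", "mir_id"
    ].tolist()

    shared = [a for a in cn.values.columns if a in expr.values.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared accessions")

    cnv_trees = _build_trees((c, s, e, (c, s, e)) for c, s, e in cnv_regions)

    target_pairs: set[tuple[str, str]] = set()
    if predicted_targets is not None:
        target_pairs = set(
            zip(predicted_targets["mir_id"], predicted_targets["gene_id"])
        )

    rows = []
    for mir_id in variable_mirs:
        region = region_by_mir.get(mir_id)
        if region is None or cn.status[region.region_id] != "ok":
            continue
        cn_row = cn.values.loc[region.region_id, shared]
        mir_cnvs = set(
            _query(cnv_trees, region.chrom, region.core_start, region.core_end)
        )
        if all_pairs or gene_positions is None:
            candidates = list(expr.values.index)
        else:
            candidates = [
                g for g, (chrom, gs, ge) in gene_positions.items()
                if g in expr.values.index and chrom == region.chrom
                and gs < region.core_end + window_bp
                and ge > region.core_start - window_bp
            ]
            candidates += [
                g for m, g in target_pairs
                if m == mir_id and g in expr.values.index and g not in candidates
            ]
        for gene in candidates:
            e_row = expr.values.loc[gene, shared]
            complete = cn_row.notna() & e_row.notna()
            n = int(complete.sum())
            record = {
                "mir_id": mir_id, "gene_id": gene,
                "region_id": region.region_id, "n": n,
                "r": float("nan"), "flagged": False, "skip_reason": "",
                "proximity_bp": _proximity(region, gene, gene_positions),
                "predicted_target": (mir_id, gene) in target_pairs,
                "shared_cnv": _shares_cnv(mir_cnvs, gene, gene_positions, cnv_trees),
            }
            if n < config.min_pair_n:
                record["skip_reason"] = "too_few_accessions"
                rows.append(record)
                continue
            x = cn_row[complete].to_numpy(dtype=float)
            y = e_row[complete].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                record["skip_reason"] = "zero_variance"
                rows.append(record)
                continue
            r = pearson_r(x, y)
            record["r"] = r
            record["flagged"] = bool(abs(r) >= config.r_threshold)
            rows.append(record)
    return pd.DataFrame(
        rows, columns=["mir_id", "gene_id", "region_id", "n", "r", "flagged",
                       "skip_reason", "proximity_bp", "predicted_target",
                       "shared_cnv"],
    )


def _proximity(region, gene_id, gene_positions) -> float:
    if not gene_positions or gene_id not in gene_positions:
        return float("nan")
    chrom, gs, ge = gene_positions[gene_id]
    if chrom != region.chrom:
        return float("nan")
    if gs < region.core_end and region.core_start < ge:
        return 0.0
    return float(max(gs - region.core_end, region.core_start - ge))


def _shares_cnv(mir_cnvs, gene_id, gene_positions, cnv_trees) -> bool:
    if not mir_cnvs or not gene_positions or gene_id not in gene_positions:
        return False
    chrom, gs, ge = gene_positions[gene_id]
    return bool(mir_cnvs & set(_query(cnv_trees, chrom, gs, ge)))


def expression_by_class(
    organ_expr: Mapping[str, pd.DataFrame],
    mature_to_mir: Mapping[str, str],
    mir_classes: Mapping[str, str],
    detect_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per organ x conservation class abundance summaries.

    ``organ_expr`` maps organ name to a one-column frame (or Series-
    like frame) of RPM per mature miRNA. Unmapped miRNAs are excluded
    with a warning. Detectable = RPM strictly above the threshold.
    Classes with no miRNA in an organ yield an empty (zero-count) row.
    """
    classes = sorted(set(mir_classes.values()))
    rows = []
    for organ, frame in organ_expr.items():
        rpm = frame.iloc[:, 0] if isinstance(frame, pd.DataFrame) else frame
        mapped = {}
        for mirna, value in rpm.items():
            mir = mature_to_mir.get(mirna)
            if mir is None or mir not in mir_classes:
                warnings.warn(f"mature miRNA {mirna!r} has no classified locus")
                continue
            mapped.setdefault(mir_classes[mir], []).append(float(value))
        for cls in classes:
            values = np.array(mapped.get(cls, []), dtype=float)
            if values.size:
                q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
            else:
                q1 = med = q3 = float("nan")
            rows.append({
                "organ": organ, "conservation": cls, "n_mirnas": values.size,
                "median_rpm": med, "q1_rpm": q1, "q3_rpm": q3,
                "n_detectable": int((values > detect_threshold).sum()),
            })
    return pd.DataFrame(rows)
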