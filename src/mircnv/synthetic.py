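"""Self-contained synthetic study generator.

Emulates the statistical structure of the real inputs — a reference
genome with repeats, a miRBase-style stem-loop catalogue with
conservation classes and seven overlapping precursor pairs, a
population of inbred accessions with integer copy-number states,
Poisson read depth proportional to local copy number, MLPA signals
proportional to CN/2, and expression vectors with planted dosage
correlations — with complete ground truth for every downstream stage.

Every generator consumes only an explicit seed; sub-streams are
derived with fixed integer tags so that a study is byte-identical
across runs of the same seed. Inbred accessions are modeled as
effectively homozygous, so planted states are whole-locus copy
numbers (0 = full deletion, 2 = reference state, 4/6 = duplications).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from . import io
from .annotation import (AnnotationSet, FamilyTaxaTable, GeneModel, MirLocus,
                         TransposableElement)
from .config import PipelineConfig
from .genotyping import GenotypeRegion, group_and_define_regions

BASES = np.frombuffer(b"ACGT", dtype="S1")

# sub-stream tags: one per generator so streams never collide
_TAG_GENOME = 1
_TAG_CATALOGUE = 2
_TAG_ANNOTATIONS = 3
_TAG_POPULATION = 4
_TAG_DEPTH = 5
_TAG_MLPA = 6
_TAG_EXPRESSION = 7
_TAG_CENSUS = 8
_TAG_RPM = 9


def _rng(seed: int, tag: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag, *extra]))


# --- genome ---------------------------------------------------------------

def simulate_genome(
    length: int,
    n_repeat_blocks: int = 0,
    repeat_len: int = 60,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[dict[str, str], list[dict]]:
    """Uniform-random genome with planted duplicated blocks.

    Each repeat block copies a random source segment to a random
    non-overlapping destination, so its k-mers occur (at least) twice
    genome-wide. Returns the sequence dict and the repeat truth.
    """
    if repeat_len > length:
        raise ValueError("repeat_len exceeds genome length")
    rng = _rng(seed, _TAG_GENOME)
    seq = rng.choice(BASES, size=length)
    repeats: list[dict] = []
    occupied: list[tuple[int, int]] = []

    def place(width: int) -> int:
        for _ in range(1000):
            pos = int(rng.integers(0, length - width))
            if all(pos + width <= s or pos >= e for s, e in occupied):
                occupied.append((pos, pos + width))
                return pos
        raise RuntimeError("could not place repeat block")

    for _ in range(n_repeat_blocks):
        src = place(repeat_len)
        dst = place(repeat_len)
        seq[dst : dst + repeat_len] = seq[src : src + repeat_len]
        repeats.append({"src": src, "dst": dst, "length": repeat_len})
    return {chrom: b"".join(seq).decode()}, repeats


def plant_sequence_copies(
    genome: dict[str, str],
    query: str,
    n_copies: int,
    max_divergence: float = 0.03,
    seed: int = 0,
    min_gap: int = 500,
) -> tuple[dict[str, str], list[dict]]:
    """Plant diverged copies of ``query`` at random positions/strands.

    Divergence is by substitution only, at most ``max_divergence`` of
    the query length per copy, keeping each copy's identity to the
    query at or above ``1 - max_divergence``. Returns the modified
    genome and the planted-copy truth.
    """
    from .mask import reverse_complement

    rng = _rng(seed, _TAG_CENSUS)
    (chrom, seq), = genome.items()
    seq = list(seq)
    qlen = len(query)
    max_subs = int(max_divergence * qlen)
    occupied: list[tuple[int, int]] = []
    truth = []
    for i in range(n_copies):
        for _ in range(1000):
            pos = int(rng.integers(0, len(seq) - qlen))
            if all(pos + qlen + min_gap <= s or pos >= e + min_gap for s, e in occupied):
                break
        else:
            raise RuntimeError("could not place census copy")
        occupied.append((pos, pos + qlen))
        n_subs = int(rng.integers(0, max_subs + 1))
        copy = list(query)
        sub_sites = rng.choice(qlen, size=n_subs, replace=False) if n_subs else []
        for site in sub_sites:
            current = copy[site]
            options = [b for b in "ACGT" if b != current]
            copy[site] = options[int(rng.integers(0, 3))]
        strand = "+" if rng.random() < 0.5 else "-"
        planted = "".join(copy) if strand == "+" else reverse_complement("".join(copy))
        seq[pos : pos + qlen] = planted
        truth.append({
            "start": pos, "end": pos + qlen, "strand": strand,
            "n_substitutions": n_subs,
            "identity": (qlen - n_subs) / qlen,
        })
    return {chrom: "".join(seq)}, truth


# --- catalogue & annotations ----------------------------------------------

CONSERVED_TAXA = dict(outside_brassicaceae=True, brassicaceae_beyond_athaliana=True)
NONCONSERVED_TAXA = dict(outside_brassicaceae=False, brassicaceae_beyond_athaliana=True)
SINGLETON_TAXA = dict(outside_brassicaceae=False, brassicaceae_beyond_athaliana=False)


def simulate_catalogue(
    genome_length: int,
    n_conserved: int = 20,
    n_nonconserved: int = 20,
    n_singleton: int = 20,
    n_overlapping_pairs: int = 7,
    seed: int = 0,
    chrom: str = "chr1",
    mir_len_range: tuple[int, int] = (90, 250),
    spacing: int = 900,
    start_offset: int = 1000,
) -> tuple[list[MirLocus], FamilyTaxaTable]:
    """Stem-loop catalogue with planted conservation classes.

    Exactly ``n_overlapping_pairs`` precursor pairs overlap each other
    (as neighbouring family members do in the real catalogue); all
    other loci are spaced at least ``spacing`` bp apart so extended
    genotyping regions never collide. Conserved families get multiple
    members, nonconserved families two, singletons one.
    """
    rng = _rng(seed, _TAG_CATALOGUE)
    n_total = n_conserved + n_nonconserved + n_singleton
    classes = (["conserved"] * n_conserved + ["nonconserved_family"] * n_nonconserved
               + ["singleton"] * n_singleton)
    # overlapping pairs are drawn from nonconserved families, mirroring
    # the paired family members (e.g. a/b suffixes) seen in practice
    if n_overlapping_pairs * 2 > n_nonconserved:
        raise ValueError("not enough nonconserved loci to form the overlapping pairs")

    lengths = rng.integers(mir_len_range[0], mir_len_range[1] + 1, size=n_total)
    positions = []
    cursor = start_offset
    # lay out loci left to right; members of an overlapping pair share ~40 bp
    order = list(range(n_total))
    pair_partners: dict[int, int] = {}
    nonconserved_idx = [i for i, c in enumerate(classes) if c == "nonconserved_family"]
    for p in range(n_overlapping_pairs):
        a, b = nonconserved_idx[2 * p], nonconserved_idx[2 * p + 1]
        pair_partners[a] = b
    placed: dict[int, tuple[int, int]] = {}
    shuffled = list(order)
    rng.shuffle(shuffled)
    for i in shuffled:
        if i in placed:
            continue
        start = cursor
        end = start + int(lengths[i])
        placed[i] = (start, end)
        cursor = end + spacing
        if i in pair_partners:
            j = pair_partners[i]
            overlap = min(40, int(lengths[i]) // 2, int(lengths[j]) // 2)
            jstart = end - overlap
            placed[j] = (jstart, jstart + int(lengths[j]))
            cursor = jstart + int(lengths[j]) + spacing
    if cursor > genome_length:
        raise ValueError(
            f"genome too short for catalogue: need {cursor} bp, have {genome_length}"
        )

    # family assignment
    mirs: list[MirLocus] = []
    taxa_rows = []
    conserved_ids = [i for i, c in enumerate(classes) if c == "conserved"]
    n_cons_fams = max(1, n_conserved // 3)  # conserved families have ~3 members
    for f in range(n_cons_fams):
        members = conserved_ids[f::n_cons_fams]
        fam = f"MIR1{f:02d}"
        taxa_rows.append({"family": fam, **CONSERVED_TAXA,
                          "members_in_athaliana": len(members)})
        for k, i in enumerate(members):
            s, e = placed[i]
            mirs.append(MirLocus(f"syn-{fam}{chr(97 + k)}", chrom, s, e,
                                 "+" if rng.random() < 0.5 else "-", fam))
    fam_counter = 0
    i = 0
    while i < len(nonconserved_idx):
        a = nonconserved_idx[i]
        fam = f"MIR5{fam_counter:02d}"
        members = [a]
        if a in pair_partners:
            members.append(pair_partners[a])
            i += 2
        elif i + 1 < len(nonconserved_idx) and nonconserved_idx[i + 1] not in pair_partners.values():
            members.append(nonconserved_idx[i + 1])
            i += 2
        else:
            i += 1
        taxa_rows.append({"family": fam, **NONCONSERVED_TAXA,
                          "members_in_athaliana": len(members)})
        for k, m in enumerate(members):
            s, e = placed[m]
            mirs.append(MirLocus(f"syn-{fam}{chr(97 + k)}", chrom, s, e,
                                 "+" if rng.random() < 0.5 else "-", fam))
        fam_counter += 1
    singleton_ids = [i for i, c in enumerate(classes) if c == "singleton"]
    for k, i in enumerate(singleton_ids):
        fam = f"MIR8{k:02d}"
        s, e = placed[i]
        taxa_rows.append({"family": fam, **SINGLETON_TAXA, "members_in_athaliana": 1})
        mirs.append(MirLocus(f"syn-{fam}", chrom, s, e,
                             "+" if rng.random() < 0.5 else "-", fam))
    taxa = FamilyTaxaTable(pd.DataFrame(taxa_rows))
    ann.classify_catalogue(mirs, taxa)
    mirs.sort(key=lambda m: m.start)
    return mirs, taxa


TE_SUPERFAMILIES = ("DNA/MuDR", "RC/Helitron", "LTR/Gypsy", "LTR/Copia")


def simulate_annotations(
    mirs: Sequence[MirLocus],
    genome_length: int,
    seed: int = 0,
    chrom: str = "chr1",
    n_background_genes: int = 40,
    n_background_tes: int = 100,
    te_superfamily_probs: Mapping[str, float] | None = None,
    mir_te_superfamily_probs: Mapping[str, float] | None = None,
    frac_mir_with_te: float = 0.25,
    frac_mir_in_gene: float = 0.3,
    frac_genic_coding: float = 0.4,
    centromere: tuple[int, int] | None = None,
    n_cnv_regions: int = 10,
) -> tuple[AnnotationSet, dict]:
    """Genome annotations with planted MIR contexts.

    A chosen fraction of nonconserved/singleton loci is overlapped by
    TEs whose superfamily distribution differs from the genome-wide
    background (the source of a planted enrichment ratio), a fraction
    of loci is buried in gene models with or without CDS overlap, and
    CNV regions cover part of the catalogue. Truth records every
    planted context.
    """
    rng = _rng(seed, _TAG_ANNOTATIONS)
    te_bg = te_superfamily_probs or {
        "DNA/MuDR": 0.2, "RC/Helitron": 0.45, "LTR/Gypsy": 0.2, "LTR/Copia": 0.15}
    te_mir = mir_te_superfamily_probs or {
        "DNA/MuDR": 0.44, "RC/Helitron": 0.32, "LTR/Gypsy": 0.15, "LTR/Copia": 0.09}
    genes: list[GeneModel] = []
    tes: list[TransposableElement] = []
    truth: dict = {"gene_overlap": {}, "te": {}, "in_centromere": {}, "in_cnv": {}}

    mir_spans = [(m.start, m.end) for m in mirs]

    def free_position(width: int) -> int:
        for _ in range(2000):
            pos = int(rng.integers(0, genome_length - width))
            if all(pos + width <= s - 400 or pos >= e + 400 for s, e in mir_spans):
                return pos
        raise RuntimeError("no free annotation slot")

    # background genes away from loci
    for g in range(n_background_genes):
        width = int(rng.integers(800, 3000))
        pos = free_position(width)
        cds = [(pos + 100, pos + width - 100)]
        genes.append(GeneModel(f"GENE{g:04d}", chrom, pos, pos + width, cds))

    # genic loci: gene wrapped around the MIR, CDS overlapping or not;
    # loci overlapping another locus are left intergenic so the wrapped
    # gene cannot silently cover the partner
    isolated = [
        m for m in mirs
        if not any(o is not m and o.start < m.end + 350 and m.start - 350 < o.end
                   for o in mirs)
    ]
    genic = [m for m in isolated if rng.random() < frac_mir_in_gene]
    for gi, m in enumerate(genic):
        gstart, gend = max(0, m.start - 300), min(genome_length, m.end + 300)
        coding = rng.random() < frac_genic_coding
        if coding:
            cds = [(m.start + (m.end - m.start) // 2, gend - 50)]
            truth["gene_overlap"][m.id] = "coding"
        else:
            cds = [(gend - 60, gend - 10)]  # CDS clear of the locus
            truth["gene_overlap"][m.id] = "noncoding"
        genes.append(GeneModel(f"GENE_MIR{gi:03d}", chrom, gstart, gend, cds))
    for m in mirs:
        truth["gene_overlap"].setdefault(m.id, "intergenic")

    # background TEs
    superfams = list(te_bg)
    bg_p = np.array([te_bg[s] for s in superfams])
    for t in range(n_background_tes):
        width = int(rng.integers(200, 2000))
        pos = free_position(width)
        sf = superfams[int(rng.choice(len(superfams), p=bg_p))]
        tes.append(TransposableElement(f"TE{t:04d}", chrom, pos, pos + width, sf))

    # TE-overlapping loci (never conserved ones)
    mir_p = np.array([te_mir[s] for s in superfams])
    te_counter = n_background_tes
    for m in mirs:
        if m.conservation == "conserved":
            truth["te"][m.id] = []
            continue
        if rng.random() < frac_mir_with_te:
            sf = superfams[int(rng.choice(len(superfams), p=mir_p))]
            width = int(rng.integers(150, 600))
            pos = max(0, m.start - width // 3)
            te_id = f"TE{te_counter:04d}"
            te_counter += 1
            tes.append(TransposableElement(te_id, chrom, pos, pos + width, sf))
            truth["te"][m.id] = [(te_id, sf)]
        else:
            truth["te"][m.id] = []

    centromeres = []
    if centromere is not None:
        centromeres.append((chrom, centromere[0], centromere[1]))
    for m in mirs:
        truth["in_centromere"][m.id] = bool(
            centromere and m.start < centromere[1] and centromere[0] < m.end
        )

    cnvs = []
    cnv_mirs = [m for m in mirs if rng.random() < 0.3][:n_cnv_regions]
    for m in cnv_mirs:
        pad = int(rng.integers(100, 800))
        cnvs.append((chrom, max(0, m.start - pad), min(genome_length, m.end + pad)))
    for _ in range(n_cnv_regions - len(cnvs)):
        width = int(rng.integers(1000, 5000))
        pos = free_position(width)
        cnvs.append((chrom, pos, pos + width))
    cnv_ids = {m.id for m in cnv_mirs}
    for m in mirs:
        truth["in_cnv"][m.id] = m.id in cnv_ids

    return AnnotationSet(genes=genes, tes=tes, centromeres=centromeres,
                         cnv_regions=cnvs), truth


# --- population -----------------------------------------------------------

DEFAULT_STATE_PROBS: dict[str, dict[int, float]] = {
    # conserved loci: overwhelmingly two-copy, rare private duplications —
    # ~96% of accessions carry no conserved-locus change at all
    "conserved": {2: 0.998, 4: 0.001, 6: 0.001},
    # young loci: losses dominate and are group-structured
    "nonconserved_family": {0: 0.03, 2: 0.96, 4: 0.004, 6: 0.006},
    "singleton": {0: 0.03, 2: 0.956, 4: 0.004, 6: 0.01},
}

DEFAULT_GROUPS = ("Germany", "Spain", "Sweden", "Italy", "Relict")

# per-group multiplier on the loss probability of nonconserved loci.
# Accessions genetically close to the reference show far fewer detected
# deletions (reference bias), distant/relict groups far more; at the
# default study scale these weights put the reference-proximal group
# near a 20% rate of carrying any nonconserved loss and the relict
# group near 80%.
DEFAULT_GROUP_LOSS_WEIGHT = {
    "Germany": 0.2, "Spain": 0.9, "Sweden": 1.2, "Italy": 1.05, "Relict": 1.7,
}


def simulate_population(
    regions: Sequence[GenotypeRegion],
    region_conservation: Mapping[str, str],
    n_accessions: int = 200,
    groups: Sequence[str] = DEFAULT_GROUPS,
    cn_state_probs: Mapping[str, Mapping[int, float]] | None = None,
    group_loss_weight: Mapping[str, float] | None = None,
    seed: int = 0,
    reference_accession: str = "Col-0",
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted integer CN states, regions x accessions.

    Per-region states are drawn from the conservation-class-specific
    distribution; the loss-state probability of nonconserved loci is
    additionally scaled per genetic group (renormalized against the
    two-copy state). The reference accession is forced to CN 2
    everywhere. Returns the truth matrix and the group assignment.
    """
    probs = {k: dict(v) for k, v in (cn_state_probs or DEFAULT_STATE_PROBS).items()}
    for cls, p in probs.items():
        total = sum(p.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"state probabilities for {cls!r} sum to {total}, not 1")
    weight = dict(group_loss_weight or DEFAULT_GROUP_LOSS_WEIGHT)
    rng = _rng(seed, _TAG_POPULATION)
    accessions = [reference_accession] + [f"acc_{i:04d}" for i in range(n_accessions - 1)]
    group_assign = pd.Series(
        [list(groups)[i % len(groups)] for i in range(n_accessions)], index=accessions
    )
    group_assign[reference_accession] = list(groups)[0]

    cn = pd.DataFrame(2, index=[r.region_id for r in regions], columns=accessions,
                      dtype=int)
    for region in regions:
        cls = region_conservation[region.region_id]
        base = probs.get(cls, {2: 1.0})
        for acc in accessions:
            if acc == reference_accession:
                continue
            p = dict(base)
            if cls in ("nonconserved_family", "singleton") and 0 in p:
                w = weight.get(group_assign[acc], 1.0)
                p0 = min(0.9, p[0] * w)
                p[2] = p.get(2, 0.0) + p[0] - p0
                p[0] = p0
            states = sorted(p)
            draw = rng.choice(len(states), p=np.array([p[s] for s in states]))
            cn.loc[region.region_id, acc] = states[int(draw)]
    return cn, group_assign


def region_conservation_map(
    regions: Sequence[GenotypeRegion], mirs: Sequence[MirLocus]
) -> dict[str, str]:
    by_id = {m.id: m for m in mirs}
    return {
        r.region_id: by_id[r.member_mir_ids[0]].conservation or "singleton"
        for r in regions
    }


# --- depth ----------------------------------------------------------------

def simulate_depth(
    genome: dict[str, str],
    regions: Sequence[GenotypeRegion],
    cn_truth: pd.DataFrame,
    accession: str,
    lam: float = 20.0,
    seed: int = 0,
    accession_index: int | None = None,
    dispersion: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-base depth for one accession.

    depth ~ Poisson(lam * CN_local / 2) with CN_local the planted
    region copy number inside each extended region span and 2
    elsewhere. With ``dispersion`` set, a negative-binomial with that
    size parameter replaces the Poisson for robustness testing.
    Deterministic per (seed, accession).
    """
    if lam <= 0:
        raise ValueError("mean coverage lam must be positive")
    idx = accession_index if accession_index is not None else _stable_index(accession)
    rng = _rng(seed, _TAG_DEPTH, idx)
    depth: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        rate = np.full(len(seq), lam, dtype=float)
        for region in regions:
            if region.chrom != chrom:
                continue
            cn = int(cn_truth.loc[region.region_id, accession])
            rate[region.ext_start : region.ext_end] = lam * cn / 2.0
        if dispersion is None:
            depth[chrom] = rng.poisson(rate).astype(np.int32)
        else:
            # NB with mean rate and size parameter `dispersion`
            p = dispersion / (dispersion + rate)
            depth[chrom] = rng.negative_binomial(dispersion, p).astype(np.int32)
    return depth


def _stable_index(accession: str) -> int:
    import zlib

    return zlib.crc32(accession.encode()) & 0x7FFFFFFF


def depth_source(
    genome: dict[str, str],
    regions: Sequence[GenotypeRegion],
    cn_truth: pd.DataFrame,
    lam: float = 20.0,
    seed: int = 0,
    dispersion: float | None = None,
):
    """Accession -> depth-profile callable for :func:`genotype_cohort`."""
    order = {acc: i for i, acc in enumerate(cn_truth.columns)}

    def source(accession: str) -> dict[str, np.ndarray]:
        return simulate_depth(
            genome, regions, cn_truth, accession, lam=lam, seed=seed,
            accession_index=order[accession], dispersion=dispersion,
        )

    return source


# --- MLPA -----------------------------------------------------------------

def simulate_mlpa(
    cn_truth: pd.DataFrame,
    target_regions: Mapping[str, str],
    samples: Sequence[str],
    control_scale: float = 1000.0,
    sigma: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw MLPA signals proportional to CN/2 with lognormal noise.

    ``target_regions`` maps probe target MIR id -> region id in the
    truth matrix. raw = control_scale * (CN/2) * LogNormal(0, sigma);
    the three control probes behave as fixed two-copy loci. Returns
    (raw signal frame, probe design frame).
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = _rng(seed, _TAG_MLPA)
    probes = [f"probe_{mir}" for mir in target_regions]
    controls = ["ctrl_1", "ctrl_2", "ctrl_3"]
    design = pd.DataFrame({
        "probe": probes + controls,
        "target_mir": list(target_regions) + ["", "", ""],
        "is_control": [False] * len(probes) + [True] * 3,
    })
    raw = pd.DataFrame(index=list(samples), columns=probes + controls, dtype=float)
    for sample in samples:
        for mir, region in target_regions.items():
            cn = float(cn_truth.loc[region, sample])
            noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
            raw.loc[sample, f"probe_{mir}"] = control_scale * (cn / 2.0) * noise
        for ctrl in controls:
            noise = float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0
            raw.loc[sample, ctrl] = control_scale * noise
    return raw, design


# --- expression -----------------------------------------------------------

def simulate_expression(
    cn_truth: pd.DataFrame,
    planted_pairs: Sequence[tuple[str, str, float]],
    n_null_genes: int = 200,
    accessions: Sequence[str] | None = None,
    base: float = 100.0,
    spread: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Expression matrix with planted dosage correlations.

    ``planted_pairs`` lists (gene_id, region_id, target_r). For each,
    expression = base + spread * (r * z_cn + sqrt(1 - r^2) * eps) with
    z_cn the standardized planted CN of the region, which achieves the
    target population correlation; independent genes are i.i.d.
    normal around ``base``. Values are clipped at zero (10 sigma away
    at the defaults). Returns (genes x accessions frame, pair truth).
    """
    rng = _rng(seed, _TAG_EXPRESSION)
    accessions = list(accessions or cn_truth.columns)
    rows = {}
    truth = []
    for gene_id, region_id, r in planted_pairs:
        if abs(r) > 1:
            raise ValueError(f"target correlation {r} outside [-1, 1]")
        cn = cn_truth.loc[region_id, accessions].to_numpy(dtype=float)
        if np.all(cn == cn[0]):
            raise ValueError(
                f"region {region_id} has constant planted CN; cannot plant r={r}"
            )
        z = (cn - cn.mean()) / cn.std()
        eps = rng.standard_normal(len(accessions))
        rows[gene_id] = base + spread * (r * z + np.sqrt(1 - r * r) * eps)
        truth.append({"gene_id": gene_id, "region_id": region_id, "target_r": r})
    for g in range(n_null_genes):
        rows[f"NULL{g:04d}"] = base + spread * rng.standard_normal(len(accessions))
    values = pd.DataFrame(rows, index=accessions).T.clip(lower=0.0)
    return values, truth


def simulate_organ_rpm(
    mirs: Sequence[MirLocus],
    organs: Sequence[str] = ("leaf", "flower", "root"),
    class_scale: Mapping[str, float] | None = None,
    sigma: float = 1.0,
    detect_dropout: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Mature-miRNA RPM per organ with class-ordered abundance.

    Conserved loci produce far more mature miRNA than young loci; the
    default scales plant that ordering. A per-class dropout sets RPM
    to zero (undetectable). Returns organ -> RPM frame and the
    mature-name -> locus map.
    """
    scale = class_scale or {"conserved": 500.0, "nonconserved_family": 5.0,
                            "singleton": 1.0}
    dropout = detect_dropout or {"conserved": 0.02, "nonconserved_family": 0.3,
                                 "singleton": 0.5}
    rng = _rng(seed, _TAG_RPM)
    mature_to_mir = {f"{m.id}-5p": m.id for m in mirs}
    out = {}
    for organ in organs:
        values = {}
        for mature, mir_id in mature_to_mir.items():
            cls = next(m.conservation for m in mirs if m.id == mir_id)
            if rng.random() < dropout[cls]:
                values[mature] = 0.0
            else:
                values[mature] = float(scale[cls] * rng.lognormal(0.0, sigma))
        out[organ] = pd.DataFrame({"rpm": values})
    return out, mature_to_mir


# --- whole-study orchestration --------------------------------------------

@dataclass
class SyntheticStudy:
    """A complete synthetic study plus its ground truth."""

    seed: int
    config: PipelineConfig
    genome: dict[str, str]
    repeats: list[dict]
    mirs: list[MirLocus]
    taxa: FamilyTaxaTable
    annotations: AnnotationSet
    context_truth: dict
    regions: list[GenotypeRegion]
    cn_truth: pd.DataFrame
    groups: pd.Series
    lam: float
    mlpa_raw: pd.DataFrame
    mlpa_design: pd.DataFrame
    mlpa_sigma: float
    expression: pd.DataFrame
    expression_truth: list[dict]
    gene_positions: dict[str, tuple[str, int, int]]
    masked_mirs: list[str] = field(default_factory=list)

    def depth_source(self, dispersion: float | None = None):
        return depth_source(self.genome, self.regions, self.cn_truth,
                            lam=self.lam, seed=self.seed, dispersion=dispersion)

    @property
    def reference_accession(self) -> str:
        return str(self.cn_truth.columns[0])

    def expected_states(self, config: PipelineConfig | None = None) -> pd.DataFrame:
        """Genotype states implied by the planted integer CNs."""
        config = config or self.config
        cn = self.cn_truth
        states = np.where(cn < config.loss_threshold, "loss",
                          np.where(cn >= config.gain_threshold, "gain", "normal"))
        return pd.DataFrame(states, index=cn.index, columns=cn.columns)

    def write(self, outdir: str | Path) -> None:
        """Serialize the study in the formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.genome, outdir / "genome.fa")
        ann.mirs_to_gff3(self.mirs, outdir / "mirs.gff3")
        self.taxa.to_tsv(outdir / "family_taxa.tsv")
        ann.genes_to_gff3(self.annotations.genes, outdir / "genes.gff3")
        ann.tes_to_gff3(self.annotations.tes, outdir / "tes.gff3")
        io.write_bed3(self.annotations.centromeres, outdir / "centromeres.bed")
        io.write_bed3(self.annotations.cnv_regions, outdir / "cnv_regions.bed")
        self.cn_truth.rename_axis("region_id").to_csv(outdir / "truth_cn.tsv", sep="\t")
        self.groups.rename("group").rename_axis("accession_id").to_csv(
            outdir / "accession_groups.tsv", sep="\t")
        raw = self.mlpa_raw.rename_axis("sample")
        raw.to_csv(outdir / "mlpa_raw.tsv", sep="\t", float_format="%.6f")
        self.mlpa_design.to_csv(outdir / "mlpa_design.tsv", sep="\t", index=False)
        self.expression.rename_axis("gene_id").to_csv(
            outdir / "expression.tsv", sep="\t", float_format="%.6f")
        truth = {
            "seed": self.seed,
            "lam": self.lam,
            "mlpa_sigma": self.mlpa_sigma,
            "repeats": self.repeats,
            "masked_mirs": self.masked_mirs,
            "context_truth": {
                k: ({kk: list(map(list, vv)) if isinstance(vv, list) else vv
                     for kk, vv in v.items()} if isinstance(v, dict) else v)
                for k, v in self.context_truth.items()
            },
            "expression_truth": self.expression_truth,
            "config": self.config.to_dict(),
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)


def simulate_study(
    seed: int = 0,
    genome_length: int = 500_000,
    n_conserved: int = 20,
    n_nonconserved: int = 20,
    n_singleton: int = 20,
    n_overlapping_pairs: int = 7,
    n_accessions: int = 200,
    lam: float = 20.0,
    mlpa_sigma: float = 0.1,
    n_mlpa_samples: int = 48,
    n_repeat_blocks: int = 3,
    n_masked_mirs: int = 1,
    planted_r: Sequence[float] = (0.7, 0.5, -0.4),
    n_null_genes: int = 200,
    config: PipelineConfig | None = None,
) -> SyntheticStudy:
    """Generate the default synthetic study end to end.

    500 kb genome, 60 loci (20 per conservation class) with seven
    overlapping pairs, 200 accessions in five genetic groups at 20x
    diploid coverage, 48-sample MLPA panel at 10% lognormal noise, and
    an expression matrix with planted dosage correlations. One locus
    (``n_masked_mirs``) gets its genotyping region duplicated
    elsewhere in the genome so the uniqueness mask removes it — the
    failed-genotyping pathway stays exercised.
    """
    config = config or PipelineConfig(seed=seed)
    genome, repeats = simulate_genome(
        genome_length, n_repeat_blocks=n_repeat_blocks, seed=seed)
    mirs, taxa = simulate_catalogue(
        genome_length, n_conserved, n_nonconserved, n_singleton,
        n_overlapping_pairs, seed=seed)
    annotations, context_truth = simulate_annotations(mirs, genome_length, seed=seed)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    regions = group_and_define_regions(mirs, flank=config.flank,
                                       chrom_lengths=chrom_lengths)

    # duplicate the extended span of the last region(s) into empty space
    # so masking wipes them out -> failed genotyping
    masked_mirs: list[str] = []
    if n_masked_mirs:
        (chrom, seq), = genome.items()
        seq = list(seq)
        tail = genome_length - 10_000
        for region in regions[-n_masked_mirs:]:
            block = seq[region.ext_start : region.ext_end]
            if tail + len(block) > genome_length:
                raise ValueError("no room to plant region duplicates")
            seq[tail : tail + len(block)] = block
            tail += len(block) + 200
            masked_mirs.extend(region.member_mir_ids)
        genome = {chrom: "".join(seq)}

    cons_map = region_conservation_map(regions, mirs)
    cn_truth, groups = simulate_population(
        regions, cons_map, n_accessions=n_accessions, seed=seed)

    # MLPA panel: probes for a spread of variable loci, biased sample set
    expected = np.where(cn_truth < config.loss_threshold, "loss",
                        np.where(cn_truth >= config.gain_threshold, "gain", "normal"))
    variable_regions = cn_truth.index[(expected != "normal").any(axis=1)]
    target_regions = {}
    region_by_id = {r.region_id: r for r in regions}
    for rid in list(variable_regions)[:8]:
        target_regions[region_by_id[rid].member_mir_ids[0]] = rid
    carrier_mask = (expected != "normal")[
        [list(cn_truth.index).index(r) for r in target_regions.values()], :
    ].any(axis=0) if target_regions else np.zeros(cn_truth.shape[1], bool)
    carriers = [a for a, hit in zip(cn_truth.columns, carrier_mask) if hit]
    others = [a for a in cn_truth.columns if a not in carriers]
    samples = (carriers + others)[:n_mlpa_samples]
    mlpa_raw, mlpa_design = simulate_mlpa(
        cn_truth, target_regions, samples, sigma=mlpa_sigma, seed=seed)

    # planted dosage pairs on loss-variable regions
    loss_regions = [rid for rid in variable_regions
                    if (cn_truth.loc[rid] == 0).any()]
    planted_pairs = []
    gene_positions: dict[str, tuple[str, int, int]] = {}
    for i, r in enumerate(planted_r):
        if i >= len(loss_regions):
            break
        rid = loss_regions[i]
        gene_id = f"DOSAGE{i:02d}"
        planted_pairs.append((gene_id, rid, float(r)))
        region = region_by_id[rid]
        gene_positions[gene_id] = (region.chrom, region.ext_end + 2000,
                                   region.ext_end + 4000)
    expression, expression_truth = simulate_expression(
        cn_truth, planted_pairs, n_null_genes=n_null_genes, seed=seed)
    # null genes live far from every locus on a nominal second chromosome
    for g in expression.index:
        if g not in gene_positions:
            gene_positions[g] = ("chr_null", 0, 1000)

    return SyntheticStudy(
        seed=seed, config=config, genome=genome, repeats=repeats, mirs=mirs,
        taxa=taxa, annotations=annotations, context_truth=context_truth,
        regions=regions, cn_truth=cn_truth, groups=groups, lam=lam,
        mlpa_raw=mlpa_raw, mlpa_design=mlpa_design, mlpa_sigma=mlpa_sigma,
        expression=expression, expression_truth=expression_truth,
        gene_positions=gene_positions, masked_mirs=masked_mirs,
    )


def simulate_cohort(
    seed: int = 0,
    n_accessions: int = 200,
    n_regions: int = 50,
    lam: float = 20.0,
    genome_length: int = 200_000,
    config: PipelineConfig | None = None,
) -> SyntheticStudy:
    """Smaller genotyping-focused study: ~``n_regions`` clean regions.

    57 loci with seven overlapping pairs give exactly 50 regions; no
    repeat blocks or masked loci, so every region is callable.
    """
    n_mirs = n_regions + 7
    per_class = n_mirs // 3
    return simulate_study(
        seed=seed, genome_length=genome_length,
        n_conserved=n_mirs - 2 * per_class, n_nonconserved=per_class,
        n_singleton=per_class, n_accessions=n_accessions, lam=lam,
        n_repeat_blocks=0, n_masked_mirs=0, config=config,
    )
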