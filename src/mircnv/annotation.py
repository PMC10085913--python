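"""MIR catalogue, conservation classes and genomic context.

A miRNA gene (MIR) is the genomic stem-loop precursor locus. Families
are classified by phylogenetic breadth: ``conserved`` families have
members outside Brassicaceae, ``nonconserved_family`` members are
restricted to Brassicaceae (or form a multi-member family within
A. thaliana), and ``singleton`` loci are unique to A. thaliana. Each
locus is annotated with its overlap against protein-coding gene
models (intergenic / coding / noncoding), transposable elements with
superfamily labels, centromeres and known CNV regions. All overlap
tests are strand-agnostic and count a single shared base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from . import io

CONSERVATION_CLASSES = ("conserved", "nonconserved_family", "singleton")
GENE_OVERLAP_CLASSES = ("intergenic", "coding", "noncoding")


class UnknownFamilyError(KeyError):
    """Raised when a family is missing from the taxa table."""


class ChromosomeMismatchError(ValueError):
    """Raised when a locus sits on a chromosome absent from the annotations."""


@dataclass
class MirLocus:
    """One stem-loop precursor locus (0-based half-open coordinates)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    conservation: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.id}: start must be < end")
        if not self.family:
            raise ValueError(f"{self.id}: family must be nonempty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        if self.conservation is not None and self.conservation not in CONSERVATION_CLASSES:
            raise ValueError(f"{self.id}: bad conservation class {self.conservation!r}")

    def overlaps(self, other: "MirLocus") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class GeneModel:
    """A protein-coding gene span with its CDS sub-intervals."""

    id: str
    chrom: str
    start: int
    end: int
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.id}: start must be < end")
        for s, e in self.cds:
            if not s < e:
                raise ValueError(f"{self.id}: invalid CDS interval [{s}, {e})")


@dataclass
class TransposableElement:
    id: str
    chrom: str
    start: int
    end: int
    superfamily: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.id}: start must be < end")


class FamilyTaxaTable:
    """Phylogenetic breadth of each MIR family.

    Backed by a frame with one row per family:
    ``family``, ``outside_brassicaceae`` (bool), ``brassicaceae_beyond_athaliana``
    (bool), ``members_in_athaliana`` (int).
    """

    COLUMNS = [
        "family", "outside_brassicaceae",
        "brassicaceae_beyond_athaliana", "members_in_athaliana",
    ]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"taxa table missing columns: {sorted(missing)}")
        self.table = table.set_index("family", drop=False) if table.index.name != "family" else table

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyTaxaTable":
        df = io.read_tsv(path)
        for col in ("outside_brassicaceae", "brassicaceae_beyond_athaliana"):
            df[col] = df[col].astype(bool)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        io.write_tsv(self.table.reset_index(drop=True), path)

    def __contains__(self, family: str) -> bool:
        return family in self.table.index

    def row(self, family: str) -> pd.Series:
        try:
            return self.table.loc[family]
        except KeyError:
            raise UnknownFamilyError(f"family {family!r} not in taxa table") from None


def classify_conservation(family: str, taxa: FamilyTaxaTable) -> str:
    """Classify a family by its phylogenetic distribution.

    ``conserved`` if members occur outside Brassicaceae;
    ``nonconserved_family`` if restricted to Brassicaceae but found
    beyond A. thaliana, or forming a multi-member family within it;
    ``singleton`` if unique to A. thaliana with a single member.
    """
    row = taxa.row(family)
    if bool(row["outside_brassicaceae"]):
        return "conserved"
    if bool(row["brassicaceae_beyond_athaliana"]) or int(row["members_in_athaliana"]) > 1:
        return "nonconserved_family"
    return "singleton"


def classify_catalogue(mirs: Sequence[MirLocus], taxa: FamilyTaxaTable) -> None:
    """Assign ``conservation`` in place for every locus."""
    for mir in mirs:
        mir.conservation = classify_conservation(mir.family, taxa)


class AnnotationSet:
    """Genome annotations used for context classification."""

    def __init__(
        self,
        genes: Sequence[GeneModel] = (),
        tes: Sequence[TransposableElement] = (),
        centromeres: Sequence[tuple[str, int, int]] = (),
        cnv_regions: Sequence[tuple[str, int, int]] = (),
        pseudogenes: Sequence[tuple[str, str, int, int]] = (),
    ):
        self.genes = list(genes)
        self.tes = list(tes)
        self.centromeres = list(centromeres)
        self.cnv_regions = list(cnv_regions)
        self.pseudogenes = list(pseudogenes)
        for chrom, s, e in list(centromeres) + list(cnv_regions):
            if not s < e:
                raise ValueError(f"invalid interval [{s}, {e}) on {chrom}")
        self._gene_trees = _build_trees((g.chrom, g.start, g.end, g) for g in self.genes)
        self._cds_trees = _build_trees(
            (g.chrom, s, e, g) for g in self.genes for s, e in g.cds
        )
        self._te_trees = _build_trees((t.chrom, t.start, t.end, t) for t in self.tes)
        self._cen_trees = _build_trees((c, s, e, None) for c, s, e in self.centromeres)
        self._cnv_trees = _build_trees((c, s, e, (c, s, e)) for c, s, e in self.cnv_regions)

    @property
    def chromosomes(self) -> set[str]:
        chroms = {g.chrom for g in self.genes} | {t.chrom for t in self.tes}
        chroms |= {c for c, _, _ in self.centromeres} | {c for c, _, _ in self.cnv_regions}
        return chroms


def _build_trees(items: Iterable[tuple[str, int, int, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, data in items:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, data)
    return trees


def _query(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> list:
    tree = trees.get(chrom)
    if tree is None:
        return []
    return [iv.data for iv in tree.overlap(start, end)]


@dataclass
class MirContext:
    """Genomic context of one MIR locus."""

    mir_id: str
    gene_overlap: str
    te_overlaps: list[tuple[str, str]]
    in_centromere: bool
    in_cnv: bool
    cnv_contained: bool = False
    pseudogene_overlap: bool = False


def gene_overlap_class(mir: MirLocus, genes: Sequence[GeneModel] | AnnotationSet) -> str:
    """Classify a locus against protein-coding gene models.

    ``intergenic`` when no gene span shares a base pair with the locus;
    ``coding`` when any CDS sub-interval does; ``noncoding`` otherwise
    (e.g. intronic or UTR placement). Coding takes precedence whenever
    any CDS base of any overlapping gene is shared.
    """
    if isinstance(genes, AnnotationSet):
        ann = genes
    else:
        ann = AnnotationSet(genes=genes)
    overlapping = _query(ann._gene_trees, mir.chrom, mir.start, mir.end)
    if not overlapping:
        return "intergenic"
    if _query(ann._cds_trees, mir.chrom, mir.start, mir.end):
        return "coding"
    return "noncoding"


def annotate_context(
    mirs: Sequence[MirLocus], annotations: AnnotationSet, strict_chrom: bool = True
) -> list[MirContext]:
    """Annotate every locus with gene/TE/centromere/CNV context.

    With ``strict_chrom`` (default) a locus on a chromosome absent from
    the annotation namespace raises :class:`ChromosomeMismatchError`.
    """
    known = annotations.chromosomes
    contexts = []
    for mir in mirs:
        if strict_chrom and known and mir.chrom not in known:
            raise ChromosomeMismatchError(
                f"{mir.id}: chromosome {mir.chrom!r} not present in annotations"
            )
        tes = _query(annotations._te_trees, mir.chrom, mir.start, mir.end)
        te_overlaps = sorted((t.id, t.superfamily) for t in tes)
        cnv_hits = _query(annotations._cnv_trees, mir.chrom, mir.start, mir.end)
        contained = any(s <= mir.start and mir.end <= e for _, s, e in cnv_hits)
        pseudo = bool(
            _query(_build_trees((c, s, e, None) for _, c, s, e in annotations.pseudogenes),
                   mir.chrom, mir.start, mir.end)
        ) if annotations.pseudogenes else False
        contexts.append(
            MirContext(
                mir_id=mir.id,
                gene_overlap=gene_overlap_class(mir, annotations),
                te_overlaps=te_overlaps,
                in_centromere=bool(_query(annotations._cen_trees, mir.chrom, mir.start, mir.end)),
                in_cnv=bool(cnv_hits),
                cnv_contained=contained,
                pseudogene_overlap=pseudo,
            )
        )
    return contexts


def te_family_enrichment(
    contexts: Sequence[MirContext], annotations: AnnotationSet
) -> pd.DataFrame:
    """Per-superfamily enrichment of MIR-overlapping TEs.

    enrichment(s) = fraction of superfamily *s* among MIR-overlapping
    TEs divided by its fraction among all annotated TEs. A superfamily
    absent genome-wide yields a missing (NaN) ratio, never zero.
    Duplicated TE ids are counted once among the MIR-overlapping set.
    """
    mir_tes: dict[str, str] = {}
    for ctx in contexts:
        for te_id, superfamily in ctx.te_overlaps:
            mir_tes[te_id] = superfamily
    if not mir_tes:
        raise ValueError("no MIR-overlapping TEs: enrichment undefined")
    mir_counts = pd.Series(list(mir_tes.values())).value_counts()
    genome_counts = pd.Series([t.superfamily for t in annotations.tes]).value_counts()
    superfamilies = sorted(set(mir_counts.index) | set(genome_counts.index))
    rows = []
    n_mir = int(mir_counts.sum())
    n_genome = int(genome_counts.sum())
    for s in superfamilies:
        mc = int(mir_counts.get(s, 0))
        gc = int(genome_counts.get(s, 0))
        mir_frac = mc / n_mir
        genome_frac = gc / n_genome if n_genome else float("nan")
        enrichment = mir_frac / genome_frac if gc > 0 else float("nan")
        rows.append({
            "superfamily": s,
            "mir_te_count": mc,
            "mir_te_fraction": mir_frac,
            "genome_te_count": gc,
            "genome_te_fraction": genome_frac,
            "enrichment": enrichment,
        })
    return pd.DataFrame(rows)


def context_table(
    mirs: Sequence[MirLocus], contexts: Sequence[MirContext]
) -> pd.DataFrame:
    """Flatten loci + contexts into the per-MIR context table."""
    by_id = {c.mir_id: c for c in contexts}
    rows = []
    for mir in mirs:
        ctx = by_id[mir.id]
        rows.append({
            "mir_id": mir.id,
            "chrom": mir.chrom,
            "start": mir.start,
            "end": mir.end,
            "strand": mir.strand,
            "family": mir.family,
            "conservation": mir.conservation,
            "gene_overlap": ctx.gene_overlap,
            "te_count": len(ctx.te_overlaps),
            "te_superfamilies": ",".join(sorted({s for _, s in ctx.te_overlaps})),
            "in_centromere": ctx.in_centromere,
            "in_cnv": ctx.in_cnv,
            "cnv_contained": ctx.cnv_contained,
        })
    return pd.DataFrame(rows)


def per_chromosome_counts(mirs: Sequence[MirLocus]) -> pd.DataFrame:
    df = pd.DataFrame({"chrom": [m.chrom for m in mirs]})
    out = df.value_counts("chrom").rename("n_mirs").reset_index()
    return out.sort_values("chrom").reset_index(drop=True)


# --- GFF3 I/O -------------------------------------------------------------

def mirs_to_gff3(mirs: Sequence[MirLocus], path: str | Path) -> None:
    io.write_gff3(
        (
            {
                "seqid": m.chrom, "type": "miRNA_primary_transcript",
                "start": m.start, "end": m.end, "strand": m.strand,
                "attributes": {"ID": m.id, "family": m.family,
                               **({"conservation": m.conservation} if m.conservation else {})},
            }
            for m in mirs
        ),
        path,
    )


def mirs_from_gff3(path: str | Path) -> list[MirLocus]:
    df = io.read_gff3(path)
    df = df[df["type"] == "miRNA_primary_transcript"]
    return [
        MirLocus(
            id=row["ID"], chrom=row["seqid"], start=int(row["start"]),
            end=int(row["end"]), strand=row["strand"], family=row["family"],
            conservation=row.get("conservation") if isinstance(row.get("conservation"), str) else None,
        )
        for _, row in df.iterrows()
    ]


def genes_to_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "seqid": g.chrom, "type": "gene", "start": g.start, "end": g.end,
            "attributes": {"ID": g.id},
        })
        for i, (s, e) in enumerate(g.cds):
            rows.append({
                "seqid": g.chrom, "type": "CDS", "start": s, "end": e,
                "attributes": {"ID": f"{g.id}.cds{i}", "Parent": g.id},
            })
    io.write_gff3(rows, path)


def genes_from_gff3(path: str | Path) -> list[GeneModel]:
    df = io.read_gff3(path)
    genes = {
        row["ID"]: GeneModel(row["ID"], row["seqid"], int(row["start"]), int(row["end"]))
        for _, row in df[df["type"] == "gene"].iterrows()
    }
    for _, row in df[df["type"] == "CDS"].iterrows():
        genes[row["Parent"]].cds.append((int(row["start"]), int(row["end"])))
    return list(genes.values())


def tes_to_gff3(tes: Sequence[TransposableElement], path: str | Path) -> None:
    io.write_gff3(
        (
            {
                "seqid": t.chrom, "type": "transposable_element",
                "start": t.start, "end": t.end,
                "attributes": {"ID": t.id, "superfamily": t.superfamily},
            }
            for t in tes
        ),
        path,
    )


def tes_from_gff3(path: str | Path) -> list[TransposableElement]:
    df = io.read_gff3(path)
    df = df[df["type"] == "transposable_element"]
    return [
        TransposableElement(row["ID"], row["seqid"], int(row["start"]),
                            int(row["end"]), row["superfamily"])
        for _, row in df.iterrows()
    ]
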