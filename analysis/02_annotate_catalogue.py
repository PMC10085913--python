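#!/usr/bin/env python
"""Classify conservation and genomic context of the synthetic catalogue.

Reads the study written by 01_simulate_study.py, classifies each
locus (conserved / nonconserved family / singleton), annotates
gene/TE/centromere/CNV context and computes TE-superfamily
enrichment among locus-overlapping TEs.
"""

from pathlib import Path

import pandas as pd

from mircnv import annotation as ann
from mircnv import io

BASE = Path(__file__).resolve().parent.parent / "results"
STUDY = BASE / "study"
OUT = BASE / "annotation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mirs = ann.mirs_from_gff3(STUDY / "mirs.gff3")
    taxa = ann.FamilyTaxaTable.from_tsv(STUDY / "family_taxa.tsv")
    ann.classify_catalogue(mirs, taxa)
    annotations = ann.AnnotationSet(
        genes=ann.genes_from_gff3(STUDY / "genes.gff3"),
        tes=ann.tes_from_gff3(STUDY / "tes.gff3"),
        centromeres=[tuple(r) for r in
                     io.read_bed3(STUDY / "centromeres.bed").itertuples(index=False)],
        cnv_regions=[tuple(r) for r in
                     io.read_bed3(STUDY / "cnv_regions.bed").itertuples(index=False)],
    )
    contexts = ann.annotate_context(mirs, annotations)
    table = ann.context_table(mirs, contexts)
    io.write_tsv(table, OUT / "mir_contexts.tsv")

    cons = table["conservation"].value_counts()
    print("conservation classes:", cons.to_dict())
    print("gene overlap classes:", table["gene_overlap"].value_counts().to_dict())
    te_assoc = table[table["te_count"] > 0]
    print(f"{len(te_assoc)} loci overlap >=1 TE "
          f"(0 conserved: {int((te_assoc['conservation'] == 'conserved').sum())})")

    enrichment = ann.te_family_enrichment(contexts, annotations)
    io.write_tsv(enrichment, OUT / "te_enrichment.tsv")
    top = enrichment.sort_values("enrichment", ascending=False).iloc[0]
    print(f"most enriched TE superfamily among locus-overlapping TEs: "
          f"{top['superfamily']} ({top['enrichment']:.2f}x genome-wide)")

    io.write_tsv(ann.per_chromosome_counts(mirs), OUT / "per_chromosome.tsv")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
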