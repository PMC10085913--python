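import numpy as np
import pandas as pd
import pytest

from mircnv import synthetic
from mircnv.annotation import (AnnotationSet, FamilyTaxaTable, GeneModel,
                               MirLocus, TransposableElement)
from mircnv.config import PipelineConfig
from mircnv.pipeline import run_genotyping

COHORT_SEED = 20230410


@pytest.fixture(scope="session")
def cohort_study():
    """Default genotyping cohort: 200 accessions x 50 clean regions, 20x."""
    return synthetic.simulate_cohort(seed=COHORT_SEED, n_accessions=200,
                                     n_regions=50, lam=20.0)


@pytest.fixture(scope="session")
def cohort_result(cohort_study):
    return run_genotyping(cohort_study)


@pytest.fixture(scope="session")
def small_study():
    """Small full-featured study (repeats, masked locus, MLPA, expression)."""
    return synthetic.simulate_study(
        seed=7, genome_length=120_000, n_conserved=6, n_nonconserved=6,
        n_singleton=6, n_overlapping_pairs=2, n_accessions=40,
        n_mlpa_samples=24, n_null_genes=40,
    )


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def taxa_table():
    return FamilyTaxaTable(pd.DataFrame([
        {"family": "MIR166", "outside_brassicaceae": True,
         "brassicaceae_beyond_athaliana": True, "members_in_athaliana": 7},
        {"family": "MIR5645", "outside_brassicaceae": False,
         "brassicaceae_beyond_athaliana": True, "members_in_athaliana": 6},
        {"family": "MIR5998", "outside_brassicaceae": False,
         "brassicaceae_beyond_athaliana": False, "members_in_athaliana": 2},
        {"family": "MIR854x", "outside_brassicaceae": False,
         "brassicaceae_beyond_athaliana": False, "members_in_athaliana": 1},
    ]))


@pytest.fixture
def simple_annotations():
    genes = [
        GeneModel("G1", "chr1", 50, 400, cds=[(150, 300)]),
        GeneModel("G2", "chr1", 500, 900, cds=[(600, 800)]),
        GeneModel("G3", "chr1", 1000, 2000, cds=[(1600, 1900)]),  # intronic slot
    ]
    tes = [
        TransposableElement("T1", "chr1", 90, 260, "DNA/MuDR"),
        TransposableElement("T2", "chr1", 200, 350, "RC/Helitron"),
        TransposableElement("T3", "chr1", 3000, 3400, "LTR/Gypsy"),
        TransposableElement("T4", "chr1", 5000, 5600, "LTR/Copia"),
    ]
    return AnnotationSet(
        genes=genes, tes=tes,
        centromeres=[("chr1", 2500, 4000)],
        cnv_regions=[("chr1", 80, 500), ("chr1", 6000, 7000)],
    )


def make_mir(id="syn-MIRx", chrom="chr1", start=100, end=220, strand="+",
             family="MIRx", conservation=None):
    return MirLocus(id=id, chrom=chrom, start=start, end=end, strand=strand,
                    family=family, conservation=conservation)
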