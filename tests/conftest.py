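"""Shared fixtures: a hand-built annotation playground and a session-scoped
default synthetic study (fixture -> pool -> cohort -> trained bundle)."""

from __future__ import annotations

import numpy as np
import pytest

from ncboost.annotate import GeneIndex
from ncboost.pipeline import build_pool, run_training_pipeline
from ncboost.simulate import FixtureSpec, build_fixture
from ncboost.types import (
    NONCODING_RNA,
    PROTEIN_CODING,
    GeneModel,
    Transcript,
    VariantRecord,
)

SEED = 1


def make_variant(chrom: str, pos: int, **kw) -> VariantRecord:
    kw.setdefault("ref", "A")
    kw.setdefault("alt", "G")
    return VariantRecord(chrom=chrom, pos=pos, **kw)


@pytest.fixture(scope="session")
def toy_genes():
    """Hand-built gene set covering every annotation corner case.

    chrT layout:
      gene A (+, coding): exons (10000-10400), (10800-11200), (11600-12000);
        CDS 10200-11800 -> UTR5 10000-10199, UTR3 11801-12000
      ncRNA N1: single exon 10450-10550 inside intron 1 of A
      gene C (+, coding): hull 20000-21000 (single exon CDS 20100-20900)
      gene D (+, coding): hull 23002-24002 -> midpoint 22001 equidistant to C/D
      gene E (-, coding): hull 30000-32000, so TSS=32000 and TSE=30000
      ncRNA F: exons (40000-40100), (40250-40350) (standalone, two-exon)
    """
    a = GeneModel(
        "A", "A", "chrT", "+", PROTEIN_CODING,
        (
            Transcript(
                "A.t1", 10000, 12000,
                ((10000, 10400), (10800, 11200), (11600, 12000)),
                cds_start=10200, cds_end=11800,
            ),
        ),
    )
    n1 = GeneModel(
        "N1", "N1", "chrT", "+", NONCODING_RNA,
        (Transcript("N1.t1", 10450, 10550, ((10450, 10550),)),),
    )
    c = GeneModel(
        "C", "C", "chrT", "+", PROTEIN_CODING,
        (Transcript("C.t1", 20000, 21000, ((20000, 21000),), 20100, 20900),),
    )
    d = GeneModel(
        "D", "D", "chrT", "+", PROTEIN_CODING,
        (Transcript("D.t1", 23002, 24002, ((23002, 24002),), 23102, 23902),),
    )
    e = GeneModel(
        "E", "E", "chrT", "-", PROTEIN_CODING,
        (
            Transcript(
                "E.t1", 30000, 32000,
                ((30000, 30500), (31000, 32000)),
                cds_start=30200, cds_end=31800,
            ),
        ),
    )
    f = GeneModel(
        "F", "F", "chrT", "+", NONCODING_RNA,
        (Transcript("F.t1", 40000, 40350, ((40000, 40100), (40250, 40350)),),),
    )
    return [a, n1, c, d, e, f]


@pytest.fixture(scope="session")
def toy_index(toy_genes):
    return GeneIndex(toy_genes)


#: Engineered precedence / conflicting / splicing cases: (pos, expected
#: region, expected gene or None).
ENGINEERED_CASES = [
    (10250, "exonic", "A"),          # inside CDS
    (10405, "splicing", "A"),        # 5 bp into intron 1 from the exon boundary
    (10100, "UTR5", "A"),            # 5' UTR exon part
    (11900, "UTR3", "A"),            # 3' UTR exon part
    (10700, "intronic", "A"),        # deep intron, outside N1
    (10500, "ncRNA_exonic", "N1"),   # ncRNA exon inside a coding intron
    (9750, "upstream", "A"),         # 250 bp 5' of a + strand TSS
    (12500, "downstream", "A"),      # 500 bp 3' of a + strand TSE
    (22001, "conflicting", None),    # exactly equidistant to C and D
    (29001, "downstream", "E"),      # 999 bp past a - strand TSE
    (32500, "upstream", "E"),        # 500 bp 5' of a - strand TSS
    (40105, "ncRNA_splicing", "F"),  # 5 bp into the ncRNA intron
]


@pytest.fixture(scope="session")
def default_fixture():
    return build_fixture(FixtureSpec(seed=SEED))


@pytest.fixture(scope="session")
def pools(default_fixture):
    common, rare, tally = build_pool(default_fixture)
    return {"common": common, "rare": rare, "tally": tally}


@pytest.fixture(scope="session")
def pipeline_result(default_fixture, pools):
    return run_training_pipeline(
        default_fixture, common_pool=pools["common"], seed=SEED
    )
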