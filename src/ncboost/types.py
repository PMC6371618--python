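"""Core domain types: gene models, variant records and annotated variants.

Coordinates are 1-based and fully closed throughout (VCF convention); gene
model input files in other dialects are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

NUCLEOTIDES = frozenset("ACGT")

PROTEIN_CODING = "protein_coding"
NONCODING_RNA = "noncoding_rna"

#: The six region classes retained for scoring (all relative to a
#: protein-coding gene).
RETAINED_REGIONS = ("intronic", "UTR5", "UTR3", "upstream", "downstream", "intergenic")

#: Region classes that lead to exclusion from the non-coding variant set.
EXCLUSION_REGIONS = (
    "exonic",
    "splicing",
    "ncRNA_exonic",
    "ncRNA_intronic",
    "ncRNA_splicing",
    "ncRNA_flank",
    "conflicting",
)


class GeneModelError(ValueError):
    """Raised for structurally invalid gene models."""


@dataclass(frozen=True)
class Transcript:
    """A transcript with exon structure and an optional CDS.

    ``exons`` are (start, end) closed intervals sorted by start and pairwise
    non-overlapping; ``cds_start``/``cds_end`` are genomic coordinates
    (``cds_start`` <= ``cds_end`` irrespective of strand) or ``None`` for
    non-coding transcripts.
    """

    tx_id: str
    tx_start: int
    tx_end: int
    exons: Tuple[Tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def validate(self) -> None:
        if self.tx_start > self.tx_end:
            raise GeneModelError(f"{self.tx_id}: tx_start > tx_end")
        if not self.exons:
            raise GeneModelError(f"{self.tx_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise GeneModelError(f"{self.tx_id}: exon start > end")
            if s < self.tx_start or e > self.tx_end:
                raise GeneModelError(f"{self.tx_id}: exon outside transcript span")
            if prev_end is not None and s <= prev_end:
                raise GeneModelError(f"{self.tx_id}: exons unsorted or overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise GeneModelError(f"{self.tx_id}: half-specified CDS")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
                raise GeneModelError(f"{self.tx_id}: CDS outside transcript span")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts on a single strand."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str  # "+" or "-"
    biotype: str  # PROTEIN_CODING or NONCODING_RNA
    transcripts: Tuple[Transcript, ...]

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in (PROTEIN_CODING, NONCODING_RNA):
            raise GeneModelError(f"{self.gene_id}: bad biotype {self.biotype!r}")
        if not self.transcripts:
            raise GeneModelError(f"{self.gene_id}: no transcripts")
        for tx in self.transcripts:
            tx.validate()
            if self.biotype == NONCODING_RNA and tx.is_coding:
                raise GeneModelError(f"{self.gene_id}: non-coding RNA with a CDS")

    @property
    def start(self) -> int:
        """5'-agnostic leftmost coordinate across transcripts."""
        return min(tx.tx_start for tx in self.transcripts)

    @property
    def end(self) -> int:
        return max(tx.tx_end for tx in self.transcripts)

    @property
    def tss(self) -> int:
        """Gene-extremal transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tse(self) -> int:
        """Gene-extremal transcription end site (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    @property
    def is_coding(self) -> bool:
        return self.biotype == PROTEIN_CODING


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic single-nucleotide variant, optionally with population data.

    ``maf`` is the global minor allele frequency folded to [0, 0.5];
    ``maf_by_pop`` holds per-population folded frequencies; ``daf`` is the
    derived allele frequency in [0, 1]; ``common_flag`` mirrors the dbSNP
    COMMON annotation used to classify common vs rare variants.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""
    maf: Optional[float] = None
    maf_by_pop: Optional[Mapping[str, float]] = None
    daf: Optional[float] = None
    hom_carriers: Optional[int] = None
    common_flag: Optional[bool] = None
    source: str = ""

    def validate(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"{self.key}: ref/alt must be single bases of ACGT")
        if self.ref == self.alt:
            raise ValueError(f"{self.key}: ref == alt")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.key}: MAF {self.maf} outside [0, 0.5]")

    @property
    def key(self) -> str:
        """Stable identifier: explicit id when given, else coordinates."""
        return self.id or f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant with its resolved region class and associated gene.

    ``region`` is one of the six retained classes or an exclusion class;
    ``gene_id`` is absent only for ``conflicting`` variants; ``distance_bp``
    is 0 for intragenic variants, otherwise the unsigned distance to the
    nearer of the gene's TSS/TSE.
    """

    variant: VariantRecord
    region: str
    gene_id: Optional[str]
    distance_bp: int

    @property
    def key(self) -> str:
        return self.variant.key

    @property
    def is_retained(self) -> bool:
        return self.region in RETAINED_REGIONS
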