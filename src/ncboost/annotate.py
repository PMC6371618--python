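"""Region classification of SNVs against gene models.

Implements a gene-based annotator in the RefSeq style: each variant is
classified against every nearby gene, candidate labels are resolved through
the precedence rule

    exonic = splicing > ncRNA > UTR5 = UTR3 > intronic
           > upstream = downstream > intergenic

and remaining gene ties are broken by the shortest unsigned distance to
either the TSS or the TSE.  Exact distance ties across two or more genes are
tagged ``conflicting``.  Exonic and splice-site variants of protein-coding
genes, and all variants whose winning label involves a non-coding RNA, are
excluded from the retained non-coding set.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .types import (
    NONCODING_RNA,
    RETAINED_REGIONS,
    AnnotatedVariant,
    GeneModel,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: Lower tier number = higher precedence.
PRECEDENCE_TIER = {
    "exonic": 0,
    "splicing": 0,
    "ncRNA_exonic": 1,
    "ncRNA_intronic": 1,
    "ncRNA_splicing": 1,
    "UTR5": 2,
    "UTR3": 2,
    "intronic": 3,
    "upstream": 4,
    "downstream": 4,
    "ncRNA_flank": 4,
    "intergenic": 5,
}

#: Deterministic preference when one gene earns several labels of the same
#: tier (rare; e.g. the exonic side of a splice junction).
_LABEL_ORDER = [
    "exonic",
    "splicing",
    "ncRNA_exonic",
    "ncRNA_splicing",
    "ncRNA_intronic",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
    "ncRNA_flank",
    "intergenic",
]
_LABEL_RANK = {lab: i for i, lab in enumerate(_LABEL_ORDER)}

_NC_PREFIX = {
    "exonic": "ncRNA_exonic",
    "intronic": "ncRNA_intronic",
    "splicing": "ncRNA_splicing",
    "upstream": "ncRNA_flank",
    "downstream": "ncRNA_flank",
}


def distance_to_gene(pos: int, gene: GeneModel) -> int:
    """Unsigned bp distance to the nearer of TSS/TSE; 0 if intragenic."""
    if gene.start <= pos <= gene.end:
        return 0
    return min(abs(pos - gene.start), abs(pos - gene.end))


def classify_against_gene(
    variant: VariantRecord,
    gene: GeneModel,
    splicing_threshold: int = 10,
    flank: int = 1000,
) -> Set[str]:
    """Return every region label the variant earns against one gene.

    Labels for non-coding RNA genes are mapped onto the ``ncRNA_*`` classes;
    flanking labels are strand-aware (upstream = 5' of the TSS).  A variant
    more than ``flank`` bp outside the gene earns no label.  A chromosome
    mismatch yields an empty set.
    """
    gene.validate()
    if variant.chrom != gene.chrom:
        return set()
    pos = variant.pos
    labels: Set[str] = set()

    for tx in gene.transcripts:
        if not (tx.tx_start <= pos <= tx.tx_end):
            continue
        # Internal exon boundaries are splice junctions; transcript termini
        # are not.
        n = len(tx.exons)
        for i, (s, e) in enumerate(tx.exons):
            if i > 0 and abs(pos - s) <= splicing_threshold:
                labels.add("splicing")
            if i < n - 1 and abs(pos - e) <= splicing_threshold:
                labels.add("splicing")
        in_exon = any(s <= pos <= e for s, e in tx.exons)
        if in_exon:
            if tx.is_coding:
                if pos < tx.cds_start:
                    labels.add("UTR5" if gene.strand == "+" else "UTR3")
                elif pos > tx.cds_end:
                    labels.add("UTR3" if gene.strand == "+" else "UTR5")
                else:
                    labels.add("exonic")
            else:
                labels.add("exonic")
        else:
            labels.add("intronic")

    if not labels and gene.start <= pos <= gene.end:
        # Inside the gene hull but covered by no transcript (multi-transcript
        # gap): treat as intronic at the gene level.
        labels.add("intronic")

    if not labels:
        # Flanking regions, measured from the gene-extremal TSS/TSE.
        if gene.strand == "+":
            if gene.start - flank <= pos < gene.start:
                labels.add("upstream")
            elif gene.end < pos <= gene.end + flank:
                labels.add("downstream")
        else:
            if gene.end < pos <= gene.end + flank:
                labels.add("upstream")
            elif gene.start - flank <= pos < gene.start:
                labels.add("downstream")

    if gene.biotype == NONCODING_RNA:
        labels = {_NC_PREFIX[lab] for lab in labels}
    return labels


class GeneIndex:
    """Chromosome-indexed collection of gene models for fast lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: List[GeneModel] = list(genes)
        if not self.genes:
            raise ValueError("empty gene collection")
        for g in self.genes:
            g.validate()
        self._by_chrom: Dict[str, List[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._coding_mask: Dict[str, np.ndarray] = {}
        self._max_len: Dict[str, int] = {}
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
            self._starts[chrom] = np.array([g.start for g in gs], dtype=np.int64)
            self._ends[chrom] = np.array([g.end for g in gs], dtype=np.int64)
            self._coding_mask[chrom] = np.array([g.is_coding for g in gs], dtype=bool)
            self._max_len[chrom] = max(g.end - g.start + 1 for g in gs)

    @property
    def chromosomes(self) -> Set[str]:
        return set(self._by_chrom)

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def candidates(self, chrom: str, pos: int, flank: int) -> List[GeneModel]:
        """Genes whose hull extended by ``flank`` covers ``pos``."""
        gs = self._by_chrom.get(chrom)
        if not gs:
            return []
        starts = self._starts[chrom]
        lo = int(np.searchsorted(starts, pos - flank - self._max_len[chrom], "left"))
        hi = int(np.searchsorted(starts, pos + flank, "right"))
        return [
            g
            for g in gs[lo:hi]
            if g.start - flank <= pos <= g.end + flank
        ]

    def nearest_coding(self, chrom: str, pos: int) -> Tuple[List[GeneModel], int]:
        """Nearest protein-coding gene(s) on a chromosome and their distance.

        Returns every gene at the minimal distance (more than one on an
        exact tie).
        """
        gs = self._by_chrom.get(chrom)
        if not gs:
            return [], -1
        starts, ends = self._starts[chrom], self._ends[chrom]
        d = np.maximum(0, np.maximum(starts - pos, pos - ends))
        d = np.where(self._coding_mask[chrom], d, np.iinfo(np.int64).max)
        if not self._coding_mask[chrom].any():
            return [], -1
        dmin = int(d.min())
        return [gs[i] for i in np.flatnonzero(d == dmin)], dmin


def annotate_variant(
    variant: VariantRecord,
    genes: GeneIndex,
    splicing_threshold: int = 10,
    flank: int = 1000,
) -> Optional[AnnotatedVariant]:
    """Resolve the region class and associated gene of one variant.

    Returns ``None`` (with a logged warning) for variants on chromosomes
    carrying no annotated genes: no nearest gene exists there and the
    downstream feature set requires one.
    """
    if variant.chrom not in genes.chromosomes:
        logger.warning(
            "variant %s on chromosome without annotated genes; dropped", variant.key
        )
        return None

    candidates: List[Tuple[int, str, GeneModel, int]] = []
    for gene in genes.candidates(variant.chrom, variant.pos, flank):
        for label in classify_against_gene(variant, gene, splicing_threshold, flank):
            candidates.append(
                (
                    PRECEDENCE_TIER[label],
                    label,
                    gene,
                    distance_to_gene(variant.pos, gene),
                )
            )

    if not candidates:
        near, dist = genes.nearest_coding(variant.chrom, variant.pos)
        if not near:
            logger.warning(
                "variant %s: no protein-coding gene on chromosome; dropped",
                variant.key,
            )
            return None
        if len(near) > 1:
            return AnnotatedVariant(variant, "conflicting", None, dist)
        return AnnotatedVariant(variant, "intergenic", near[0].gene_id, dist)

    best_tier = min(t for t, _, _, _ in candidates)
    tier_cands = [c for c in candidates if c[0] == best_tier]
    # Criterion B favours the nearest *protein-coding* gene when both coding
    # and non-coding genes are tied at the winning tier.
    if any(c[2].is_coding for c in tier_cands):
        tier_cands = [c for c in tier_cands if c[2].is_coding]

    by_gene: Dict[str, Tuple[str, GeneModel, int]] = {}
    for _, label, gene, dist in tier_cands:
        prev = by_gene.get(gene.gene_id)
        if prev is None or _LABEL_RANK[label] < _LABEL_RANK[prev[0]]:
            by_gene[gene.gene_id] = (label, gene, dist)

    dmin = min(dist for _, _, dist in by_gene.values())
    winners = [v for v in by_gene.values() if v[2] == dmin]
    if len(winners) > 1:
        return AnnotatedVariant(variant, "conflicting", None, dmin)
    label, gene, dist = winners[0]
    return AnnotatedVariant(variant, label, gene.gene_id, dist)


def annotate_variants(
    variants: Iterable[VariantRecord],
    genes: GeneIndex,
    splicing_threshold: int = 10,
    flank: int = 1000,
) -> List[AnnotatedVariant]:
    """Annotate a collection, silently dropping gene-less chromosomes."""
    out = []
    for v in variants:
        av = annotate_variant(v, genes, splicing_threshold, flank)
        if av is not None:
            out.append(av)
    return out


def filter_noncoding(
    annotated: Sequence[AnnotatedVariant],
) -> Tuple[List[AnnotatedVariant], Dict[str, int]]:
    """Split annotated variants into the retained non-coding set and a tally
    of exclusions per region class."""
    retained: List[AnnotatedVariant] = []
    tally: Counter = Counter()
    for av in annotated:
        if av.region in RETAINED_REGIONS:
            retained.append(av)
        else:
            tally[av.region] += 1
    return retained, dict(tally)
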