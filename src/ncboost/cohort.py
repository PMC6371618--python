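"""Cohort construction: positive curation, allele-frequency classes,
gene partitioning and region-matched negative sampling.

The training design pairs each pathogenic variant with a fixed number of
common variants drawn from the same region class and from genes of the same
genome partition, with at most one positive and one negative variant per
gene, so that the downstream per-partition models can be scored without any
gene-level contamination.
"""

from __future__ import annotations

import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .types import AnnotatedVariant, VariantRecord

logger = logging.getLogger(__name__)


class CohortSamplingError(RuntimeError):
    """Raised when a (region, partition) cell lacks the pool depth required
    for matched-negative sampling."""


def classify_allele_frequency(v: VariantRecord) -> str:
    """Classify a panel variant as ``common``, ``rare`` or ``excluded``.

    Common requires the COMMON flag set and MAF > 0.05; rare requires the
    flag unset and MAF < 0.01; everything else (no MAF, or neither rule
    firing) is excluded.
    """
    if v.maf is None or v.common_flag is None:
        return "excluded"
    if v.common_flag and v.maf > 0.05:
        return "common"
    if not v.common_flag and v.maf < 0.01:
        return "rare"
    return "excluded"


@dataclass
class CurationTables:
    """Lookup tables backing positive-set curation.

    Absent entries fail closed: a variant missing from a table fails the
    corresponding filter and is counted separately in the audit.
    """

    source_gene: Mapping[str, str]
    mendelian_class: Mapping[str, str]  # gene_id -> monogenic | complex | non_mendelian
    phenotype_consistent: Mapping[str, bool]
    hom_carriers: Mapping[str, int]


#: Fixed curation filter order (the audit is reproducible only with a fixed
#: order).
CURATION_STEPS = (
    "gene_agreement",
    "mendelian_monogenic",
    "phenotype_consistent",
    "homozygous_carriers",
)


def curate_positives(
    candidates: Sequence[AnnotatedVariant],
    tables: CurationTables,
) -> Tuple[List[AnnotatedVariant], "OrderedDict[str, int]"]:
    """Apply the positive-set curation filters in fixed order.

    Filters: (1) the annotation gene must agree with the source's claimed
    gene; (2) the gene must be a monogenic Mendelian disease gene; (3) the
    reported phenotype must be consistent; (4) no homozygous carriers in the
    population database.  Returns the retained set and per-filter removal
    counts (missing-table entries counted under ``<step>_missing``).
    """
    audit: "OrderedDict[str, int]" = OrderedDict()
    for step in CURATION_STEPS:
        audit[step] = 0
        audit[f"{step}_missing"] = 0
    retained: List[AnnotatedVariant] = []
    for av in candidates:
        key = av.key
        fate = None
        sg = tables.source_gene.get(key)
        if sg is None:
            fate = "gene_agreement_missing"
        elif sg != av.gene_id:
            fate = "gene_agreement"
        if fate is None:
            mc = tables.mendelian_class.get(av.gene_id)
            if mc is None:
                fate = "mendelian_monogenic_missing"
            elif mc != "monogenic":
                fate = "mendelian_monogenic"
        if fate is None:
            pc = tables.phenotype_consistent.get(key)
            if pc is None:
                fate = "phenotype_consistent_missing"
            elif not pc:
                fate = "phenotype_consistent"
        if fate is None:
            hc = tables.hom_carriers.get(key)
            if hc is None:
                fate = "homozygous_carriers_missing"
            elif hc > 0:
                fate = "homozygous_carriers"
        if fate is None:
            retained.append(av)
        else:
            audit[fate] += 1
    return retained, audit


def dedupe_one_per_gene(
    positives: Sequence[AnnotatedVariant], seed: int
) -> List[AnnotatedVariant]:
    """Randomly keep exactly one positive per gene (seeded, deterministic)."""
    rng = np.random.default_rng(seed)
    by_gene: Dict[str, List[AnnotatedVariant]] = {}
    for av in sorted(positives, key=lambda a: a.key):
        by_gene.setdefault(av.gene_id, []).append(av)
    kept = []
    for gene in sorted(by_gene):
        group = by_gene[gene]
        kept.append(group[int(rng.integers(len(group)))])
    kept.sort(key=lambda a: (a.variant.chrom, a.variant.pos, a.key))
    return kept


@dataclass
class GenomePartition:
    """Random split of the protein-coding gene universe into k partitions,
    stratified by chromosome and by positive-gene status."""

    k: int
    assignment: Dict[str, int]  # gene_id -> partition index in 1..k
    seed: int

    def of(self, gene_id: str) -> Optional[int]:
        return self.assignment.get(gene_id)

    def genes_in(self, index: int) -> Set[str]:
        return {g for g, p in self.assignment.items() if p == index}

    def to_dict(self) -> dict:
        return {"k": self.k, "seed": self.seed, "assignment": self.assignment}

    @classmethod
    def from_dict(cls, d: dict) -> "GenomePartition":
        return cls(int(d["k"]), {g: int(p) for g, p in d["assignment"].items()}, int(d["seed"]))


def partition_genes(
    genes: Iterable[Tuple[str, str]],
    positive_genes: Set[str],
    k: int = 10,
    seed: int = 0,
) -> GenomePartition:
    """Stratified random gene-to-partition assignment.

    ``genes`` is an iterable of (gene_id, chrom).  Within each chromosome
    and within each {positive, non-positive} stratum, genes are spread
    across partitions as evenly as integer division allows; remainders are
    dealt greedily to the partitions with the smallest running stratum
    totals, which keeps the global positive-gene counts within one of each
    other.  The input order is irrelevant: genes are canonically sorted
    before shuffling.
    """
    gene_list = sorted(set(genes))
    ids = {g for g, _ in gene_list}
    if len(ids) != len(gene_list):
        raise ValueError("a gene_id maps to more than one chromosome")
    unknown = positive_genes - ids
    if unknown:
        raise ValueError(f"positive genes absent from gene list: {sorted(unknown)[:5]}")
    if k > len(gene_list):
        raise ValueError(f"k={k} exceeds the number of genes ({len(gene_list)})")
    rng = np.random.default_rng(seed)
    assignment: Dict[str, int] = {}
    for stratum_positive in (True, False):
        load = np.zeros(k, dtype=np.int64)
        chroms = sorted({c for _, c in gene_list})
        for chrom in chroms:
            members = [
                g
                for g, c in gene_list
                if c == chrom and ((g in positive_genes) == stratum_positive)
            ]
            if not members:
                continue
            members = list(np.array(members)[rng.permutation(len(members))])
            q, r = divmod(len(members), k)
            order = np.lexsort((rng.random(k), load))
            extras = set(order[:r].tolist())
            slots: List[int] = []
            for p in range(k):
                slots.extend([p] * (q + (1 if p in extras else 0)))
            slots = list(np.array(slots)[rng.permutation(len(slots))])
            for g, p in zip(members, slots):
                assignment[g] = p + 1
                load[p] += 1
    return GenomePartition(k, assignment, seed)


@dataclass
class TrainingCohort:
    """Positives and matched negatives with their pairing and audit trail."""

    positives: List[AnnotatedVariant]
    negatives: List[AnnotatedVariant]
    pairing: Dict[str, List[str]]  # positive key -> negative keys
    region_fractions: Dict[str, float] = field(default_factory=dict)

    @property
    def rows(self) -> List[Tuple[AnnotatedVariant, int]]:
        return [(av, 1) for av in self.positives] + [(av, 0) for av in self.negatives]

    def region_counts(self, label: int) -> Counter:
        group = self.positives if label == 1 else self.negatives
        return Counter(av.region for av in group)


def sample_matched_negatives(
    positives: Sequence[AnnotatedVariant],
    pool: Sequence[AnnotatedVariant],
    partition: GenomePartition,
    ratio: int = 10,
    seed: int = 0,
) -> TrainingCohort:
    """For each positive, draw ``ratio`` negatives without replacement from
    pool variants of the same region class whose genes lie in the same
    genome partition.

    At most one negative per gene across the whole cohort; no pool variant
    is ever reused between positives.  When a (region, partition) cell lacks
    depth the builder fails loudly rather than borrowing from other
    partitions.
    """
    pos_genes = Counter(av.gene_id for av in positives)
    dup = [g for g, n in pos_genes.items() if n > 1]
    if dup:
        raise ValueError(f"more than one positive per gene: {dup[:5]}")
    for av in positives:
        if partition.of(av.gene_id) is None:
            raise ValueError(f"positive gene {av.gene_id} absent from partition")

    cells: Dict[Tuple[str, int], Dict[str, List[AnnotatedVariant]]] = {}
    for nv in pool:
        p = partition.of(nv.gene_id)
        if p is None:
            continue
        cells.setdefault((nv.region, p), {}).setdefault(nv.gene_id, []).append(nv)

    rng = np.random.default_rng(seed)
    used_genes: Set[str] = set()
    used_variants: Set[str] = set()
    negatives: List[AnnotatedVariant] = []
    pairing: Dict[str, List[str]] = {}
    for pos in sorted(positives, key=lambda a: a.key):
        cell_key = (pos.region, partition.of(pos.gene_id))
        cell = cells.get(cell_key, {})
        eligible_genes = sorted(
            g
            for g, vs in cell.items()
            if g not in used_genes and any(v.key not in used_variants for v in vs)
        )
        if len(eligible_genes) < ratio:
            raise CohortSamplingError(
                f"cell (region={cell_key[0]}, partition={cell_key[1]}) has "
                f"{len(eligible_genes)} eligible genes; {ratio} required "
                f"(deficit {ratio - len(eligible_genes)}) for positive {pos.key}"
            )
        chosen_genes = rng.choice(eligible_genes, size=ratio, replace=False)
        pairing[pos.key] = []
        for g in sorted(chosen_genes):
            options = sorted(
                (v for v in cell[g] if v.key not in used_variants),
                key=lambda v: v.key,
            )
            nv = options[int(rng.integers(len(options)))]
            negatives.append(nv)
            pairing[pos.key].append(nv.key)
            used_genes.add(g)
            used_variants.add(nv.key)

    n = len(positives)
    fractions = {r: c / n for r, c in Counter(a.region for a in positives).items()}
    cohort = TrainingCohort(list(positives), negatives, pairing, fractions)
    violations = audit_cohort(cohort, partition, ratio)
    if violations:
        raise AssertionError(f"cohort invariants violated: {violations}")
    return cohort


def audit_cohort(
    cohort: TrainingCohort, partition: GenomePartition, ratio: int
) -> List[str]:
    """Independent re-verification of the cohort invariants; returns a list
    of violation descriptions (empty when the cohort is sound)."""
    problems: List[str] = []
    pos_by_key = {a.key: a for a in cohort.positives}
    neg_by_key = {a.key: a for a in cohort.negatives}
    if any(n > 1 for n in Counter(a.gene_id for a in cohort.positives).values()):
        problems.append("more than one positive per gene")
    if any(n > 1 for n in Counter(a.gene_id for a in cohort.negatives).values()):
        problems.append("more than one negative per gene")
    if len(neg_by_key) != len(cohort.negatives):
        problems.append("a negative variant reused")
    pos_counts = cohort.region_counts(1)
    neg_counts = cohort.region_counts(0)
    for region, c in pos_counts.items():
        if neg_counts.get(region, 0) != ratio * c:
            problems.append(
                f"region {region}: {neg_counts.get(region, 0)} negatives for {c} positives"
            )
    for pkey, nkeys in cohort.pairing.items():
        p = pos_by_key[pkey]
        for nk in nkeys:
            nv = neg_by_key[nk]
            if nv.region != p.region:
                problems.append(f"pair {pkey}/{nk}: region mismatch")
            if partition.of(nv.gene_id) != partition.of(p.gene_id):
                problems.append(f"pair {pkey}/{nk}: partition mismatch")
    return problems


def sample_region_context_pairs(
    positives: Sequence[AnnotatedVariant],
    pool: Sequence[AnnotatedVariant],
    seed: int = 0,
) -> List[Tuple[AnnotatedVariant, AnnotatedVariant]]:
    """Pair each positive with one pool variant from the same gene AND the
    same region class; positives with no eligible match are dropped with a
    log message.  Multiple pairs per gene are allowed in this mode."""
    rng = np.random.default_rng(seed)
    by_gene_region: Dict[Tuple[str, str], List[AnnotatedVariant]] = {}
    for nv in pool:
        by_gene_region.setdefault((nv.gene_id, nv.region), []).append(nv)
    pairs = []
    for pos in sorted(positives, key=lambda a: a.key):
        options = [
            v
            for v in by_gene_region.get((pos.gene_id, pos.region), [])
            if (v.variant.chrom, v.variant.pos) != (pos.variant.chrom, pos.variant.pos)
        ]
        if not options:
            logger.info(
                "positive %s (%s/%s): no region-matched pool variant; dropped",
                pos.key,
                pos.gene_id,
                pos.region,
            )
            continue
        options.sort(key=lambda v: v.key)
        pairs.append((pos, options[int(rng.integers(len(options)))]))
    return pairs
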