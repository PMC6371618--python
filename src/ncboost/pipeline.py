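"""End-to-end orchestration on a fixture: annotate the panel, build the
region-matched cohort, assemble features, train the partitioned bundle and
run the benchmark designs.

The held-out benchmark mirrors a tenfold cross-validation: every cohort
variant is scored by the one bundle member whose training excluded the
variant's gene partition, so the AUROC/AUPRC are computed on scores that are
leakage-free by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotate import annotate_variants, filter_noncoding
from .boost import (
    BoostingParams,
    NCBoostBundle,
    audit_leakage,
    cross_model_correlation,
    score_variants,
    train_bundle,
)
from .cohort import (
    GenomePartition,
    TrainingCohort,
    classify_allele_frequency,
    dedupe_one_per_gene,
    partition_genes,
    sample_matched_negatives,
    sample_region_context_pairs,
)
from .evaluate import BenchmarkResult, roc_pr, run_spike_in_experiment
from .features import assemble_matrix
from .simulate import FixtureBundle, FixtureSpec, build_fixture, panel_variant_records
from .types import AnnotatedVariant

logger = logging.getLogger(__name__)


def build_pool(
    fixture: FixtureBundle,
) -> Tuple[List[AnnotatedVariant], List[AnnotatedVariant], Dict[str, int]]:
    """Annotate the population panel and split it into the retained common
    and rare pools (with the exclusion tally)."""
    records = panel_variant_records(fixture.panel)
    annotated = annotate_variants(records, fixture.gene_index)
    retained, tally = filter_noncoding(annotated)
    common = [av for av in retained if classify_allele_frequency(av.variant) == "common"]
    rare = [av for av in retained if classify_allele_frequency(av.variant) == "rare"]
    return common, rare, tally


def build_cohort(
    fixture: FixtureBundle,
    common_pool: Sequence[AnnotatedVariant],
    k: int = 10,
    seed: int = 0,
) -> Tuple[TrainingCohort, GenomePartition]:
    """One positive per gene, k-way gene partition, 1:ratio region- and
    partition-matched negatives."""
    positives = dedupe_one_per_gene(fixture.positives, seed)
    partition = partition_genes(
        fixture.coding_gene_universe,
        {av.gene_id for av in positives},
        k=k,
        seed=seed,
    )
    cohort = sample_matched_negatives(
        positives, common_pool, partition, ratio=fixture.spec.neg_ratio, seed=seed
    )
    return cohort, partition


def cohort_features(
    fixture: FixtureBundle, cohort: TrainingCohort, config: str = "ABCD"
) -> Tuple[pd.DataFrame, np.ndarray, List[str]]:
    rows = cohort.rows
    avs = [av for av, _ in rows]
    y = np.array([label for _, label in rows], dtype=int)
    X = assemble_matrix(
        avs,
        config,
        panel=fixture.panel,
        tracks=fixture.tracks,
        gene_table=fixture.gene_table,
        reference=fixture.reference,
    )
    genes = [av.gene_id for av in avs]
    return X, y, genes


@dataclass
class PipelineResult:
    fixture: FixtureBundle
    cohort: TrainingCohort
    partition: GenomePartition
    X: pd.DataFrame
    y: np.ndarray
    genes: List[str]
    bundle: NCBoostBundle
    scored: pd.DataFrame
    benchmark: BenchmarkResult
    leakage_violations: int


def run_training_pipeline(
    fixture: FixtureBundle,
    common_pool: Optional[Sequence[AnnotatedVariant]] = None,
    config: str = "ABCD",
    k: int = 10,
    seed: int = 0,
    params: Optional[BoostingParams] = None,
) -> PipelineResult:
    """Fixture -> cohort -> features -> bundle -> held-out benchmark."""
    if common_pool is None:
        common_pool, _, _ = build_pool(fixture)
    cohort, partition = build_cohort(fixture, common_pool, k=k, seed=seed)
    X, y, genes = cohort_features(fixture, cohort, config)
    bundle = train_bundle(
        X, y, genes, partition, params=params or BoostingParams(), seed=seed, config=config
    )
    scored = score_variants(bundle, X, genes)
    bench = roc_pr(scored["score"].to_numpy(), y)
    violations = audit_leakage(bundle, scored)
    return PipelineResult(
        fixture, cohort, partition, X, y, genes, bundle, scored, bench, violations
    )


def run_consistency_check(
    fixture: FixtureBundle,
    common_pool: Optional[Sequence[AnnotatedVariant]] = None,
    config: str = "ABCD",
    seed: int = 0,
    params: Optional[BoostingParams] = None,
) -> Tuple[np.ndarray, float, float]:
    """The 11-partition diagnostic: build an 11-way partition, reserve the
    11th as a validation partition, train the 10-model bundle on the rest
    and report the pairwise Spearman correlation of the 10 models' scores on
    the reserved rows."""
    if common_pool is None:
        common_pool, _, _ = build_pool(fixture)
    positives = dedupe_one_per_gene(fixture.positives, seed)
    part11 = partition_genes(
        fixture.coding_gene_universe,
        {av.gene_id for av in positives},
        k=11,
        seed=seed,
    )
    cohort = sample_matched_negatives(
        positives, common_pool, part11, ratio=fixture.spec.neg_ratio, seed=seed
    )
    rows = cohort.rows
    holdout_rows = [(av, lab) for av, lab in rows if part11.of(av.gene_id) == 11]
    train_rows = [(av, lab) for av, lab in rows if part11.of(av.gene_id) != 11]
    if not holdout_rows:
        raise ValueError("no cohort rows fell in the reserved partition")
    part10 = GenomePartition(
        10,
        {g: p for g, p in part11.assignment.items() if p != 11},
        part11.seed,
    )
    def _features(rs):
        avs = [av for av, _ in rs]
        return (
            assemble_matrix(
                avs,
                config,
                panel=fixture.panel,
                tracks=fixture.tracks,
                gene_table=fixture.gene_table,
                reference=fixture.reference,
            ),
            np.array([lab for _, lab in rs], dtype=int),
            [av.gene_id for av in avs],
        )

    X_tr, y_tr, genes_tr = _features(train_rows)
    X_ho, _, genes_ho = _features(holdout_rows)
    bundle = train_bundle(
        X_tr, y_tr, genes_tr, part10, params=params or BoostingParams(),
        seed=seed, config=config,
    )
    return cross_model_correlation(bundle, X_ho, genes_ho)


def run_spike_in(
    fixture: FixtureBundle,
    result: PipelineResult,
    common_pool: Sequence[AnnotatedVariant],
    n_individuals: int = 100,
    background_size: int = 4000,
    seed: int = 0,
    config: str = "ABCD",
) -> Tuple[pd.DataFrame, float]:
    """Simulated disease genomes: spike each pathogenic variant and its
    region-matched internal control into individual backgrounds of common
    variants and report within-individual competition-rank percentiles."""
    rng = np.random.default_rng(seed)
    pool = sorted(common_pool, key=lambda a: a.key)
    if len(pool) > background_size:
        pool = [pool[i] for i in rng.choice(len(pool), background_size, replace=False)]
    Xbg = assemble_matrix(
        pool,
        config,
        panel=fixture.panel,
        tracks=fixture.tracks,
        gene_table=fixture.gene_table,
        reference=fixture.reference,
    )
    bg_scored = score_variants(result.bundle, Xbg, [av.gene_id for av in pool])
    bg_scores = bg_scored["score"].to_numpy()
    mafs = np.array([av.variant.maf for av in pool], dtype=float)
    carrier_p = 1.0 - (1.0 - mafs) ** 2
    backgrounds = []
    for _ in range(n_individuals):
        carried = rng.random(len(pool)) < carrier_p
        if not carried.any():
            carried[rng.integers(len(pool))] = True
        backgrounds.append(bg_scores[carried])

    pairs = sample_region_context_pairs(result.cohort.positives, common_pool, seed=seed)
    pos_score = dict(zip(result.scored["variant_id"], result.scored["score"]))
    spike_pairs = []
    for pos_av, neg_av in pairs:
        Xn = assemble_matrix(
            [neg_av],
            config,
            panel=fixture.panel,
            tracks=fixture.tracks,
            gene_table=fixture.gene_table,
            reference=fixture.reference,
        )
        neg_s = float(
            score_variants(result.bundle, Xn, [neg_av.gene_id])["score"].iloc[0]
        )
        spike_pairs.append((pos_av.key, float(pos_score[pos_av.key]), neg_s))
    return run_spike_in_experiment(backgrounds, spike_pairs)


def run_null_replicates(
    base_spec: FixtureSpec,
    n_seeds: int = 10,
    k: int = 10,
    params: Optional[BoostingParams] = None,
) -> List[float]:
    """Held-out AUROC under the exchangeable null (all effect sizes zero),
    across fixture seeds."""
    aurocs = []
    for i in range(n_seeds):
        spec = dc_replace(
            base_spec,
            effect_sizes={c: 0.0 for c in base_spec.effect_sizes},
            seed=base_spec.seed + 1000 + i,
        )
        fixture = build_fixture(spec)
        res = run_training_pipeline(fixture, k=k, seed=spec.seed, params=params)
        aurocs.append(res.benchmark.auroc)
    return aurocs
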