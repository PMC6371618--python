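"""Benchmark machinery: ranking metrics, per-region bias tests, cross-source
designs, spike-in prioritization and gene-level enrichment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, wilcoxon
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    """AUROC/AUPRC with the underlying curves.

    AUROC is the probability that a random positive outranks a random
    negative (ties counted 1/2); AUPRC is the step integral of the
    precision-recall curve over descending-score thresholds, so a constant
    score yields the positive prevalence.
    """

    auroc: float
    auprc: float
    roc_points: np.ndarray  # (fpr, tpr) columns
    pr_points: np.ndarray  # (recall, precision) columns
    n_pos: int
    n_neg: int


def roc_pr(scores: Sequence[float], labels: Sequence[int]) -> BenchmarkResult:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return BenchmarkResult(
        auroc, auprc, np.column_stack([fpr, tpr]), np.column_stack([rec, prec]), n_pos, n_neg
    )


def _per_gene_medians(frame: pd.DataFrame) -> pd.Series:
    return frame.groupby("gene_id")["score"].median()


def region_bias_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    exact_limit: int = 25,
) -> float:
    """Two-sided Wilcoxon rank-sum p-value between the median-per-gene score
    distributions of two (class, region) groups.

    Each group is first reduced to one median score per gene.  The exact
    null distribution is used for group sizes up to ``exact_limit`` when the
    data are tie-free; the normal approximation with continuity correction
    otherwise.  Groups with fewer than two genes yield NaN.
    """
    a = _per_gene_medians(group_a).to_numpy()
    b = _per_gene_medians(group_b).to_numpy()
    if len(a) < 2 or len(b) < 2:
        logger.warning("region bias test: a group has < 2 genes; p-value undefined")
        return float("nan")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= exact_limit and len(b) <= exact_limit and not ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def region_bias_matrix(
    scored: pd.DataFrame,
    group_cols: Tuple[str, str] = ("label", "region"),
) -> pd.DataFrame:
    """Full pairwise matrix of two-sided rank-sum p-values between every
    (class, region) group's per-gene median score distribution."""
    groups = {key: sub for key, sub in scored.groupby(list(group_cols))}
    keys = sorted(groups, key=str)
    mat = pd.DataFrame(np.nan, index=[str(k) for k in keys], columns=[str(k) for k in keys])
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            p = region_bias_test(groups[ka], groups[kb])
            mat.loc[str(ka), str(kb)] = p
            mat.loc[str(kb), str(ka)] = p
    return mat


@dataclass(frozen=True)
class RankPercentileResult:
    """Within-individual competition rank of a spiked variant.

    Standard competition ("1224") ranking: tied scores share the best rank.
    ``percentile`` = 100 * (N - rank + 1) / N, so rank 1 maps to 100.
    """

    rank: int
    percentile: float
    n: int


def spike_in_percentile(
    background_scores: Sequence[float], spiked_score: float
) -> RankPercentileResult:
    bg = np.asarray(background_scores, dtype=float)
    if len(bg) == 0:
        raise ValueError("background must be non-empty")
    n = len(bg) + 1
    rank = 1 + int(np.sum(bg > spiked_score))
    return RankPercentileResult(rank, 100.0 * (n - rank + 1) / n, n)


def run_spike_in_experiment(
    individual_backgrounds: Sequence[np.ndarray],
    spike_pairs: Sequence[Tuple[str, float, Optional[float]]],
) -> Tuple[pd.DataFrame, float]:
    """Spike each (pathogenic, internal-control) score pair into every
    individual's background and summarise the within-individual rank
    percentiles.

    ``spike_pairs`` rows are (variant_id, pathogenic_score, control_score);
    pairs without a control are skipped for the paired test but still
    reported.  Returns per-variant median percentiles and the one-sided
    (pathogenic > control) Wilcoxon signed-rank p-value over the paired
    medians.
    """
    rows = []
    for vid, path_score, ctrl_score in spike_pairs:
        path_pct = [
            spike_in_percentile(bg, path_score).percentile
            for bg in individual_backgrounds
        ]
        ctrl_pct = None
        if ctrl_score is not None:
            ctrl_pct = [
                spike_in_percentile(bg, ctrl_score).percentile
                for bg in individual_backgrounds
            ]
        else:
            logger.info("spike pair %s has no internal control; unpaired", vid)
        rows.append(
            {
                "variant_id": vid,
                "median_pathogenic_percentile": float(np.median(path_pct)),
                "median_control_percentile": (
                    float(np.median(ctrl_pct)) if ctrl_pct is not None else np.nan
                ),
            }
        )
    table = pd.DataFrame(rows)
    paired = table.dropna(subset=["median_control_percentile"])
    diffs = (
        paired["median_pathogenic_percentile"] - paired["median_control_percentile"]
    ).to_numpy()
    if len(diffs) == 0 or np.all(diffs == 0):
        p = 1.0
    else:
        p = float(
            wilcoxon(diffs, alternative="greater", zero_method="wilcox").pvalue
        )
    return table, p


def cross_source_eval(
    meta: pd.DataFrame,
    X: pd.DataFrame,
    pairing: Mapping[str, Sequence[str]],
    partition,
    configs: Sequence[Tuple[str, Callable[[Set[str]], bool], Callable[[Set[str]], bool]]],
    trainer: Callable[[pd.DataFrame, np.ndarray, Sequence[str]], object],
    scorer: Callable[[object, pd.DataFrame, Sequence[str]], pd.DataFrame],
) -> pd.DataFrame:
    """Train on one annotation-source split of the positives and test on the
    complementary split, with no gene overlap between the two.

    ``meta`` is indexed by variant id with columns ``gene_id``, ``label``
    and ``sources`` (a set, for positives).  Negatives follow their paired
    positive.  Each config is (name, train_selector, test_selector) over
    source sets; a variant matching both selectors goes to training.  Test
    rows whose genes overlap training genes are dropped (counted in the
    output) so the two gene sets are disjoint by construction; the audit
    re-checks this and errors on any residue.
    """
    neg_sources: Dict[str, Set[str]] = {}
    for pkey, nkeys in pairing.items():
        src = meta.loc[pkey, "sources"]
        for nk in nkeys:
            neg_sources[nk] = src

    results = []
    for name, train_sel, test_sel in configs:
        def side(vid: str) -> Optional[str]:
            src = meta.loc[vid, "sources"] if meta.loc[vid, "label"] == 1 else neg_sources.get(vid)
            if src is None:
                return None
            if train_sel(src):
                return "train"
            if test_sel(src):
                return "test"
            return None

        sides = {vid: side(vid) for vid in meta.index}
        train_ids = [v for v, s in sides.items() if s == "train"]
        test_ids = [v for v, s in sides.items() if s == "test"]
        train_genes = set(meta.loc[train_ids, "gene_id"])
        dropped = [v for v in test_ids if meta.loc[v, "gene_id"] in train_genes]
        test_ids = [v for v in test_ids if v not in set(dropped)]
        overlap = set(meta.loc[test_ids, "gene_id"]) & train_genes
        if overlap:
            raise ValueError(f"config {name}: residual gene overlap {sorted(overlap)[:5]}")
        y_test = meta.loc[test_ids, "label"].to_numpy()
        if len(train_ids) == 0 or y_test.sum() == 0 or y_test.sum() == len(y_test):
            logger.warning("config %s: degenerate split; skipped", name)
            results.append(
                {"config": name, "auroc": np.nan, "auprc": np.nan,
                 "n_train_pos": int(meta.loc[train_ids, "label"].sum()) if train_ids else 0,
                 "n_test_pos": int(y_test.sum()), "n_dropped_gene_overlap": len(dropped)}
            )
            continue
        bundle = trainer(
            X.loc[train_ids],
            meta.loc[train_ids, "label"].to_numpy(),
            list(meta.loc[train_ids, "gene_id"]),
        )
        scored = scorer(bundle, X.loc[test_ids], list(meta.loc[test_ids, "gene_id"]))
        bench = roc_pr(scored["score"].to_numpy(), y_test)
        results.append(
            {
                "config": name,
                "auroc": bench.auroc,
                "auprc": bench.auprc,
                "n_train_pos": int(meta.loc[train_ids, "label"].sum()),
                "n_test_pos": int(y_test.sum()),
                "n_dropped_gene_overlap": len(dropped),
            }
        )
    return pd.DataFrame(results)


@dataclass
class EnrichmentResult:
    """Fisher-exact gene-level enrichment of target genes among genes
    bearing high-scoring positions."""

    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float
    alternative: str
    threshold: float
    top_fraction: float
    min_positions: int
    degenerate: bool = False


def gene_threshold_enrichment(
    position_scores: pd.DataFrame,
    reference_positive_scores: Sequence[float],
    gene_universe: Set[str],
    target_genes: Set[str],
    top_fractions: Sequence[float] = (0.05, 0.10, 0.15, 0.20),
    min_positions: Sequence[int] = (1, 10),
    alternative: str = "greater",
) -> Dict[Tuple[float, int], EnrichmentResult]:
    """For each (top fraction, minimum position count): a gene "bears" when
    at least ``min_positions`` of its scored positions exceed the
    (1 - fraction) quantile of the reference pathogenic scores; a 2x2 table
    of target vs non-target by bearing vs not over the gene universe is
    tested with a one-sided (enrichment) Fisher exact test.
    """
    ref = np.asarray(reference_positive_scores, dtype=float)
    if len(ref) == 0:
        raise ValueError("reference positive scores must be non-empty")
    if not gene_universe:
        raise ValueError("empty gene universe")
    target = set(target_genes) & set(gene_universe)
    out: Dict[Tuple[float, int], EnrichmentResult] = {}
    for frac in top_fractions:
        threshold = float(np.quantile(ref, 1.0 - frac))
        exceed = (
            position_scores[position_scores["score"] > threshold]
            .groupby("gene_id")["score"]
            .size()
        )
        for m in min_positions:
            bearing = {g for g, c in exceed.items() if c >= m and g in gene_universe}
            a = len(target & bearing)
            b = len(target - bearing)
            c = len(bearing - target)
            d = len(gene_universe) - a - b - c
            table = ((a, b), (c, d))
            degenerate = min(a + b, c + d, a + c, b + d) == 0
            oddsr, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
            out[(frac, m)] = EnrichmentResult(
                table=table,
                odds_ratio=float(oddsr),
                p_value=float(p),
                alternative=alternative,
                threshold=threshold,
                top_fraction=frac,
                min_positions=m,
                degenerate=degenerate,
            )
    return out
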