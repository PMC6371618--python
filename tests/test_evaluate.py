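"""Benchmark machinery: ranking metrics, rank-sum bias tests, spike-in
percentiles, Fisher enrichment, cross-source designs."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ncboost.boost import BoostingParams, score_variants, train_bundle
from ncboost.cohort import partition_genes
from ncboost.evaluate import (
    cross_source_eval,
    gene_threshold_enrichment,
    region_bias_matrix,
    region_bias_test,
    roc_pr,
    run_spike_in_experiment,
    spike_in_percentile,
)

from _oracles import (
    oracle_auroc,
    oracle_competition_percentile,
    oracle_fisher_greater,
    oracle_ranksum_two_sided,
)


class TestRocPr:
    def test_perfect_separation(self):
        res = roc_pr([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert res.auroc == 1.0 and res.auprc == 1.0

    def test_constant_scores_give_tie_convention(self):
        res = roc_pr([0.5] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        assert res.auroc == 0.5
        assert res.auprc == pytest.approx(0.2)  # prevalence

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_small_n(self):
        rng = np.random.default_rng(61)
        for _ in range(25):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=int)
            labels[: max(1, int(rng.integers(1, n)))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)  # coarse -> ties
            got = roc_pr(scores, labels).auroc
            assert got == pytest.approx(oracle_auroc(scores, labels), abs=1e-12)

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(67)
        scores = rng.normal(size=80)
        labels = (rng.random(80) < 0.3).astype(int)
        labels[0], labels[1] = 1, 0
        a = roc_pr(scores, labels).auroc
        b = roc_pr(np.exp(3 * scores) + 5, labels).auroc
        assert a == pytest.approx(b, abs=1e-12)

    def test_counts_recorded(self):
        res = roc_pr([1, 2, 3, 4], [0, 1, 0, 1])
        assert (res.n_pos, res.n_neg) == (2, 2)


class TestRegionBias:
    def _group(self, scores_by_gene):
        rows = [
            {"gene_id": g, "score": s} for g, ss in scores_by_gene.items() for s in ss
        ]
        return pd.DataFrame(rows)

    def test_per_gene_median_reduction(self):
        a = self._group({"g1": [1, 5, 9]})
        b = self._group({"h1": [5], "h2": [5]})
        # gene g1 contributes its median 5, equal to both of b's genes
        p = region_bias_test(a, b)
        assert np.isnan(p)  # a has a single gene -> undefined
        a2 = self._group({"g1": [1, 5, 9], "g2": [4, 5, 6]})
        p2 = region_bias_test(a2, b)
        assert not np.isnan(p2)

    def test_identical_distributions_p_near_one(self):
        a = self._group({f"g{i}": [float(i)] for i in range(8)})
        b = self._group({f"h{i}": [float(i) + 0.001] for i in range(8)})
        assert region_bias_test(a, b) > 0.5

    def test_full_separation_matches_exact_enumeration(self):
        a = self._group({f"g{i}": [float(i)] for i in range(10)})
        b = self._group({f"h{i}": [float(i) + 100] for i in range(10)})
        p = region_bias_test(a, b)
        # smallest achievable two-sided exact rank-sum p for 10 vs 10
        from math import comb

        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(71)
        for _ in range(5):
            n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + rng.normal() * 0.5
            p = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(oracle_ranksum_two_sided(x, y), abs=1e-12)

    def test_pairwise_matrix_is_symmetric(self):
        rng = np.random.default_rng(73)
        rows = []
        for label in (0, 1):
            for region in ("UTR5", "intronic"):
                for g in range(5):
                    rows.append(
                        {"label": label, "region": region,
                         "gene_id": f"{label}{region}{g}",
                         "score": float(rng.normal(loc=label))}
                    )
        mat = region_bias_matrix(pd.DataFrame(rows))
        assert mat.shape == (4, 4)
        assert mat.equals(mat.T)


class TestSpikeInPercentile:
    def test_top_rank(self):
        r = spike_in_percentile([0.1, 0.2, 0.3, 0.4], 0.9)
        assert r.rank == 1 and r.percentile == 100.0 and r.n == 5

    def test_tie_with_top_background_shares_rank_one(self):
        r = spike_in_percentile([0.9, 0.2, 0.3, 0.4], 0.9)
        assert r.rank == 1 and r.percentile == 100.0

    def test_bottom_rank(self):
        r = spike_in_percentile([0.5, 0.6, 0.7], 0.1)
        assert r.rank == 4 and r.percentile == pytest.approx(25.0)

    def test_exhaustive_tie_structures_to_pool_six(self):
        """All score multisets from a 3-letter alphabet, pools up to size 6,
        agree exactly with the sort-based oracle."""
        for n_bg in range(1, 6):
            for bg in product((0.0, 1.0, 2.0), repeat=n_bg):
                for spiked in (0.0, 1.0, 2.0):
                    got = spike_in_percentile(list(bg), spiked)
                    rank, pct = oracle_competition_percentile(bg, spiked)
                    assert got.rank == rank
                    assert got.percentile == pct

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            spike_in_percentile([], 0.5)


class TestSpikeInExperiment:
    def test_always_top_pathogenic_has_median_100(self):
        backgrounds = [np.array([0.1, 0.2, 0.3])] * 10
        table, _ = run_spike_in_experiment(backgrounds, [("v1", 0.99, 0.15)])
        assert table["median_pathogenic_percentile"].iloc[0] == 100.0

    def test_identical_scores_give_large_p(self):
        backgrounds = [np.linspace(0, 1, 50) for _ in range(20)]
        pairs = [(f"v{i}", 0.5, 0.5) for i in range(10)]
        _, p = run_spike_in_experiment(backgrounds, pairs)
        assert p >= 0.5

    def test_paired_p_decreases_with_planted_gap(self):
        rng = np.random.default_rng(79)
        backgrounds = [rng.normal(size=200) for _ in range(30)]
        ps = []
        for gap in (0.0, 0.5, 2.0):
            pairs = [
                (f"v{i}", float(rng.normal() * 0.1 + gap), float(rng.normal() * 0.1))
                for i in range(12)
            ]
            _, p = run_spike_in_experiment(backgrounds, pairs)
            ps.append(p)
        assert ps[2] < ps[1] < ps[0] or (ps[2] < ps[0] and ps[1] <= ps[0])

    def test_missing_control_skipped_but_reported(self):
        backgrounds = [np.array([0.5])] * 3
        table, p = run_spike_in_experiment(
            backgrounds, [("v1", 0.9, None), ("v2", 0.9, 0.1)]
        )
        assert len(table) == 2
        assert np.isnan(table.loc[table["variant_id"] == "v1",
                                  "median_control_percentile"]).all()


class TestGeneThresholdEnrichment:
    def test_fisher_matches_hypergeometric_oracle(self):
        universe = {f"g{i}" for i in range(20)}
        positions = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "score": [1.0] * 10}
        )
        res = gene_threshold_enrichment(
            positions, [0.5], universe, {f"g{i}" for i in range(8)},
            top_fractions=[0.05], min_positions=[1],
        )[(0.05, 1)]
        (a, b), (c, d) = res.table
        oddsr, p = oracle_fisher_greater(a, b, c, d)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        if np.isfinite(oddsr):
            assert res.odds_ratio == pytest.approx(oddsr, rel=1e-9)

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(83)
        universe = {f"g{i}" for i in range(200)}
        target = {f"g{i}" for i in range(50)}
        rows = []
        for g in universe:
            base = 2.0 if g in target and rng.random() < 0.6 else 0.0
            for _ in range(5):
                rows.append({"gene_id": g, "score": float(rng.normal(base, 0.3))})
        res = gene_threshold_enrichment(
            pd.DataFrame(rows), list(rng.normal(2.0, 0.3, 40)), universe, target,
            top_fractions=[0.10], min_positions=[1],
        )[(0.10, 1)]
        assert res.odds_ratio > 1.0
        assert res.p_value < 0.05

    def test_degenerate_all_bearing_flagged(self):
        universe = {"g1", "g2"}
        positions = pd.DataFrame({"gene_id": ["g1", "g2"], "score": [9.0, 9.0]})
        res = gene_threshold_enrichment(
            positions, [0.1], universe, {"g1"}, top_fractions=[0.05], min_positions=[1]
        )[(0.05, 1)]
        assert res.degenerate

    def test_min_positions_threshold(self):
        universe = {"g1", "g2"}
        positions = pd.DataFrame(
            {"gene_id": ["g1"] * 12 + ["g2"], "score": [9.0] * 13}
        )
        res = gene_threshold_enrichment(
            positions, [0.1], universe, {"g1"}, top_fractions=[0.05], min_positions=[10]
        )[(0.05, 10)]
        (a, b), (c, d) = res.table
        assert (a, b, c, d) == (1, 0, 0, 1)  # only g1 bears at >= 10 positions

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            gene_threshold_enrichment(
                pd.DataFrame({"gene_id": [], "score": []}), [], {"g"}, set()
            )


FAST = BoostingParams(n_rounds=60, early_stopping_rounds=None)


def _source_cohort(rng, signal=True, n_pos=40, ratio=2):
    n = n_pos * (1 + ratio)
    y = np.array([1] * n_pos + [0] * (n_pos * ratio))
    X = pd.DataFrame(
        rng.normal(size=(n, 8)), columns=[f"f{j}" for j in range(8)],
        index=[f"v{i}" for i in range(n)],
    )
    if signal:
        X.iloc[y == 1, :4] += 2.0
    genes = [f"g{i}" for i in range(n)]
    sources = []
    for i in range(n_pos):
        sources.append(frozenset({"S1"}) if i % 2 == 0 else frozenset({"S2"}))
    meta = pd.DataFrame(
        {
            "gene_id": genes,
            "label": y,
            "sources": [sources[i] if i < n_pos else None for i in range(n)],
        },
        index=X.index,
    )
    pairing = {
        f"v{i}": [f"v{n_pos + i * ratio + j}" for j in range(ratio)]
        for i in range(n_pos)
    }
    part = partition_genes(
        [(g, "c1") for g in genes], {genes[i] for i in range(n_pos)}, k=5,
        seed=int(rng.integers(1000)),
    )
    return X, meta, pairing, part, genes


class TestCrossSourceEval:
    def _run(self, rng, signal):
        X, meta, pairing, part, genes = _source_cohort(rng, signal=signal)

        def trainer(Xt, yt, gt):
            return train_bundle(Xt, yt, gt, part, params=FAST,
                                seed=int(rng.integers(1000)))

        def scorer(bundle, Xs, gs):
            return score_variants(bundle, Xs, gs)

        configs = [
            ("S1->S2", lambda s: "S1" in s, lambda s: "S2" in s),
            ("S2->S1", lambda s: "S2" in s, lambda s: "S1" in s),
        ]
        return cross_source_eval(meta, X, pairing, part, configs, trainer, scorer)

    def test_table_shape_and_gene_disjointness(self):
        rng = np.random.default_rng(89)
        table = self._run(rng, signal=True)
        assert list(table["config"]) == ["S1->S2", "S2->S1"]
        assert table[["auroc", "auprc"]].notna().all().all()

    def test_signal_transfers_across_sources(self):
        rng = np.random.default_rng(91)
        aurocs = [self._run(np.random.default_rng(91 + i), signal=True)["auroc"].mean()
                  for i in range(3)]
        assert float(np.mean(aurocs)) >= 0.85

    def test_null_model_stays_at_chance(self):
        aurocs = [self._run(np.random.default_rng(300 + i), signal=False)["auroc"].mean()
                  for i in range(5)]
        assert 0.4 <= float(np.mean(aurocs)) <= 0.6
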