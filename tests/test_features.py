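"""Feature assembly: windowed AF statistics, sequence context, track
lookups, median imputation."""

import numpy as np
import pandas as pd
import pytest

from ncboost.features import (
    CATEGORY_FEATURES,
    FeatureTrack,
    GeneFeatureTable,
    PopulationPanel,
    TrackError,
    assemble,
    assemble_matrix,
    feature_names,
    gc_cpg_content,
    impute,
    lookup_track,
    training_medians,
    window_af_stat,
)
from ncboost.types import AnnotatedVariant

from conftest import make_variant
from _oracles import (
    oracle_gc_cpg,
    oracle_track_lookup,
    oracle_window_het,
    oracle_window_mean,
)


def _panel(rows):
    return PopulationPanel(pd.DataFrame(rows))


def _random_panel(rng, n=200, span=10_000, chrom="chrP"):
    pos = np.sort(rng.choice(span, size=n, replace=False)) + 1
    maf = rng.uniform(0, 0.5, n)
    return _panel(
        {
            "chrom": chrom,
            "pos": pos,
            "maf": maf,
            "daf": rng.uniform(0, 1, n),
            "maf_AFR": rng.uniform(0, 0.5, n),
        }
    )


class TestWindowAFStat:
    def test_query_only_window_is_missing(self):
        panel = _panel({"chrom": ["chrP"], "pos": [500], "maf": [0.3], "daf": [0.3]})
        v = make_variant("chrP", 500, maf=0.3)
        assert np.isnan(window_af_stat(v, panel, "meanMAF"))

    def test_single_neighbour_mean(self):
        panel = _panel(
            {"chrom": ["chrP", "chrP"], "pos": [500, 700], "maf": [0.3, 0.2],
             "daf": [0.3, 0.2]}
        )
        v = make_variant("chrP", 500)
        assert window_af_stat(v, panel, "meanMAF") == pytest.approx(0.2, abs=1e-15)

    def test_unknown_population_lists_available(self):
        panel = _panel({"chrom": ["chrP"], "pos": [1], "maf": [0.1]})
        with pytest.raises(ValueError, match="AFR"):
            window_af_stat(make_variant("chrP", 5), panel, "meanMAF", "XYZ")

    @pytest.mark.parametrize("stat,pop", [("meanMAF", "global"), ("meanMAF", "AFR"),
                                          ("meanDAF", "global"), ("meanHet", "global")])
    def test_matches_bruteforce_scan(self, stat, pop):
        rng = np.random.default_rng(17)
        panel = _random_panel(rng)
        for _ in range(125):
            v = make_variant("chrP", int(rng.integers(1, 10_000)))
            got = window_af_stat(v, panel, stat, pop)
            if stat == "meanHet":
                exp = oracle_window_het(panel.frame, v.chrom, v.pos)
            else:
                col = {"meanMAF": "maf" if pop == "global" else f"maf_{pop}",
                       "meanDAF": "daf"}[stat]
                exp = oracle_window_mean(panel.frame, v.chrom, v.pos, col)
            if np.isnan(exp):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(exp, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(19)
        panel = _random_panel(rng)
        shifted = _panel(panel.frame.assign(pos=panel.frame["pos"] + 12345))
        for _ in range(50):
            p = int(rng.integers(1, 10_000))
            a = window_af_stat(make_variant("chrP", p), panel, "meanMAF")
            b = window_af_stat(make_variant("chrP", p + 12345), shifted, "meanMAF")
            assert (np.isnan(a) and np.isnan(b)) or a == b

    def test_query_exclusion_is_noop(self):
        """Adding a panel record at the query's own position never changes
        the statistic."""
        rng = np.random.default_rng(21)
        panel = _random_panel(rng)
        p = 5000
        v = make_variant("chrP", p)
        base = window_af_stat(v, panel, "meanMAF")
        augmented = _panel(
            pd.concat(
                [panel.frame,
                 pd.DataFrame({"chrom": ["chrP"], "pos": [p], "maf": [0.49],
                               "daf": [0.9], "maf_AFR": [0.49]})],
                ignore_index=True,
            )
        )
        assert window_af_stat(v, augmented, "meanMAF") == base

    def test_het_and_maf_bounded_by_half(self):
        rng = np.random.default_rng(29)
        panel = _random_panel(rng)
        for _ in range(50):
            v = make_variant("chrP", int(rng.integers(1, 10_000)))
            for stat in ("meanMAF", "meanHet"):
                val = window_af_stat(v, panel, stat)
                assert np.isnan(val) or 0.0 <= val <= 0.5

    def test_folded_panel_enforced(self):
        with pytest.raises(ValueError, match="folded"):
            _panel({"chrom": ["c"], "pos": [1], "maf": [0.7]})


class TestGcCpg:
    def test_homopolymer_g(self):
        ref = {"chrS": "G" * 301}
        gc, cpg = gc_cpg_content("chrS", 151, ref)
        assert gc == 100.0 and cpg == 0.0

    def test_alternating_cg(self):
        ref = {"chrS": "CG" * 151}
        gc, cpg = gc_cpg_content("chrS", 100, ref)  # window starts on a C
        assert gc == 100.0
        assert cpg == pytest.approx(100.0 * 75 / 150)

    def test_outside_chromosome_raises(self):
        with pytest.raises(ValueError):
            gc_cpg_content("chrS", 500, {"chrS": "ACGT" * 10})

    def test_matches_character_counting_oracle(self):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=5000))
        ref = {"chrS": seq}
        for pos in rng.integers(1, 5000, size=200):
            got = gc_cpg_content("chrS", int(pos), ref)
            exp = oracle_gc_cpg(seq, int(pos))
            for g, e in zip(got, exp):
                assert (np.isnan(g) and np.isnan(e)) or g == pytest.approx(e, abs=1e-12)


class TestTrackLookup:
    def test_bin_containment_and_gap(self):
        tr = FeatureTrack.from_records(
            "CDTS", [("c1", 1, 10, 1.5), ("c1", 21, 30, -2.0)], resolution=10
        )
        assert lookup_track(tr, "c1", 5) == 1.5
        assert lookup_track(tr, "c1", 25) == -2.0
        assert np.isnan(lookup_track(tr, "c1", 15))
        assert np.isnan(lookup_track(tr, "c2", 5))

    def test_overlapping_intervals_rejected_at_load(self):
        with pytest.raises(TrackError):
            FeatureTrack.from_records("bad", [("c1", 1, 10, 0.0), ("c1", 5, 15, 1.0)])

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(37)
        records = []
        cursor = 1
        while cursor < 50_000:
            width = int(rng.integers(1, 200))
            if rng.random() < 0.8:
                records.append(("c1", cursor, cursor + width - 1, float(rng.normal())))
            cursor += width + int(rng.integers(0, 50))
        tr = FeatureTrack.from_records("t", records)
        for pos in rng.integers(1, 50_000, size=1000):
            got = tr.lookup("c1", int(pos))
            exp = oracle_track_lookup(records, "c1", int(pos))
            assert (np.isnan(got) and np.isnan(exp)) or got == exp

    def test_plant_splits_covering_bin(self):
        tr = FeatureTrack.from_records("t", [("c1", 1, 100, 5.0)])
        tr.plant("c1", 50, 99.0)
        assert tr.lookup("c1", 49) == 5.0
        assert tr.lookup("c1", 50) == 99.0
        assert tr.lookup("c1", 51) == 5.0


def _av(variant, region, gene):
    return AnnotatedVariant(variant, region, gene, 0)


class TestAssemble:
    def test_category_d_isolation(self):
        ref = {"chrS": "ACGT" * 100}
        av = _av(make_variant("chrS", 200, ref="T", alt="C"), "UTR5", "G1")
        fv = assemble(av, "D", reference=ref)
        assert list(fv.values.index) == CATEGORY_FEATURES["D"]
        assert fv.values["region_UTR5"] == 1.0
        flags = [c for c in fv.values.index if c.startswith("region_")]
        assert fv.values[flags].sum() == 1.0
        assert not fv.values[["GC", "CpG"]].isna().any()

    def test_absent_gene_gets_column_medians(self):
        frame = pd.DataFrame(
            {f: np.arange(5, dtype=float) for f in CATEGORY_FEATURES["C"]},
            index=[f"g{i}" for i in range(5)],
        )
        table = GeneFeatureTable(frame)
        av = _av(make_variant("chrS", 10), "intronic", "unknown_gene")
        fv = assemble(av, "C", gene_table=table)
        assert (fv.values == 2.0).all()  # median of 0..4

    def test_empty_config_errors(self):
        av = _av(make_variant("chrS", 10), "intronic", "g")
        with pytest.raises(ValueError):
            assemble(av, "")

    def test_non_retained_variant_rejected(self):
        av = _av(make_variant("chrS", 10), "exonic", "g")
        with pytest.raises(ValueError):
            assemble(av, "D", reference={"chrS": "A" * 100})

    def test_full_assembly_matches_per_feature_oracle(self, default_fixture, pipeline_result):
        """Column-by-column equality between the assembled cohort matrix and
        independently recomputed values."""
        res = pipeline_result
        fx = default_fixture
        rows = res.cohort.rows[:50] + res.cohort.rows[-50:]
        avs = [av for av, _ in rows]
        X = assemble_matrix(
            avs, "ABCD", panel=fx.panel, tracks=fx.tracks,
            gene_table=fx.gene_table, reference=fx.reference,
        )
        track_frames = {
            name: [
                (c, int(s), int(e), float(v))
                for c, ss, ee, vv in (
                    (ch, *fx.tracks[name]._data[ch]) for ch in fx.tracks[name]._data
                )
                for s, e, v in zip(ss, ee, vv)
            ]
            for name in ("GerpN", "bStatistic", "CDTS")
        }
        for av in avs[:25]:
            v = av.variant
            for name, recs in track_frames.items():
                exp = oracle_track_lookup(recs, v.chrom, v.pos)
                got = X.at[av.key, name]
                assert (np.isnan(got) and np.isnan(exp)) or got == exp
            exp = oracle_window_mean(fx.panel.frame, v.chrom, v.pos, "maf")
            got = X.at[av.key, "meanMAFGnomAD"]
            assert (np.isnan(got) and np.isnan(exp)) or got == pytest.approx(exp, abs=1e-12)
            gc_exp, cpg_exp = oracle_gc_cpg(fx.reference[v.chrom], v.pos)
            assert X.at[av.key, "GC"] == pytest.approx(gc_exp, abs=1e-12)
            assert X.at[av.key, "CpG"] == pytest.approx(cpg_exp, abs=1e-12)
            assert X.at[av.key, "pLI"] == fx.gene_table.value(av.gene_id, "pLI")

    def test_assembly_is_deterministic(self, default_fixture):
        fx = default_fixture
        avs = fx.positives[:10]
        kw = dict(panel=fx.panel, tracks=fx.tracks, gene_table=fx.gene_table,
                  reference=fx.reference)
        X1 = assemble_matrix(avs, "ABCD", **kw)
        X2 = assemble_matrix(avs, "ABCD", **kw)
        pd.testing.assert_frame_equal(X1, X2, check_exact=True)


class TestImpute:
    def test_median_fill(self):
        X = pd.DataFrame({"f": [1.0, np.nan, 3.0]})
        med = training_medians(X)
        assert med["f"] == 2.0
        assert impute(X, med)["f"].tolist() == [1.0, 2.0, 3.0]

    def test_test_rows_use_training_medians(self):
        train = pd.DataFrame({"f": [0.0, 0.0, 4.0]})
        test = pd.DataFrame({"f": [np.nan, 100.0, np.nan]})
        med = training_medians(train)
        filled = impute(test, med)
        assert filled["f"].tolist() == [0.0, 100.0, 0.0]  # not the test median

    def test_all_missing_training_feature_raises(self):
        X = pd.DataFrame({"ok": [1.0, 2.0], "broken": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="broken"):
            training_medians(X)

    def test_random_missingness_matches_oracle_fill(self):
        rng = np.random.default_rng(41)
        X = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        holes = rng.random(X.shape) < 0.3
        Xm = X.mask(holes)
        if Xm.isna().all().any():
            Xm.iloc[0] = 0.0
        med = training_medians(Xm)
        filled = impute(Xm, med)
        for col in Xm.columns:
            expected_med = float(np.median(Xm[col].dropna()))
            for i in range(len(Xm)):
                if np.isnan(Xm[col].iloc[i]):
                    assert filled[col].iloc[i] == pytest.approx(expected_med)
                else:
                    assert filled[col].iloc[i] == Xm[col].iloc[i]


def test_feature_names_ordering_and_validation():
    names = feature_names("DA")
    assert names[: len(CATEGORY_FEATURES["A"])] == CATEGORY_FEATURES["A"]
    with pytest.raises(ValueError):
        feature_names("AZ")
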