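import numpy as np
import pandas as pd
import pytest

from lncloc.features import build_feature_table, build_synthetic_features, synthetic_schema
from lncloc.genome import tile_genome
from lncloc.interactome import LncRNA
from lncloc.pwm import PWM
from lncloc.schema import FamilySchema, Family, FeatureTable, canonical_schema
from lncloc.tracks import (IntervalTrack, aggregate_track, paired_context_features,
                           repeat_features, repeat_pair, shared_motif_features)


class TestCanonicalSchema:
    def test_reference_resource_counts(self):
        s = canonical_schema()
        assert len(s["kmer"].features) == 512
        assert s.n_features("primary") == 1280
        assert s.n_features("secondary") == 333
        assert s.n_features() == 1613

    def test_every_feature_in_exactly_one_family(self):
        s = canonical_schema()
        assert len(set(s.all_features)) == len(s.all_features) == 1613

    def test_duplicate_feature_rejected(self):
        with pytest.raises(ValueError, match="more than one family"):
            FamilySchema((Family("a", "primary", ("x",)),
                          Family("b", "secondary", ("x",))))


class TestFeatureTable:
    def test_missing_values_rejected(self):
        schema = FamilySchema((Family("f", "primary", ("a", "b")),))
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(ValueError, match="missing values"):
            FeatureTable(df, schema)

    def test_lncrna_specific_columns_flagged(self):
        ft_schema = synthetic_schema()
        df = pd.DataFrame(0.0, index=[0], columns=ft_schema.all_features)
        ft = FeatureTable(df, ft_schema)
        assert set(ft.lncrna_specific_columns()) == {
            "triplex_pairs", "triplex_total_len", "triplex_max_score",
            "triplex_coverage"}

    def test_tsv_roundtrip(self, tmp_path):
        schema = synthetic_schema()
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.integers(0, 5, (3, len(schema.all_features))).astype(float),
                          index=[10, 11, 12], columns=schema.all_features)
        ft = FeatureTable(df, schema)
        ft.to_tsv(tmp_path / "f.tsv", schema_path=tmp_path / "s.json")
        back = FeatureTable.from_tsv(tmp_path / "f.tsv", schema)
        pd.testing.assert_frame_equal(back.values, ft.values)


class TestTrackAggregation:
    def track(self):
        return IntervalTrack(np.array(["chr1", "chr1", "chr1"], dtype=object),
                             np.array([100, 2100, 2300]),
                             np.array([300, 2200, 2600]),
                             np.array([2.0, 5.0, 9.0]))

    def test_no_overlap_is_zero(self):
        assert aggregate_track(self.track(), "chr1", 5000, 6000, "max") == 0.0
        assert aggregate_track(self.track(), "chr1", 5000, 6000, "sum") == 0.0

    def test_max_of_overlapping_peaks(self):
        assert aggregate_track(self.track(), "chr1", 2000, 3000, "max") == 9.0

    def test_sum_weights_by_overlap_length(self):
        # interval [100,300) score 2 inside tile [0,1000): 200 bases x 2
        assert aggregate_track(self.track(), "chr1", 0, 1000, "sum") == 400.0

    def test_sum_additive_over_tile_partition(self):
        t = self.track()
        whole = aggregate_track(t, "chr1", 2000, 3000, "sum")
        halves = (aggregate_track(t, "chr1", 2000, 2500, "sum")
                  + aggregate_track(t, "chr1", 2500, 3000, "sum"))
        assert whole == halves

    def test_negative_length_interval_rejected(self):
        with pytest.raises(ValueError, match="negative-length"):
            IntervalTrack(np.array(["c"], dtype=object), np.array([10]),
                          np.array([5]), np.array([1.0]))


class TestRepeatFeatures:
    def test_counts_per_family(self):
        inst = IntervalTrack(np.array(["chr1"] * 3, dtype=object),
                             np.array([100, 400, 700]), np.array([250, 600, 900]),
                             np.zeros(3))
        labels = np.array(["Alu", "Alu", "L1"], dtype=object)
        counts = repeat_features("chr1", 0, 1000, inst, ["Alu", "L1", "ERVK"], labels)
        assert counts == {"Alu": 2, "L1": 1, "ERVK": 0}

    def test_repeat_pair_is_set_intersection(self):
        assert repeat_pair({"Alu", "L1"}, {"L1", "ERVK"}) == 1
        assert repeat_pair(set(), {"L1"}) == 0


class TestSharedMotifs:
    def test_disjoint_sets_no_edges(self):
        assert shared_motif_features(set(), {"a"}, set(), {"r"}, []) == (0, 0, 0)

    def test_tf_pair_counts_common_proteins(self):
        out = shared_motif_features({"Sp1", "Sp2", "X"}, {"Sp1", "Sp2"},
                                    set(), set(), [])
        assert out[0] == 2

    def test_ppi_pair_matches_exhaustive_edge_oracle(self, rng):
        proteins = [f"p{i}" for i in range(20)]
        for _ in range(20):
            lnc_side = set(rng.choice(proteins, 5, replace=False))
            tile_side = set(rng.choice(proteins, 5, replace=False))
            edges = [tuple(rng.choice(proteins, 2, replace=False)) for _ in range(30)]
            _, _, got = shared_motif_features(tile_side, lnc_side, set(), set(), edges)
            oracle = {frozenset(e) for e in edges
                      if (e[0] in lnc_side and e[1] in tile_side)
                      or (e[1] in lnc_side and e[0] in tile_side)}
            assert got == len(oracle)


class TestPairedContext:
    def test_randomized_peaks_match_double_overlap_oracle(self, rng):
        tile = ("chr1", 5000, 6000)
        gene = ("chr1", 20_000, 22_000)
        tracks = {}
        oracle = 0
        for i in range(15):
            starts = rng.integers(0, 30_000, 6)
            tr = IntervalTrack(np.array(["chr1"] * 6, dtype=object), starts,
                               starts + 500, np.ones(6))
            tracks[f"ag{i}"] = tr
            on_tile = any(s < 6000 and s + 500 > 5000 for s in starts)
            on_gene = any(s < 22_000 and s + 500 > 20_000 for s in starts)
            oracle += int(on_tile and on_gene)
        chip_pair, _ = paired_context_features(tile, gene, tracks, {})
        assert chip_pair == oracle


class TestResourceAssembly:
    def test_small_end_to_end_table(self, rng):
        tiling = tile_genome({"chr1": 6000}, 1000)
        seq = "".join(rng.choice(list("ACGT"), 6000))
        # plant a strong motif occurrence in tile 2
        motif = "ACGTACGT"
        seq = seq[:2100] + motif + seq[2100 + len(motif):]
        pwm = PWM("tf1", np.eye(4)[[0, 1, 2, 3, 0, 1, 2, 3]])
        lnc = LncRNA("lncX", "chr1", 0, 1000, transcript=seq[:1000])
        rep = IntervalTrack(np.array(["chr1"], dtype=object), np.array([2500]),
                            np.array([2700]), np.zeros(1))
        track = IntervalTrack(np.array(["chr1"], dtype=object), np.array([2000]),
                              np.array([2400]), np.array([7.0]))
        df = build_feature_table(
            tiling, {"chr1": seq}, tile_ids=np.arange(6), lncrna=lnc,
            tf_pwms={"tf1": [pwm]}, repeat_track=rep,
            repeat_labels=np.array(["Alu"], dtype=object),
            max_tracks={"acc": track}, pwm_pval=1e-3)
        assert df.loc[2, "tf_motif_tf1"] >= 1
        assert df.loc[2, "repeat_Alu"] == 1
        assert df.loc[2, "acc"] == 7.0
        assert df.loc[5, "acc"] == 0.0
        assert {"triplex_pairs", "tf_pair", "ppi_pair"} <= set(df.columns)


def test_synthetic_features_cover_schema(small_cohort):
    cfg, genome, tracks, imap = small_cohort
    name = "lnc_triplex"
    ids = imap.bound[name][:20]
    ft = build_synthetic_features(genome, tracks, name, ids)
    assert ft.values.shape == (20, 512 + 4 + 4)
    assert (ft.matrix(("kmer",)).sum(axis=1) == 996).all()
    assert not ft.values.isna().any().any()
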