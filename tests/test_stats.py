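import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp, rankdata

from lncloc.kmers import canonical, canonical_kmers
from lncloc.stats import (enrichment_battery, kmer_density_correlation,
                          seed_enrichment_matrix, seed_to_kmers, signed_ks)


def brute_force_ks(a, b):
    """Naive ECDF sweep over all pooled evaluation points."""
    xs = np.unique(np.concatenate([a, b]))
    best = 0.0
    for x in xs:
        fa = (a <= x).mean()
        fb = (b <= x).mean()
        best = max(best, abs(fb - fa))
    return best


class TestSignedKS:
    def test_identical_samples_give_zero(self):
        x = np.arange(10, dtype=float)
        d, p = signed_ks(x, x)
        assert d == 0.0
        assert p == 1.0

    def test_positive_shift_is_positive_and_antisymmetric(self, rng):
        a = rng.normal(size=300)
        b = a + 1.0
        d_ab, _ = signed_ks(b, a)   # bound = shifted-up sample
        d_ba, _ = signed_ks(a, b)
        assert d_ab > 0
        assert d_ba == -d_ab

    def test_magnitude_matches_brute_force_on_500_instances(self, rng):
        for _ in range(500):
            n, m = rng.integers(3, 40, 2)
            a = np.round(rng.normal(size=n), 1)  # ties across samples
            b = np.round(rng.normal(rng.uniform(-1, 1), 1.2, size=m), 1)
            d, _ = signed_ks(a, b)
            assert abs(d) == pytest.approx(brute_force_ks(a, b), abs=1e-12)
            assert abs(d) == pytest.approx(ks_2samp(a, b).statistic, abs=1e-12)

    def test_asymptotic_pvalue_tracks_scipy(self, rng):
        a = rng.normal(size=400)
        b = rng.normal(0.25, 1, size=500)
        _, p = signed_ks(a, b)
        p_ref = ks_2samp(a, b, method="asymp").pvalue
        assert p == pytest.approx(p_ref, rel=0.1, abs=1e-6)

    def test_sign_convention_flag(self, rng):
        a = rng.normal(size=100) + 2
        b = rng.normal(size=100)
        d_default, _ = signed_ks(a, b, sign_convention=1)
        d_flipped, _ = signed_ks(a, b, sign_convention=-1)
        assert d_default == -d_flipped > 0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            signed_ks(np.array([]), np.array([1.0]))


class TestBattery:
    def test_single_feature_adjusted_p_equals_raw(self, rng):
        b = {("l1", "f"): (rng.normal(size=50), rng.normal(1, 1, 60))}
        df = enrichment_battery(b)
        assert df["p_adj"].iloc[0] == pytest.approx(df["p"].iloc[0])

    def test_constant_feature_flagged(self):
        b = {("l1", "f"): (np.ones(10), np.ones(12))}
        df = enrichment_battery(b)
        assert df["constant"].iloc[0]
        assert df["d_signed"].iloc[0] == 0.0
        assert df["p"].iloc[0] == 1.0

    def test_bh_adjustment_monotone_and_order_preserving(self, rng):
        b = {("l", f"f{i}"): (rng.normal(size=40), rng.normal(0.2 * (i % 4), 1, 40))
             for i in range(30)}
        df = enrichment_battery(b)
        assert (df["p_adj"] >= df["p"] - 1e-15).all()
        order_p = np.argsort(df["p"].to_numpy(), kind="stable")
        assert (np.diff(df["p_adj"].to_numpy()[order_p]) >= -1e-12).all()


class TestKmerCorrelation:
    def test_perfect_inverse_order_gives_minus_one(self):
        ranks = pd.Series(np.arange(1, 513, dtype=float), index=canonical_kmers(5))
        density = pd.Series(np.arange(512, 0, -1, dtype=float) / 512,
                            index=canonical_kmers(5))
        rho, _ = kmer_density_correlation(ranks, density)
        assert rho == pytest.approx(-1.0)

    def test_null_band_at_m512(self, rng):
        ranks = pd.Series(rng.permutation(512).astype(float) + 1,
                          index=canonical_kmers(5))
        density = pd.Series(rng.random(512), index=canonical_kmers(5))
        rho, _ = kmer_density_correlation(ranks, density)
        assert abs(rho) < 0.12  # 95% null band at m = 512

    def test_zero_variance_density_is_missing(self):
        ranks = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        density = pd.Series([0.5, 0.5, 0.5], index=["a", "b", "c"])
        rho, p = kmer_density_correlation(ranks, density)
        assert np.isnan(rho) and np.isnan(p)

    def test_spearman_equals_pearson_of_midranks(self, rng):
        x = pd.Series(rng.integers(0, 5, 100).astype(float))
        y = pd.Series(rng.integers(0, 5, 100).astype(float))
        rho, _ = kmer_density_correlation(x, y)
        rx, ry = rankdata(x), rankdata(y)
        pearson = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(pearson, abs=1e-12)


class TestSeedEnrichment:
    def test_seed_to_kmers_canonicalizes_overlapping_windows(self):
        out = seed_to_kmers("GAGAGAG")
        assert out == [canonical("GAGAG"), canonical("AGAGA"), canonical("GAGAG")]

    def _counts(self, rng, n=300):
        return pd.DataFrame(rng.poisson(2, size=(n, 512)).astype(float),
                            index=np.arange(n), columns=canonical_kmers(5))

    def test_identical_distributions_give_zero_matrix(self, rng):
        counts = pd.DataFrame(np.ones((40, 512)), index=np.arange(40),
                              columns=canonical_kmers(5))
        ids = np.arange(40)
        mat = seed_enrichment_matrix(counts, {"l": ids[:20]}, {"l": ids[20:]},
                                     {"m1": "AAAAAAA", "m2": "ACGTACG"})
        assert (mat.to_numpy() == 0).all()

    def test_planted_two_group_block_structure(self, rng):
        # group-G lncRNA binds G-rich tiles, group-A lncRNA binds A/T-rich
        # tiles; seeds built from each vocabulary must show matching signs
        n = 400
        counts = self._counts(rng, n)
        g_kmers = [km for km in canonical_kmers(5) if km.count("G") >= 4][:8]
        a_kmers = [km for km in canonical_kmers(5) if km.count("A") >= 4][:8]
        bound_g = np.arange(0, 100)
        bound_a = np.arange(100, 200)
        unbound = np.arange(200, 400)
        counts.loc[bound_g, g_kmers] += 3
        counts.loc[bound_a, a_kmers] += 3
        seeds = {}
        groups = {}
        for i, km in enumerate(g_kmers[:5]):
            seeds[f"mg{i}"] = km + km[:2]
            groups[f"mg{i}"] = "G"
        for i, km in enumerate(a_kmers[:5]):
            seeds[f"ma{i}"] = km + km[:2]
            groups[f"ma{i}"] = "A"
        mat = seed_enrichment_matrix(counts,
                                     {"lncG": bound_g, "lncA": bound_a},
                                     {"lncG": unbound, "lncA": unbound}, seeds)
        agree = 0
        total = 0
        for mir in mat.columns:
            for lnc in mat.index:
                matched = (groups[mir] == "G") == (lnc == "lncG")
                total += 1
                agree += int((mat.loc[lnc, mir] > 0) == matched)
        assert agree / total >= 0.8

    def test_ordering_invariant_to_input_row_order(self, rng):
        counts = self._counts(rng)
        seeds = {"m1": "AAAAAAA", "m2": "GGGGGGG", "m3": "ACGTACG"}
        b = {"l1": np.arange(0, 50), "l2": np.arange(50, 100),
             "l3": np.arange(100, 150)}
        u = {k: np.arange(150, 300) for k in b}
        m1 = seed_enrichment_matrix(counts, b, u, seeds)
        b_rev = dict(reversed(list(b.items())))
        m2 = seed_enrichment_matrix(counts, b_rev, u, seeds)
        pd.testing.assert_frame_equal(m1, m2)

    def test_seed_without_valid_kmers_dropped(self, rng):
        counts = self._counts(rng, 60)
        with pytest.warns(UserWarning, match="no valid 5-mers"):
            mat = seed_enrichment_matrix(
                counts, {"l": np.arange(30)}, {"l": np.arange(30, 60)},
                {"bad": "NNNNNNN", "ok": "AAAAAAA"})
        assert list(mat.columns) == ["ok"]
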