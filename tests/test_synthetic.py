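import dataclasses
import io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, spearmanr

from lncloc.dataset import build_dataset
from lncloc.experiments import cohort_config
from lncloc.io import write_fasta
from lncloc.kmers import canonical_kmers, kmer_density
from lncloc.stats import signed_ks
from lncloc.synthetic import (LncSpec, SyntheticConfig, generate_context_tracks,
                              generate_genome, generate_interactions,
                              lognormal_bias, xor_indicator)


def _single_lnc_config(seed=0, mechanism="noise", n_pos=100, chrom_tiles=4000,
                       **extra):
    mid = chrom_tiles * 1000 // 2
    return SyntheticConfig(
        n_chroms=1, chrom_length=chrom_tiles * 1000,
        lncrnas=(LncSpec("l", "chr1", mid - 1000, mid + 1000,
                         mechanism=mechanism, n_target_positives=n_pos),),
        decay_scale=400_000.0, seed=seed, kmer_bias=lognormal_bias(seed),
        track_block_length=10_000.0, **extra)


class TestDeterminism:
    def test_same_seed_bit_identical_outputs(self):
        cfg = cohort_config(seed=42, n_pos=30)
        g1, g2 = generate_genome(cfg), generate_genome(cfg)
        for c in cfg.chrom_names:
            assert np.array_equal(g1.sequences[c], g2.sequences[c])
        assert g1.transcripts == g2.transcripts
        assert g1.mirna_seeds == g2.mirna_seeds
        t1, t2 = generate_context_tracks(cfg, g1), generate_context_tracks(cfg, g2)
        i1 = generate_interactions(cfg, g1, t1)
        i2 = generate_interactions(cfg, g2, t2)
        for n in i1.bound:
            assert np.array_equal(i1.bound[n], i2.bound[n])
        # byte-identical FASTA export
        b1, b2 = io.StringIO(), io.StringIO()
        write_fasta(b1, g1.fasta_records())
        write_fasta(b2, g2.fasta_records())
        assert b1.getvalue() == b2.getvalue()


class TestGenome:
    def test_unbiased_config_has_uniform_composition(self):
        cfg = _single_lnc_config(seed=3, insert_rate=0.0, decoy_insert_rate=0.0)
        cfg = dataclasses.replace(cfg, kmer_bias={})
        g = generate_genome(cfg)
        counts = np.bincount(g.sequences["chr1"], minlength=4)
        freq = counts / counts.sum()
        assert np.abs(freq - 0.25).max() < 0.005

    def test_overlapping_genes_rejected(self):
        cfg = _single_lnc_config()
        lncs = (cfg.lncrnas[0],
                LncSpec("l2", "chr1", cfg.lncrnas[0].gene_start + 500,
                        cfg.lncrnas[0].gene_end + 500, mechanism="noise"))
        with pytest.raises(ValueError, match="overlapping gene intervals"):
            generate_genome(dataclasses.replace(cfg, lncrnas=lncs))

    def test_planted_bias_shapes_transcript_kmer_density(self):
        cfg = _single_lnc_config(seed=5)
        g = generate_genome(cfg)
        dens = kmer_density(g.transcripts["l"])
        w = np.array([cfg.kmer_bias[km] for km in canonical_kmers(5)])
        rho, p = spearmanr(w, dens)
        assert rho > 0 and p < 1e-6

    def test_shared_bias_reaches_seeds_and_repeats(self):
        cfg = _single_lnc_config(seed=6)
        g = generate_genome(cfg)
        w = pd.Series(cfg.kmer_bias)
        # density over the pooled miRNA seeds / repeat consensus sequences
        from lncloc.kmers import count_canonical_kmers
        seed_counts = sum(count_canonical_kmers(s) for s in g.mirna_seeds.values())
        rep_counts = sum(count_canonical_kmers(s) for s in g.repeat_consensus.values())
        assert spearmanr(w[list(canonical_kmers(5))], seed_counts)[0] > 0.05
        assert spearmanr(w[list(canonical_kmers(5))], rep_counts)[0] > 0.05

    def test_triplex_element_planted_in_transcript_and_inserts(self):
        cfg = cohort_config(seed=8, n_pos=30)
        g = generate_genome(cfg)
        el = g.triplex_elements["lnc_triplex"]
        assert el in g.transcripts["lnc_triplex"]
        assert set(el) <= {"A", "G"}


class TestTracks:
    def test_lag1_autocorrelation_above_half_at_ten_tile_blocks(self):
        cfg = _single_lnc_config(seed=2)
        g = generate_genome(cfg)
        tr = generate_context_tracks(cfg, g)
        v = tr.values["meth"]["chr1"]
        r = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert r > 0.5

    def test_one_bp_blocks_are_white_noise(self):
        cfg = dataclasses.replace(_single_lnc_config(seed=2),
                                  track_block_length=1.0)
        g = generate_genome(cfg)
        tr = generate_context_tracks(cfg, g)
        v = tr.values["meth"]["chr1"]
        assert abs(np.corrcoef(v[:-1], v[1:])[0, 1]) < 0.08

    def test_xor_indicator_balanced_by_median_split(self):
        cfg = _single_lnc_config(seed=4)
        g = generate_genome(cfg)
        tr = generate_context_tracks(cfg, g)
        xi = xor_indicator(tr, "chr1")
        assert abs(xi.mean() - 0.5) < 0.05


class TestInteractions:
    def test_effect_zero_follows_pure_distance_decay(self):
        cfg = _single_lnc_config(seed=7, mechanism="transcription", n_pos=800,
                                 chrom_tiles=12_000, positive_run_length=1.0)
        lnc = dataclasses.replace(cfg.lncrnas[0], effect_size=0.0,
                                  n_target_positives=800)
        cfg = dataclasses.replace(cfg, lncrnas=(lnc,), decay_scale=1_000_000.0)
        g = generate_genome(cfg)
        tr = generate_context_tracks(cfg, g)
        im = generate_interactions(cfg, g, tr)
        d = g.tiling.gene_distances(im.bound["l"], "chr1",
                                    lnc.gene_start, lnc.gene_end)
        # oracle: resample from the stated law with an independent stream
        rng = np.random.default_rng(123)
        tiles = g.tiling.chrom_tile_ids("chr1")
        dd = g.tiling.gene_distances(tiles, "chr1", lnc.gene_start, lnc.gene_end)
        p = np.exp(-dd / cfg.decay_scale)
        ref = dd[np.argsort(-np.log(rng.random(len(tiles))) / p)[:800]]
        ks, _ = signed_ks(d, ref)
        assert abs(ks) < 0.08

    def test_transcription_effect_enriches_track_in_positives(self):
        cfg = _single_lnc_config(seed=9, mechanism="transcription", n_pos=1000,
                                 chrom_tiles=16_000)
        cfg = dataclasses.replace(cfg, decay_scale=1_500_000.0)
        g = generate_genome(cfg)
        tr = generate_context_tracks(cfg, g)
        im = generate_interactions(cfg, g, tr)
        ds = build_dataset(im.lncrnas["l"], im.bound["l"], g.tiling,
                           ratio=2.0, cap=100, seed=1)
        vals = tr.values["gro_like"]["chr1"]
        pos_v = vals[g.tiling.starts_of(ds.positives) // 1000]
        neg_v = vals[g.tiling.starts_of(ds.negatives) // 1000]
        p = mannwhitneyu(pos_v, neg_v, alternative="greater").pvalue
        assert p < 0.01

    def test_triplex_positives_enriched_for_true_inserts(self):
        cfg = cohort_config(seed=10, n_pos=100)
        g = generate_genome(cfg)
        tr = generate_context_tracks(cfg, g)
        im = generate_interactions(cfg, g, tr)
        flags = g.insert_tiles["chr2"]
        starts = g.tiling.starts_of(im.bound["lnc_triplex"]) // 1000
        assert flags[starts].mean() > 2 * flags.mean()

    def test_domain_runs_make_bound_tiles_contiguous(self):
        cfg = _single_lnc_config(seed=11, mechanism="transcription", n_pos=300,
                                 chrom_tiles=12_000)
        g = generate_genome(cfg)
        tr = generate_context_tracks(cfg, g)
        im = generate_interactions(cfg, g, tr)
        ids = np.sort(im.bound["l"])
        adjacent = (np.diff(ids) == 1).mean()
        assert adjacent > 0.4  # far above the unclustered expectation

    def test_target_exceeding_chromosome_rejected(self):
        cfg = _single_lnc_config(n_pos=5000, chrom_tiles=4000)
        g = generate_genome(cfg)
        tr = generate_context_tracks(cfg, g)
        with pytest.raises(ValueError, match="exceeds tiles"):
            generate_interactions(cfg, g, tr)
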