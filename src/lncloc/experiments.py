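"""End-to-end synthetic studies.

These drivers wire the full pipeline together on the synthetic cohort —
generation, negative sampling, block CV, the RF model ensembles, MPV /
complementarity, rank aggregation and the association statistics — at sizes
chosen to run on a single CPU in minutes (see docs/methods.md for the study
sizes and their rationale).  Tests, the acceptance script and the analysis
drivers all call these functions, so every reported number is recomputed
from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cv import assign_folds, make_blocks
from .dataset import LabeledDataset, build_dataset
from .features import build_synthetic_features, synthetic_schema
from .importance import (ResultSet, aggregate_feature_ranks, classify_ta,
                         complementarity, mpv_table)
from .kmers import canonical_kmers, kmer_density
from .modeling import (ModelSpec, RAW, derive_seed, enumerate_model_specs,
                       train_and_eval)
from .schema import PRIMARY, Family, FamilySchema, FeatureTable
from .stats import enrichment_battery, kmer_density_correlation, signed_ks
from .synthetic import (LncSpec, SyntheticConfig, generate_context_tracks,
                        generate_genome, generate_interactions, lognormal_bias)

__all__ = ["cohort_config", "CohortReplicate", "run_cohort_replicate",
           "mechanism_recovery_study", "leakage_study",
           "negative_matching_check", "permutation_null_fpr"]

MECHANISM_FAMILY = {"transcription": "transcription", "triplex": "triplex"}
XOR_PAIR = ("methylation", "chromatin")

# study sizes for the scaled synthetic cohort (see docs/methods.md)
N_POS = 100
TREES = 200
K_FOLDS = 5
RATIO = 5.0
CAP = 100
N_PC = 10
NEIGHBORS = 4
EFFECT_SIZE = 2.0


def cohort_config(seed: int, n_pos: int = N_POS, effect_size: float = EFFECT_SIZE,
                  chrom_tiles: int = 4000, tile_width: int = 1000,
                  decay_scale: float = 400_000.0, **extra) -> SyntheticConfig:
    """Four-lncRNA cohort: one lncRNA per mechanism, one per chromosome."""
    mechs = ["transcription", "triplex", "xor_pair", "noise"]
    chrom_length = chrom_tiles * tile_width
    mid = chrom_length // 2
    lncs = tuple(
        LncSpec(f"lnc_{m}", f"chr{i + 1}", mid - tile_width, mid + tile_width,
                mechanism=m, effect_size=effect_size, n_target_positives=n_pos)
        for i, m in enumerate(mechs))
    return SyntheticConfig(n_chroms=4, chrom_length=chrom_length, lncrnas=lncs,
                           tile_width=tile_width, decay_scale=decay_scale,
                           seed=seed, kmer_bias=lognormal_bias(seed),
                           track_block_length=10 * tile_width, **extra)


@dataclass
class CohortReplicate:
    seed: int
    mpv: pd.DataFrame                  # lncRNA x family
    mxpv: pd.DataFrame
    ta_calls: pd.Series
    top_family: pd.Series              # highest-MPV family per lncRNA
    xor_complementarity: float
    xor_single_aurocs: dict[str, float]
    kmer_spearman: tuple[float, float]  # rho, p for the triplex lncRNA
    full_model_auroc: pd.Series
    datasets: dict[str, LabeledDataset] = field(repr=False, default_factory=dict)
    features: dict[str, FeatureTable] = field(repr=False, default_factory=dict)
    results: dict[str, ResultSet] = field(repr=False, default_factory=dict)


def _fit_ensemble(name, dataset, features, tiling, seed, trees, n_pc,
                  neighbors=NEIGHBORS, K=K_FOLDS):
    blocks = make_blocks(dataset, tiling, neighbors_per_seed=neighbors,
                         seed=derive_seed(seed, name, "blocks"))
    part = assign_folds(dataset, K=K, mode="block", block_of=blocks,
                        seed=derive_seed(seed, name, "folds"))
    specs = enumerate_model_specs(features.schema, name, trees=trees, n_pc=n_pc,
                                  seed=derive_seed(seed, name, "rf"))
    pc_cache: dict = {}
    return ResultSet([train_and_eval(s, dataset, part, features, pc_cache=pc_cache)
                      for s in specs]), part


def run_cohort_replicate(seed: int, n_pos: int = N_POS, trees: int = TREES,
                         ratio: float = RATIO, cap: int = CAP, n_pc: int = N_PC,
                         effect_size: float = EFFECT_SIZE,
                         ensembles: tuple[str, ...] | None = None,
                         keep_artifacts: bool = False) -> CohortReplicate:
    """One pipeline pass over the four-mechanism cohort.

    ``ensembles`` restricts the full model-set fits to a subset of lncRNAs
    (the XOR complementarity models and the rank/density correlation are
    always computed); None fits every lncRNA.
    """
    cfg = cohort_config(seed, n_pos=n_pos, effect_size=effect_size)
    genome = generate_genome(cfg)
    tracks = generate_context_tracks(cfg, genome)
    imap = generate_interactions(cfg, genome, tracks)
    schema = synthetic_schema()
    tiling = genome.tiling
    if ensembles is None:
        ensembles = tuple(sorted(imap.lncrnas))

    results: dict[str, ResultSet] = {}
    datasets: dict[str, LabeledDataset] = {}
    feats: dict[str, FeatureTable] = {}
    for name in sorted(imap.lncrnas):
        lnc = imap.lncrnas[name]
        ds = build_dataset(lnc, imap.bound[name], tiling, ratio=ratio, cap=cap,
                           seed=derive_seed(seed, name, "negatives"))
        datasets[name] = ds
        if name in ensembles or name == "lnc_xor_pair":
            feats[name] = build_synthetic_features(genome, tracks, name, ds.tile_ids)
        if name in ensembles:
            results[name], _ = _fit_ensemble(name, ds, feats[name], tiling,
                                             seed, trees, n_pc)

    mpv_m = mpv_table(results, schema, K=K_FOLDS, statistic="mpv")
    mxpv_m = mpv_table(results, schema, K=K_FOLDS, statistic="mxpv")
    ta, _ = classify_ta(mpv_m, family="transcription", threshold=0.01)
    top = mpv_m.idxmax(axis=1)

    # XOR complementarity: dedicated single-family and pair models
    xor_name = "lnc_xor_pair"
    ds, ft = datasets[xor_name], feats[xor_name]
    blocks = make_blocks(ds, tiling, NEIGHBORS, seed=derive_seed(seed, xor_name, "blocks"))
    part = assign_folds(ds, K=K_FOLDS, mode="block", block_of=blocks,
                        seed=derive_seed(seed, xor_name, "folds"))
    comp_specs = [ModelSpec(xor_name, (XOR_PAIR[0],), RAW, trees=trees,
                            seed=derive_seed(seed, xor_name, "comp")),
                  ModelSpec(xor_name, (XOR_PAIR[1],), RAW, trees=trees,
                            seed=derive_seed(seed, xor_name, "comp")),
                  ModelSpec(xor_name, XOR_PAIR, RAW, trees=trees,
                            seed=derive_seed(seed, xor_name, "comp"))]
    comp_rs = ResultSet([train_and_eval(s, ds, part, ft) for s in comp_specs])
    comp = complementarity(comp_rs, *XOR_PAIR)
    singles = {f: comp_rs.get(RAW, (f,)).mean_auroc for f in XOR_PAIR}

    # 5-mer importance ranks vs lncRNA-sequence density (triplex lncRNA)
    tri = "lnc_triplex"
    # the scaled ensemble has only 3 sequence-only specs; the top-20% cut
    # of the full-size ensemble is widened to 50% here so that several
    # k-mer-bearing forests contribute ranks (see docs/methods.md)
    ranks = aggregate_feature_ranks(results[tri].results, percentile=50,
                                    category=PRIMARY, schema=schema)
    kmer_ranks = ranks.loc[[f for f in ranks.index if f in set(canonical_kmers(5))],
                           "median_rank"]
    density = pd.Series(kmer_density(imap.lncrnas[tri].transcript),
                        index=list(canonical_kmers(5)))
    rho_p = kmer_density_correlation(kmer_ranks, density)

    all_secondary = tuple(sorted(schema.family_names("secondary")))
    full = pd.Series({n: results[n].get("sequence_pc", all_secondary).mean_auroc
                      for n in results})
    rep = CohortReplicate(seed, mpv_m, mxpv_m, ta, top, comp, singles, rho_p, full)
    if keep_artifacts:
        rep.datasets, rep.features, rep.results = datasets, feats, results
    return rep


def mechanism_recovery_study(base_seed: int, n_replicates: int = 10,
                             **kwargs) -> pd.DataFrame:
    """Replicated cohort runs; one row per replicate with the recovery calls.

    Columns record whether the mechanism-matched family attained the top
    MPV for the transcription and triplex lncRNAs, whether the TA calls
    match the planted mechanisms, the XOR complementarity and single-family
    AUROCs, and the k-mer rank/density Spearman rho and p.  Only the
    transcription and triplex model ensembles are fitted per replicate (the
    XOR complementarity set is separate and cheap); the noise-lncRNA MPV
    calibration has its own larger-n check, :func:`noise_mpv_check`.
    """
    kwargs.setdefault("ensembles", ("lnc_transcription", "lnc_triplex"))
    rows = []
    for i in range(n_replicates):
        rep = run_cohort_replicate(derive_seed(base_seed, "replicate", i), **kwargs)
        rows.append({
            "seed": rep.seed,
            "transcription_top": rep.top_family["lnc_transcription"] == "transcription",
            "triplex_top": rep.top_family["lnc_triplex"] == "triplex",
            # the TA dichotomy is defined by the transcription vs triplex
            # mechanisms; xor/noise lncRNAs have no planted TA identity
            "ta_correct": (bool(rep.ta_calls["lnc_transcription"])
                           and not bool(rep.ta_calls["lnc_triplex"])),
            "xor_complementarity": rep.xor_complementarity,
            "xor_single_max_auroc": max(rep.xor_single_aurocs.values()),
            "kmer_spearman_rho": rep.kmer_spearman[0],
            "kmer_spearman_p": rep.kmer_spearman[1],
        })
    return pd.DataFrame(rows)


def noise_mpv_check(seed: int, n_pos: int = 700, trees: int = TREES,
                    ratio: float = RATIO, cap: int = CAP, n_pc: int = N_PC,
                    chrom_tiles: int = 22_000,
                    decay_scale: float = 2_500_000.0,
                    n_seeds: int = 3) -> pd.Series:
    """Seed-averaged family MPVs for a pure-noise lncRNA (calibration).

    A lncRNA with no planted signal should have every family MPV near
    zero.  Two properties of the estimator make this a *seed-averaged*
    check at >= 4000 examples: the finite-pool pessimism of CV-AUC on null
    features (negligible at this n, not at a few hundred examples), and
    realization-level chance alignment between the autocorrelated context
    tracks and the spatial layout of one interaction map, which no amount
    of cross-validation inside that realization can remove (see
    docs/methods.md).
    """
    per_seed = []
    for i in range(n_seeds):
        s = derive_seed(seed, "noise-rep", i)
        mid = chrom_tiles * 1000 // 2
        cfg = SyntheticConfig(
            n_chroms=1, chrom_length=chrom_tiles * 1000,
            lncrnas=(LncSpec("lnc_noise", "chr1", mid - 1000, mid + 1000,
                             mechanism="noise", n_target_positives=n_pos),),
            decay_scale=decay_scale, seed=s, kmer_bias=lognormal_bias(s),
            track_block_length=10_000.0)
        genome = generate_genome(cfg)
        tracks = generate_context_tracks(cfg, genome)
        imap = generate_interactions(cfg, genome, tracks)
        name = "lnc_noise"
        ds = build_dataset(imap.lncrnas[name], imap.bound[name], genome.tiling,
                           ratio=ratio, cap=cap,
                           seed=derive_seed(s, name, "negatives"))
        ft = build_synthetic_features(genome, tracks, name, ds.tile_ids)
        rs, _ = _fit_ensemble(name, ds, ft, genome.tiling, s, trees, n_pc)
        per_seed.append(mpv_table({name: rs}, synthetic_schema(),
                                  K=K_FOLDS).loc[name])
    return pd.concat(per_seed, axis=1).mean(axis=1)


def _context_only_schema() -> FamilySchema:
    return FamilySchema((Family("context", PRIMARY,
                                ("gro_like", "polii_like", "meth", "chrom_mark")),))


def leakage_study(base_seed: int, n_seeds: int = 12, n_pos: int = 150,
                  trees: int = TREES, K: int = K_FOLDS) -> pd.DataFrame:
    """Random-CV vs block-CV AUROC on autocorrelated context tracks.

    One transcription-mechanism lncRNA per seed; the same model (raw context
    features) is evaluated under both partitions.  Random CV is expected to
    be the more optimistic estimate.
    """
    rows = []
    schema = _context_only_schema()
    for i in range(n_seeds):
        seed = derive_seed(base_seed, "leakage", i)
        cfg = cohort_config(seed, n_pos=n_pos)
        cfg = SyntheticConfig(n_chroms=1, chrom_length=cfg.chrom_length,
                              lncrnas=(cfg.lncrnas[0],), tile_width=cfg.tile_width,
                              decay_scale=cfg.decay_scale, seed=seed,
                              kmer_bias={}, track_block_length=cfg.track_block_length)
        genome = generate_genome(cfg)
        tracks = generate_context_tracks(cfg, genome)
        imap = generate_interactions(cfg, genome, tracks)
        name = cfg.lncrnas[0].name
        ds = build_dataset(imap.lncrnas[name], imap.bound[name], genome.tiling,
                           ratio=RATIO, cap=CAP, seed=derive_seed(seed, "neg"))
        df = pd.DataFrame(
            {t: [tracks.values[t][genome.tiling.chrom_of([tid])[0]]
                 [genome.tiling.starts_of([tid])[0] // cfg.tile_width]
                 for tid in ds.tile_ids] for t in schema["context"].features},
            index=ds.tile_ids)
        ft = FeatureTable(df, schema)
        spec = ModelSpec(name, ("context",), RAW, trees=trees,
                         seed=derive_seed(seed, "model"))
        blocks = make_blocks(ds, genome.tiling, NEIGHBORS, seed=derive_seed(seed, "b"))
        block_part = assign_folds(ds, K=K, mode="block", block_of=blocks,
                                  seed=derive_seed(seed, "bf"))
        random_part = assign_folds(ds, K=K, mode="random", seed=derive_seed(seed, "rf"))
        a_block = train_and_eval(spec, ds, block_part, ft).mean_auroc
        a_random = train_and_eval(spec, ds, random_part, ft).mean_auroc
        rows.append({"seed": seed, "auroc_random": a_random, "auroc_block": a_block})
    return pd.DataFrame(rows)


def negative_matching_check(seed: int, n_pos: int = 2000, ratio: float = 2.0,
                            chrom_tiles: int = 30_000, tile_width: int = 1000,
                            decay_scale: float = 4_000_000.0) -> dict:
    """Distance match of sampled negatives vs positives on one chromosome.

    Positives are drawn from the exponential distance law directly (no
    sequence needed); the report is the two-sample KS D between positive
    and sampled-negative gene distances.
    """
    from .genome import tile_genome
    from .interactome import LncRNA

    rng = np.random.default_rng(seed)
    tiling = tile_genome({"chr1": chrom_tiles * tile_width}, tile_width)
    mid = chrom_tiles // 2
    gene = (mid * tile_width - tile_width, mid * tile_width + tile_width)
    tiles = tiling.chrom_tile_ids("chr1")
    d = tiling.gene_distances(tiles, "chr1", *gene)
    p = np.exp(-d / decay_scale)
    keys = -np.log(rng.random(len(tiles))) / p
    positives = tiles[np.argsort(keys, kind="stable")[:n_pos]]
    lnc = LncRNA("lnc", "chr1", gene[0], gene[1])
    ds = build_dataset(lnc, positives, tiling, ratio=ratio, cap=CAP,
                       seed=derive_seed(seed, "neg"))
    pos_d = np.array([ds.distance[int(t)] for t in ds.positives])
    neg_d = np.array([ds.distance[int(t)] for t in ds.negatives])
    d_signed, pval = signed_ks(pos_d, neg_d)
    return {"ks_d": abs(d_signed), "p": pval, "n_pos": len(pos_d),
            "n_neg": len(neg_d)}


def permutation_null_fpr(seed: int, n_pos: int = 150, n_kmer_features: int = 26,
                         alpha: float = 0.05) -> dict:
    """False-positive rate of the enrichment battery under permuted labels.

    Bound/unbound labels are shuffled within each lncRNA's dataset, so no
    feature is truly associated; the BH-adjusted discovery fraction should
    stay at or below alpha.
    """
    cfg = cohort_config(seed, n_pos=n_pos)
    genome = generate_genome(cfg)
    tracks = generate_context_tracks(cfg, genome)
    imap = generate_interactions(cfg, genome, tracks)
    rng = np.random.default_rng(derive_seed(seed, "permute"))
    kmers = list(canonical_kmers(5))[::512 // n_kmer_features][:n_kmer_features]
    battery = {}
    for name in sorted(imap.lncrnas):
        ds = build_dataset(imap.lncrnas[name], imap.bound[name], genome.tiling,
                           ratio=RATIO, cap=CAP, seed=derive_seed(seed, name, "neg"))
        ft = build_synthetic_features(genome, tracks, name, ds.tile_ids)
        labels = ds.labels.copy()
        rng.shuffle(labels)
        vals = ft.values
        feats = kmers + list(ft.schema.features_of(["transcription", "methylation",
                                                    "chromatin", "triplex"]))
        for f in feats:
            v = vals[f].to_numpy(dtype=float)
            battery[(name, f)] = (v[labels == 1], v[labels == 0])
    df = enrichment_battery(battery, alpha=alpha)
    return {"fpr": float((df["p_adj"] < alpha).mean()), "n_tests": len(df)}
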