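"""End-to-end orchestration with content-hash caching.

``run_all`` executes the stage chain

    synth -> select -> datasets -> cv -> features -> models -> importance -> stats

inside a run directory.  Every stage writes plain files (TSV / FASTA /
bedGraph / JSON-lines) and records a content hash of its configuration and
its upstream hashes in ``manifest.json``; a stage whose hash matches and
whose outputs exist is skipped, so reruns are incremental: changing, say,
the negative-sampling ratio reruns the dataset stage and everything
downstream while the synthetic genome stays cached.

Defaults follow the reference analysis: 1 kb tiles, at least 1000 bound
tiles per analyzed lncRNA, 5:1 negatives with a 100-per-anchor cap, 5-fold
CV, 1000-tree forests of depth 10 and leaf size 10, 100 sequence PCs, and a
TA threshold of MPV >= 0.01.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .cv import assign_folds, make_blocks
from .dataset import build_dataset
from .features import build_synthetic_features, synthetic_schema
from .importance import ResultSet, aggregate_feature_ranks, classify_ta, mpv_table
from .interactome import InteractionMap, LncRNA, load_interactions, select_lncrnas
from .kmers import encode_sequence
from .modeling import derive_seed, enumerate_model_specs, train_and_eval
from .schema import PRIMARY, SECONDARY
from .stats import enrichment_battery, seed_enrichment_matrix
from .synthetic import (LncSpec, SyntheticConfig, SyntheticGenome, SyntheticTracks,
                        generate_context_tracks, generate_genome,
                        generate_interactions)
from .genome import tile_genome

__all__ = ["RunConfig", "run_all", "load_run_config"]

logger = logging.getLogger(__name__)

STAGES = ["synth", "select", "datasets", "cv", "features", "models",
          "importance", "stats"]


@dataclass
class RunConfig:
    synth: SyntheticConfig
    out_dir: str = "run"
    min_tiles: int = 1000
    ratio: float = 5.0
    cap: int = 100
    K: int = 5
    neighbors_per_seed: int = 49
    trees: int = 1000
    n_pc: int = 100
    ta_threshold: float = 0.01
    pwm_pval: float = 1e-4
    rank_percentile: float = 20.0
    seed: int = 0

    def stage_params(self, stage: str) -> dict:
        """The configuration slice a stage's outputs depend on."""
        deps = {
            "synth": {"synth": asdict(self.synth)},
            "select": {"min_tiles": self.min_tiles},
            "datasets": {"ratio": self.ratio, "cap": self.cap, "seed": self.seed},
            "cv": {"K": self.K, "neighbors_per_seed": self.neighbors_per_seed,
                   "seed": self.seed},
            "features": {},
            "models": {"trees": self.trees, "n_pc": self.n_pc, "K": self.K,
                       "seed": self.seed},
            "importance": {"ta_threshold": self.ta_threshold,
                           "rank_percentile": self.rank_percentile},
            "stats": {},
        }
        return deps[stage]


def load_run_config(path) -> RunConfig:
    """Read the documented YAML schema into a RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    synth_raw = dict(raw["synth"])
    lncs = tuple(LncSpec(**d) for d in synth_raw.pop("lncrnas"))
    synth = SyntheticConfig(lncrnas=lncs, **synth_raw)
    pipe = dict(raw.get("pipeline", {}))
    return RunConfig(synth=synth, **pipe)


def _hash(obj, *extra: str) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str) + "|".join(extra)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, run_dir: Path):
        self.path = run_dir / "manifest.json"
        self.data = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def fresh(self, stage: str, h: str, outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        return (rec is not None and rec["hash"] == h
                and all(Path(p).exists() for p in rec["outputs"]))

    def record(self, stage: str, h: str, outputs: list[Path]) -> None:
        self.data[stage] = {"hash": h, "outputs": [str(p) for p in outputs]}
        self.path.write_text(json.dumps(self.data, indent=1))

    def hash_of(self, stage: str) -> str:
        return self.data[stage]["hash"]


def _load_genome_artifacts(run_dir: Path, tile_width: int):
    """Rebuild the minimal genome/tracks view the feature stage needs from
    the synth stage's files."""
    seqs = {c: encode_sequence(s)
            for c, s in lio.read_fasta(run_dir / "synth" / "genome.fa").items()}
    transcripts = lio.read_fasta(run_dir / "synth" / "transcripts.fa")
    tiling = tile_genome({c: len(s) for c, s in seqs.items()}, tile_width)
    genes = {row["name"]: (row["chrom"], int(row["start"]), int(row["end"]))
             for _, row in lio.read_bed(run_dir / "synth" / "genes.bed").iterrows()}
    track_values: dict[str, dict[str, np.ndarray]] = {}
    for tf in sorted((run_dir / "synth" / "tracks").glob("*.bedgraph")):
        df = pd.read_csv(tf, sep="\t", header=None,
                         names=["chrom", "start", "end", "score"])
        per_chrom = {}
        for chrom, sub in df.groupby("chrom"):
            sub = sub.sort_values("start")
            per_chrom[chrom] = sub["score"].to_numpy()
        track_values[tf.stem] = per_chrom
    genome = SyntheticGenome(tiling, seqs, genes, transcripts, {}, [], {}, {},
                             "", {}, {})
    tracks = SyntheticTracks(track_values, {}, {})
    return genome, tracks, tiling


def run_all(config: RunConfig) -> Path:
    """Execute (or resume) the full pipeline; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir)
    upstream = ""
    for stage in STAGES:
        h = _hash(config.stage_params(stage), upstream)
        outputs = _stage_outputs(stage, run_dir)
        if manifest.fresh(stage, h, outputs):
            logger.info("stage %s up to date; skipped", stage)
        else:
            logger.info("running stage %s", stage)
            try:
                _run_stage(stage, config, run_dir)
            except Exception:
                logger.error("stage %s failed (hash %s)", stage, h)
                raise
            manifest.record(stage, h, _stage_outputs(stage, run_dir))
        upstream = h
    return run_dir


def _stage_outputs(stage: str, run_dir: Path) -> list[Path]:
    fixed = {
        "synth": [run_dir / "synth" / "interactions.tsv",
                  run_dir / "synth" / "genome.fa"],
        "select": [run_dir / "selected.tsv"],
        "importance": [run_dir / "importance" / "mpv.tsv",
                       run_dir / "importance" / "ta_calls.tsv"],
        "stats": [run_dir / "stats" / "enrichment.tsv"],
    }
    if stage in fixed:
        return fixed[stage]
    sub = {"datasets": "datasets", "cv": "cv", "features": "features",
           "models": "models"}[stage]
    d = run_dir / sub
    return sorted(d.glob("*")) if d.exists() else [d / ".missing"]


def _selected_names(run_dir: Path) -> list[str]:
    df = pd.read_csv(run_dir / "selected.tsv", sep="\t")
    return df.loc[df.selected, "name"].tolist()


def _interaction_map(config: RunConfig, run_dir: Path, tiling) -> InteractionMap:
    genes = lio.read_bed(run_dir / "synth" / "genes.bed")
    transcripts = lio.read_fasta(run_dir / "synth" / "transcripts.fa")
    lncrnas = {row["name"]: LncRNA(row["name"], row["chrom"], int(row["start"]),
                                   int(row["end"]), transcripts.get(row["name"], ""))
               for _, row in genes.iterrows()}
    return load_interactions(run_dir / "synth" / "interactions.tsv", tiling, lncrnas)


def _run_stage(stage: str, config: RunConfig, run_dir: Path) -> None:
    tw = config.synth.tile_width
    if stage == "synth":
        genome = generate_genome(config.synth)
        tracks = generate_context_tracks(config.synth, genome)
        imap = generate_interactions(config.synth, genome, tracks)
        lio.export_synthetic_run(run_dir / "synth", genome, tracks, imap.bound, tw)
        return

    genome, tracks, tiling = _load_genome_artifacts(run_dir, tw)
    imap = _interaction_map(config, run_dir, tiling)

    if stage == "select":
        select_lncrnas(imap, config.min_tiles).to_csv(
            run_dir / "selected.tsv", sep="\t", index=False)
        return

    names = _selected_names(run_dir)
    if stage == "datasets":
        (run_dir / "datasets").mkdir(exist_ok=True)
        for name in names:
            ds = build_dataset(imap.lncrnas[name], imap.bound[name], tiling,
                               ratio=config.ratio, cap=config.cap,
                               seed=derive_seed(config.seed, name, "negatives"))
            lio.write_dataset(run_dir / "datasets" / f"{name}.tsv", ds)
        return

    datasets = {name: lio.read_dataset(run_dir / "datasets" / f"{name}.tsv",
                                       name, config.ratio) for name in names}
    if stage == "cv":
        (run_dir / "cv").mkdir(exist_ok=True)
        for name in names:
            blocks = make_blocks(datasets[name], tiling, config.neighbors_per_seed,
                                 seed=derive_seed(config.seed, name, "blocks"))
            part = assign_folds(datasets[name], K=config.K, mode="block",
                                block_of=blocks,
                                seed=derive_seed(config.seed, name, "folds"))
            part.to_frame().to_csv(run_dir / "cv" / f"{name}.tsv", sep="\t",
                                   index=False)
        return

    if stage == "features":
        (run_dir / "features").mkdir(exist_ok=True)
        for name in names:
            ft = build_synthetic_features(genome, tracks, name,
                                          datasets[name].tile_ids)
            ft.to_tsv(run_dir / "features" / f"{name}.tsv",
                      schema_path=run_dir / "features" / "schema.json")
        return

    schema = synthetic_schema()
    if stage == "models":
        from .cv import CVPartition
        from .schema import FeatureTable
        (run_dir / "models").mkdir(exist_ok=True)
        for name in names:
            ft = FeatureTable.from_tsv(run_dir / "features" / f"{name}.tsv", schema)
            folds = pd.read_csv(run_dir / "cv" / f"{name}.tsv", sep="\t")
            part = CVPartition(config.K, "block",
                               dict(zip(folds.tile_id, folds.fold)),
                               dict(zip(folds.tile_id, folds.block_id)))
            specs = enumerate_model_specs(schema, name, trees=config.trees,
                                          n_pc=config.n_pc,
                                          seed=derive_seed(config.seed, name, "rf"))
            pc_cache: dict = {}
            results = [train_and_eval(s, datasets[name], part, ft, pc_cache=pc_cache)
                       for s in specs]
            lio.write_results_jsonl(run_dir / "models" / f"{name}.jsonl", results)
        return

    if stage == "importance":
        (run_dir / "importance").mkdir(exist_ok=True)
        results = {name: ResultSet(lio.read_results_jsonl(
            run_dir / "models" / f"{name}.jsonl")) for name in names}
        mpv_m = mpv_table(results, schema, K=config.K, statistic="mpv")
        mxpv_m = mpv_table(results, schema, K=config.K, statistic="mxpv")
        mpv_m.to_csv(run_dir / "importance" / "mpv.tsv", sep="\t")
        mxpv_m.to_csv(run_dir / "importance" / "mxpv.tsv", sep="\t")
        ta, pval = classify_ta(mpv_m, family="transcription",
                               threshold=config.ta_threshold,
                               test_family="triplex")
        out = pd.DataFrame({"ta": ta})
        out.to_csv(run_dir / "importance" / "ta_calls.tsv", sep="\t")
        for name in names:
            for cat in (PRIMARY, SECONDARY):
                try:
                    ranks = aggregate_feature_ranks(
                        results[name].results, percentile=config.rank_percentile,
                        category=cat, schema=schema)
                except ValueError:
                    continue
                ranks.to_csv(run_dir / "importance" / f"ranks_{name}_{cat}.tsv",
                             sep="\t")
        return

    if stage == "stats":
        from .schema import FeatureTable
        (run_dir / "stats").mkdir(exist_ok=True)
        battery = {}
        kmer_tables = {}
        bound_ids, unbound_ids = {}, {}
        for name in names:
            ft = FeatureTable.from_tsv(run_dir / "features" / f"{name}.tsv", schema)
            ds = datasets[name]
            ctx = schema.features_of(schema.family_names(SECONDARY)) + \
                list(schema["triplex"].features)
            for f in ctx:
                v = ft.values[f]
                battery[(name, f)] = (v.loc[ds.positives].to_numpy(),
                                      v.loc[ds.negatives].to_numpy())
            kmer_tables[name] = ft.matrix(("kmer",))
            bound_ids[name] = ds.positives
            unbound_ids[name] = ds.negatives
        enrichment_battery(battery).to_csv(run_dir / "stats" / "enrichment.tsv",
                                           sep="\t", index=False)
        seeds_df = pd.read_csv(run_dir / "synth" / "mirna_seeds.tsv", sep="\t")
        seeds = dict(zip(seeds_df.mirna, seeds_df.seed))
        kmers = pd.concat(kmer_tables.values())
        kmers = kmers[~kmers.index.duplicated()]
        mat = seed_enrichment_matrix(kmers, bound_ids, unbound_ids, seeds)
        mat.to_csv(run_dir / "stats" / "seed_enrichment.tsv", sep="\t")
        return

    raise ValueError(f"unknown stage {stage!r}")
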