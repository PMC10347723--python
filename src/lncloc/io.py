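"""Plain-text readers/writers for the pipeline's file formats.

Everything is a standard text format: FASTA for sequences, BED (0-based,
half-open) for annotations, bedGraph-like TSV for tracks, TSV for
interaction pairs, labeled datasets and CV folds, JSON-lines for model
results.  Stage outputs stay inspectable and replaceable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .modeling import ModelResult, ModelSpec
from .synthetic import SyntheticGenome, SyntheticTracks

__all__ = ["write_fasta", "read_fasta", "write_bed", "read_bed",
           "write_interactions", "write_dataset", "read_dataset",
           "write_results_jsonl", "read_results_jsonl",
           "export_synthetic_run"]


def write_fasta(path, records, width: int = 80) -> None:
    """Write (name, sequence) pairs as FASTA (path or open file-like)."""

    def _emit(fh):
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")

    if hasattr(path, "write"):
        _emit(path)
    else:
        with open(path, "w") as fh:
            _emit(fh)


def read_fasta(path) -> dict[str, str]:
    """Read a (small, uncompressed) FASTA file into {name: sequence}."""
    out: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif name is not None:
                out[name].append(line)
    return {k: "".join(v) for k, v in out.items()}


def write_bed(path, rows) -> None:
    """Write (chrom, start, end, name[, score, strand]) rows as BED."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_interactions(path, bound: dict[str, np.ndarray]) -> None:
    """Dialect-B pair list: lncRNA <TAB> tile_id."""
    with open(path, "w") as fh:
        for name in sorted(bound):
            for tid in bound[name]:
                fh.write(f"{name}\t{int(tid)}\n")


def write_dataset(path, dataset: LabeledDataset) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def read_dataset(path, lncrna: str, ratio: float = 5.0) -> LabeledDataset:
    df = pd.read_csv(path, sep="\t")
    pos = df.loc[df.label == 1, "tile_id"].to_numpy(dtype=np.int64)
    negrows = df[df.label == 0]
    neg = negrows["tile_id"].to_numpy(dtype=np.int64)
    anchor = dict(zip(neg.tolist(), negrows["anchor_id"].astype(int).tolist()))
    distance = dict(zip(df["tile_id"].astype(int), df["distance_bp"].astype(float)))
    return LabeledDataset(lncrna, np.sort(pos), np.sort(neg), anchor, distance, ratio)


def write_results_jsonl(path, results: list[ModelResult], round_to: int = 6) -> None:
    """One record per model spec: fold metrics + per-fold Gini importances."""
    with open(path, "w") as fh:
        for r in results:
            rec = {
                "lncrna": r.spec.lncrna,
                "representation": r.spec.representation,
                "family_subset": list(r.spec.family_subset),
                "trees": r.spec.trees,
                "seed": r.spec.seed,
                "n_pc": r.spec.n_pc,
                "fold_auroc": [None if np.isnan(a) else round(a, round_to)
                               for a in r.fold_auroc],
                "fold_aupr": [None if np.isnan(a) else round(a, round_to)
                              for a in r.fold_aupr],
                "features": list(r.fold_importances[0].index),
                "fold_importances": [np.round(fi.to_numpy(), round_to).tolist()
                                     for fi in r.fold_importances],
            }
            fh.write(json.dumps(rec) + "\n")


def read_results_jsonl(path) -> list[ModelResult]:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            spec = ModelSpec(rec["lncrna"], tuple(rec["family_subset"]),
                             rec["representation"], trees=rec["trees"],
                             n_pc=rec["n_pc"], seed=rec["seed"])
            imps = [pd.Series(v, index=rec["features"])
                    for v in rec["fold_importances"]]
            out.append(ModelResult(
                spec,
                [float("nan") if a is None else a for a in rec["fold_auroc"]],
                [float("nan") if a is None else a for a in rec["fold_aupr"]],
                imps))
    return out


def export_synthetic_run(outdir, genome: SyntheticGenome, tracks: SyntheticTracks,
                         bound: dict[str, np.ndarray], tile_width: int) -> None:
    """Write a generated study to disk in standard formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", genome.fasta_records())
    write_fasta(outdir / "transcripts.fa", sorted(genome.transcripts.items()))
    write_fasta(outdir / "repeat_consensus.fa", sorted(genome.repeat_consensus.items()))
    write_bed(outdir / "genes.bed",
              [(c, s, e, name, 0, "+") for name, (c, s, e) in sorted(genome.genes.items())])
    write_bed(outdir / "repeats.bed",
              [(c, s, e, fam) for c, s, e, fam in genome.repeat_instances])
    with open(outdir / "mirna_seeds.tsv", "w") as fh:
        fh.write("mirna\tseed\tgroup\n")
        for m in sorted(genome.mirna_seeds):
            fh.write(f"{m}\t{genome.mirna_seeds[m]}\t{genome.mirna_groups[m]}\n")
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for tname, per_chrom in tracks.values.items():
        with open(tracks_dir / f"{tname}.bedgraph", "w") as fh:
            for chrom in sorted(per_chrom):
                vals = per_chrom[chrom]
                for i, v in enumerate(vals):
                    fh.write(f"{chrom}\t{i * tile_width}\t{(i + 1) * tile_width}\t{v:.5f}\n")
    write_interactions(outdir / "interactions.tsv", bound)
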