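"""Feature-table assembly.

Two entry points: ``synthetic_schema`` / ``build_synthetic_features`` give
the compact five-family layout computed directly from a generated genome
(512 canonical 5-mers and the triplex quartet as primary families; the
transcription, methylation and chromatin tracks as secondary families), and
``build_feature_table`` assembles a table from external-style resources
(sequences, PWMs, repeat intervals, scored tracks, a PPI edge list) through
the per-family operations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import TiledGenome
from .kmers import canonical_kmers, count_canonical_kmers_encoded, count_canonical_kmers
from .pwm import PWM, pwm_threshold, scan_and_merge, scan_hits
from .schema import Family, FamilySchema, FeatureTable, PRIMARY, SECONDARY
from .synthetic import SyntheticGenome, SyntheticTracks
from .tracks import (IntervalTrack, aggregate_track, paired_context_features,
                     repeat_features, repeat_pair, shared_motif_features)
from .triplex import BuiltinTriplexScorer, ExternalTriplexProvider

__all__ = ["synthetic_schema", "build_synthetic_features", "build_feature_table"]

TRIPLEX_FEATURES = ("triplex_pairs", "triplex_total_len", "triplex_max_score",
                    "triplex_coverage")


def synthetic_schema() -> FamilySchema:
    """The reduced family layout of the synthetic study (2 primary + 3
    secondary families)."""
    return FamilySchema((
        Family("kmer", PRIMARY, canonical_kmers(5)),
        Family("triplex", PRIMARY, TRIPLEX_FEATURES),
        Family("transcription", SECONDARY, ("gro_like", "polii_like")),
        Family("methylation", SECONDARY, ("meth",)),
        Family("chromatin", SECONDARY, ("chrom_mark",)),
    ))


def build_synthetic_features(genome: SyntheticGenome, tracks: SyntheticTracks,
                             lncrna_name: str, tile_ids: np.ndarray,
                             triplex_provider=None) -> FeatureTable:
    """Materialize the synthetic feature table for one lncRNA's tiles.

    Triplex features are lncRNA-specific; by default the built-in scorer
    runs against the lncRNA transcript, or pass an
    :class:`~lncloc.triplex.ExternalTriplexProvider`.
    """
    schema = synthetic_schema()
    tiling = genome.tiling
    w = tiling.tile_width
    tile_ids = np.asarray(tile_ids, dtype=np.int64)
    chroms = tiling.chrom_of(tile_ids)
    starts = tiling.starts_of(tile_ids)
    scorer = None
    if triplex_provider is None:
        scorer = BuiltinTriplexScorer(genome.transcripts[lncrna_name])

    kmer_rows = np.empty((len(tile_ids), 512), dtype=np.int64)
    quartets = np.empty((len(tile_ids), 4))
    ctx = {t: np.empty(len(tile_ids)) for t in tracks.values}
    for i, (tid, chrom, start) in enumerate(zip(tile_ids, chroms, starts)):
        codes = genome.sequences[chrom][start:start + w]
        kmer_rows[i] = count_canonical_kmers_encoded(codes, 5)
        if scorer is not None:
            seq = genome.tile_sequence(chrom, start // w, w)
            quartets[i] = scorer(seq)
        else:
            quartets[i] = triplex_provider(lncrna_name, int(tid))
        ti = start // w
        for t in tracks.values:
            ctx[t][i] = tracks.values[t][chrom][ti]

    df = pd.DataFrame(kmer_rows, index=tile_ids, columns=list(canonical_kmers(5)))
    for j, name in enumerate(TRIPLEX_FEATURES):
        df[name] = quartets[:, j]
    for t, vals in ctx.items():
        df[t] = vals
    return FeatureTable(df, schema)


def build_feature_table(tiling: TiledGenome, sequences: dict[str, str],
                        tile_ids: np.ndarray,
                        lncrna=None,
                        tf_pwms: dict[str, list[PWM]] | None = None,
                        rbp_pwms: dict[str, list[PWM]] | None = None,
                        repeat_track: IntervalTrack | None = None,
                        repeat_labels: np.ndarray | None = None,
                        repeat_families: list[str] | None = None,
                        ppi_edges: list[tuple[str, str]] | None = None,
                        max_tracks: dict[str, IntervalTrack] | None = None,
                        sum_tracks: dict[str, IntervalTrack] | None = None,
                        antigen_tracks: dict[str, IntervalTrack] | None = None,
                        mark_tracks: dict[str, IntervalTrack] | None = None,
                        pwm_pval: float = 1e-4,
                        triplex_provider=None) -> pd.DataFrame:
    """Assemble a tiles x features frame from external-style resources.

    Intended for modest tile counts (the scan is exhaustive); families with
    no resources supplied are skipped.  Returns a plain DataFrame — wrap in
    a :class:`~lncloc.schema.FeatureTable` with the matching schema.
    """
    tf_pwms = tf_pwms or {}
    rbp_pwms = rbp_pwms or {}
    tile_ids = np.asarray(tile_ids, dtype=np.int64)
    w = tiling.tile_width
    chroms = tiling.chrom_of(tile_ids)
    starts = tiling.starts_of(tile_ids)
    thresholds = {p.name: pwm_threshold(p, pwm_pval)
                  for pw in list(tf_pwms.values()) + list(rbp_pwms.values()) for p in pw}

    lnc_tf_hits: set[str] = set()
    lnc_rbp_hits: set[str] = set()
    lnc_repeat_fams: set[str] = set()
    scorer = None
    if lncrna is not None:
        gene_seq = sequences[lncrna.chrom][lncrna.gene_start:lncrna.gene_end]
        lnc_tf_hits = {prot for prot, pws in tf_pwms.items()
                       if _any_hit(gene_seq, pws, thresholds)}
        lnc_rbp_hits = {prot for prot, pws in rbp_pwms.items()
                        if _any_hit(lncrna.transcript, pws, thresholds, both_strands=False)}
        if repeat_track is not None:
            idx = repeat_track.overlapping(lncrna.chrom, lncrna.gene_start, lncrna.gene_end)
            lnc_repeat_fams = {repeat_labels[i] for i in idx}
        if triplex_provider is None:
            scorer = BuiltinTriplexScorer(lncrna.transcript)

    rows = []
    for tid, chrom, start in zip(tile_ids, chroms, starts):
        seq = sequences[chrom][start:start + w]
        row: dict[str, float] = {}
        row.update(zip(canonical_kmers(5), count_canonical_kmers(seq, 5)))
        for prot, pws in tf_pwms.items():
            row[f"tf_motif_{prot}"] = scan_and_merge(seq, pws, thresholds)
        for prot, pws in rbp_pwms.items():
            # the tile's putative transcript: sense strand read as RNA
            row[f"rbp_motif_{prot}"] = scan_and_merge(seq, pws, thresholds,
                                                      both_strands=False)
        if repeat_track is not None:
            fams = repeat_families or sorted(set(repeat_labels.tolist()))
            counts = repeat_features(chrom, start, start + w, repeat_track,
                                     fams, repeat_labels)
            row.update({f"repeat_{f}": v for f, v in counts.items()})
            if lncrna is not None:
                tile_fams = {f for f, v in counts.items() if v > 0}
                row["repeat_pair"] = repeat_pair(tile_fams, lnc_repeat_fams)
        if lncrna is not None:
            quartet = (scorer(seq) if scorer is not None
                       else triplex_provider(lncrna.name, int(tid)))
            row.update(zip(TRIPLEX_FEATURES, quartet))
            tile_tf = {p for p, pws in tf_pwms.items() if _any_hit(seq, pws, thresholds)}
            tile_rbp = {p for p, pws in rbp_pwms.items()
                        if _any_hit(seq, pws, thresholds, both_strands=False)}
            tf_p, rbp_p, ppi_p = shared_motif_features(
                tile_tf, lnc_tf_hits, tile_rbp, lnc_rbp_hits, ppi_edges or [])
            row.update({"tf_pair": tf_p, "rbp_pair": rbp_p, "ppi_pair": ppi_p})
        for name, track in (max_tracks or {}).items():
            row[name] = aggregate_track(track, chrom, start, start + w, "max")
        for name, track in (sum_tracks or {}).items():
            row[name] = aggregate_track(track, chrom, start, start + w, "sum")
        if lncrna is not None and (antigen_tracks or mark_tracks):
            chip_p, chrom_p = paired_context_features(
                (chrom, start, start + w),
                (lncrna.chrom, lncrna.gene_start, lncrna.gene_end),
                antigen_tracks or {}, mark_tracks or {})
            row.update({"chip_pair": chip_p, "chromatin_pair": chrom_p})
        rows.append(row)
    return pd.DataFrame(rows, index=tile_ids)


def _any_hit(seq: str, pwms: list[PWM], thresholds: dict[str, float],
             both_strands: bool = True) -> bool:
    return any(scan_hits(seq, p, thresholds[p.name], both_strands=both_strands)
               for p in pwms)
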