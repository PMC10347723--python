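"""Interval tracks and the overlap-based context features.

Tracks are bedGraph-like collections of scored intervals (0-based,
half-open).  Cell-context features summarize a track over a tile either by
the maximum overlapping score (peak-style data: accessibility, ChIP,
RNA-seq, CAGE) or by the base-pair-weighted sum (methylation, nascent
transcription coverage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntervalTrack",
    "aggregate_track",
    "repeat_features",
    "repeat_pair",
    "shared_motif_features",
    "paired_context_features",
]

logger = logging.getLogger(__name__)


@dataclass
class IntervalTrack:
    """Scored intervals on one genome, grouped by chromosome and sorted."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.ends < self.starts).any():
            raise ValueError("negative-length interval in track")
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        for name in ("chroms", "starts", "ends", "scores"):
            setattr(self, name, getattr(self, name)[order])

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of intervals overlapping [start, end) on `chrom`."""
        m = self.chroms == chrom
        idx = np.nonzero(m & (self.starts < end) & (self.ends > start))[0]
        return idx

    @classmethod
    def from_bedgraph(cls, path) -> "IntervalTrack":
        data = np.genfromtxt(path, dtype=None, encoding="utf-8",
                             names=["chrom", "start", "end", "score"], ndmin=1)
        return cls(data["chrom"].astype(object), data["start"], data["end"], data["score"])

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e, v in zip(self.chroms, self.starts, self.ends, self.scores):
                fh.write(f"{c}\t{s}\t{e}\t{v:g}\n")


def aggregate_track(track: IntervalTrack, chrom: str, start: int, end: int,
                    mode: str = "max") -> float:
    """Summarize a track over a tile.

    mode='max': maximum score of overlapping intervals (0 if none).
    mode='sum': per-base sum within the tile, i.e. score x overlap length,
    which is additive over any partition of the tile.
    """
    idx = track.overlapping(chrom, start, end)
    if len(idx) == 0:
        return 0.0
    if mode == "max":
        return float(track.scores[idx].max())
    if mode == "sum":
        ov = np.minimum(track.ends[idx], end) - np.maximum(track.starts[idx], start)
        return float((track.scores[idx] * ov).sum())
    raise ValueError(f"unknown mode {mode!r}")


def repeat_features(chrom: str, start: int, end: int,
                    repeat_instances: IntervalTrack, families: list[str],
                    family_labels: np.ndarray) -> dict[str, int]:
    """Per-repeat-family count of instance intervals overlapping a tile.

    ``family_labels`` gives the family of each interval in
    ``repeat_instances``; unknown labels grow the output, logged.
    """
    idx = repeat_instances.overlapping(chrom, start, end)
    out = {f: 0 for f in families}
    for i in idx:
        fam = family_labels[i]
        if fam not in out:
            logger.info("unknown repeat family %r; adding column", fam)
            out[fam] = 0
        out[fam] += 1
    return out


def repeat_pair(tile_families: set[str], lncrna_families: set[str]) -> int:
    """Number of repeat families present on both the tile and the lncRNA gene."""
    return len(tile_families & lncrna_families)


def shared_motif_features(tile_tf_hits: set[str], lnc_tf_hits: set[str],
                          tile_rbp_hits: set[str], lnc_rbp_hits: set[str],
                          ppi_edges: list[tuple[str, str]]) -> tuple[int, int, int]:
    """(TF_pair, RBP_pair, PPI_pair) shared-motif features.

    TF_pair / RBP_pair count proteins hitting both the lncRNA side and the
    tile side.  PPI_pair counts unordered protein pairs (p, q) connected in
    the protein-protein interaction network with p hitting the lncRNA side
    and q the tile side (either protein class on either side), deduplicated.
    """
    tf_pair = len(tile_tf_hits & lnc_tf_hits)
    rbp_pair = len(tile_rbp_hits & lnc_rbp_hits)
    lnc_side = lnc_tf_hits | lnc_rbp_hits
    tile_side = tile_tf_hits | tile_rbp_hits
    pairs = set()
    for p, q in ppi_edges:
        if (p in lnc_side and q in tile_side) or (q in lnc_side and p in tile_side):
            pairs.add(frozenset((p, q)))
    return tf_pair, rbp_pair, len(pairs)


def paired_context_features(tile: tuple[str, int, int], lncrna_gene: tuple[str, int, int],
                            antigen_tracks: dict[str, IntervalTrack],
                            mark_tracks: dict[str, IntervalTrack]) -> tuple[int, int]:
    """(ChIP_pair, chromatin_pair): antigens / histone marks with at least one
    peak on both the DNA tile and the lncRNA gene."""

    def _shared(tracks: dict[str, IntervalTrack]) -> int:
        n = 0
        for track in tracks.values():
            on_tile = len(track.overlapping(*tile)) > 0
            on_gene = len(track.overlapping(*lncrna_gene)) > 0
            if on_tile and on_gene:
                n += 1
        return n

    return _shared(antigen_tracks), _shared(mark_tracks)
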