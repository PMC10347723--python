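"""Genome tiling: the coordinate backbone.

The genome is segmented into fixed-width, non-overlapping tiles (1 kb by
default); a trailing partial tile on each chromosome is dropped.  Tiles get
dense integer ids ordered by (chromosome, start), and every downstream stage
addresses the genome through these ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TiledGenome", "tile_genome", "interval_gap"]


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Minimum gap in bp between two half-open intervals; 0 if they overlap.

    This is the distance notion used throughout: symmetric and
    orientation-free.
    """
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


@dataclass(frozen=True)
class TiledGenome:
    """Fixed-width tiling of a genome with a (chrom, start) <-> id bijection.

    Attributes
    ----------
    chrom_sizes:
        Mapping chromosome name -> length in bp, in tiling order.
    tile_width:
        Width of every tile in bp.
    """

    chrom_sizes: dict[str, int]
    tile_width: int
    _chroms: tuple[str, ...] = field(init=False, repr=False)
    _n_tiles: dict[str, int] = field(init=False, repr=False)
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tile_width < 1:
            raise ValueError("tile_width must be >= 1")
        chroms = tuple(self.chrom_sizes)
        n_tiles: dict[str, int] = {}
        offsets: dict[str, int] = {}
        total = 0
        for c in chroms:
            size = self.chrom_sizes[c]
            n = size // self.tile_width
            if n == 0:
                warnings.warn(f"chromosome {c!r} shorter than one tile; zero tiles")
            n_tiles[c] = n
            offsets[c] = total
            total += n
        object.__setattr__(self, "_chroms", chroms)
        object.__setattr__(self, "_n_tiles", n_tiles)
        object.__setattr__(self, "_offsets", offsets)

    @property
    def n_tiles(self) -> int:
        return sum(self._n_tiles.values())

    def chrom_tile_count(self, chrom: str) -> int:
        return self._n_tiles[chrom]

    def chrom_tile_ids(self, chrom: str) -> np.ndarray:
        off = self._offsets[chrom]
        return np.arange(off, off + self._n_tiles[chrom], dtype=np.int64)

    def tile_id(self, chrom: str, position: int) -> int | None:
        """Id of the tile containing a genomic position; None if the position
        falls in the dropped trailing partial tile."""
        idx = position // self.tile_width
        if idx >= self._n_tiles[chrom]:
            return None
        return self._offsets[chrom] + idx

    def locate(self, tile_id: int) -> tuple[str, int]:
        """Inverse mapping: tile id -> (chrom, start)."""
        for c in self._chroms:
            off = self._offsets[c]
            n = self._n_tiles[c]
            if off <= tile_id < off + n:
                return c, (tile_id - off) * self.tile_width
        raise KeyError(f"tile id {tile_id} out of range")

    def chrom_of(self, tile_ids: np.ndarray) -> np.ndarray:
        """Vectorized chromosome lookup for an array of tile ids."""
        bounds = np.cumsum([self._n_tiles[c] for c in self._chroms])
        idx = np.searchsorted(bounds, np.asarray(tile_ids), side="right")
        return np.array(self._chroms, dtype=object)[idx]

    def starts_of(self, tile_ids: np.ndarray) -> np.ndarray:
        """Vectorized start-coordinate lookup."""
        tile_ids = np.asarray(tile_ids, dtype=np.int64)
        out = np.empty(len(tile_ids), dtype=np.int64)
        for c in self._chroms:
            off = self._offsets[c]
            n = self._n_tiles[c]
            m = (tile_ids >= off) & (tile_ids < off + n)
            out[m] = (tile_ids[m] - off) * self.tile_width
        return out

    def gene_distances(self, tile_ids: np.ndarray, chrom: str,
                       gene_start: int, gene_end: int) -> np.ndarray:
        """Distance (bp) from each tile to a gene interval on `chrom`.

        Tiles on other chromosomes get distance +inf (trans).
        """
        tile_ids = np.asarray(tile_ids, dtype=np.int64)
        out = np.full(len(tile_ids), np.inf)
        off = self._offsets[chrom]
        n = self._n_tiles[chrom]
        m = (tile_ids >= off) & (tile_ids < off + n)
        starts = (tile_ids[m] - off) * self.tile_width
        ends = starts + self.tile_width
        d = np.maximum(gene_start - ends, 0) + np.maximum(starts - gene_end, 0)
        d[(starts < gene_end) & (ends > gene_start)] = 0
        out[m] = d
        return out


def tile_genome(chrom_sizes: dict[str, int], tile_width: int = 1000) -> TiledGenome:
    """Segment a genome into non-overlapping fixed-width tiles.

    Each chromosome yields floor(size / tile_width) tiles at
    [i*w, (i+1)*w); any trailing partial tile is dropped.
    """
    return TiledGenome(dict(chrom_sizes), tile_width)
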