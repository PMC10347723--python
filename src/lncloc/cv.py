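"""Cross-validation partitions that respect genomic neighborhoods.

Genomic signals are spatially autocorrelated, so random CV lets information
leak between train and test via neighboring tiles and returns optimistic
performance estimates.  Block CV groups each positive with its genomic
neighbors (and each negative with its anchor positive) into blocks that
travel together between folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .genome import TiledGenome

__all__ = ["CVPartition", "make_blocks", "assign_folds"]


@dataclass
class CVPartition:
    K: int
    mode: str                       # "random" | "block"
    fold_of: dict[int, int]         # tile id -> fold
    block_of: dict[int, int] | None = None

    def test_ids(self, k: int) -> np.ndarray:
        return np.array(sorted(t for t, f in self.fold_of.items() if f == k))

    def train_ids(self, k: int) -> np.ndarray:
        return np.array(sorted(t for t, f in self.fold_of.items() if f != k))

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, f, self.block_of.get(t, -1) if self.block_of else -1)
                for t, f in sorted(self.fold_of.items())]
        return pd.DataFrame(rows, columns=["tile_id", "fold", "block_id"])


def make_blocks(dataset: LabeledDataset, tiling: TiledGenome,
                neighbors_per_seed: int = 49, seed: int = 0) -> dict[int, int]:
    """Group examples into genomic blocks.

    Positives are visited in a seeded shuffle order; each unassigned
    positive seeds a block and claims its ``neighbors_per_seed`` nearest
    unassigned positives (genomic distance, same chromosome; ties -> lower
    tile id).  Every negative joins its anchor positive's block.
    """
    if neighbors_per_seed < 0:
        raise ValueError("neighbors_per_seed must be >= 0")
    rng = np.random.default_rng(seed)
    positives = np.asarray(dataset.positives, dtype=np.int64)
    order = positives[rng.permutation(len(positives))]
    chroms = dict(zip(positives.tolist(), tiling.chrom_of(positives).tolist()))
    starts = dict(zip(positives.tolist(), tiling.starts_of(positives).tolist()))
    unassigned = set(positives.tolist())
    block_of: dict[int, int] = {}
    block_id = 0
    for p in order.tolist():
        if p not in unassigned:
            continue
        unassigned.discard(p)
        block_of[p] = block_id
        if neighbors_per_seed and unassigned:
            same = [q for q in unassigned if chroms[q] == chroms[p]]
            same.sort(key=lambda q: (abs(starts[q] - starts[p]), q))
            for q in same[:neighbors_per_seed]:
                unassigned.discard(q)
                block_of[q] = block_id
        block_id += 1
    for t in dataset.negatives.tolist():
        block_of[int(t)] = block_of[dataset.anchor[int(t)]]
    return block_of


def assign_folds(dataset: LabeledDataset, K: int = 5, mode: str = "block",
                 block_of: dict[int, int] | None = None, seed: int = 0) -> CVPartition:
    """Deal examples (random mode) or whole blocks (block mode) into K folds.

    Block mode shuffles blocks with the seed, then assigns largest-first to
    the fold with the fewest positives so far (greedy balancing; ties ->
    lowest fold index).  Random mode is stratified by label: within each
    label, a seeded shuffle is dealt round-robin, keeping the label ratio
    per fold within one example.
    """
    rng = np.random.default_rng(seed)
    fold_of: dict[int, int] = {}
    if mode == "random":
        labels = dataset.labels
        ids = dataset.tile_ids
        for lab in (1, 0):
            sel = ids[labels == lab]
            sel = sel[rng.permutation(len(sel))]
            for i, t in enumerate(sel.tolist()):
                fold_of[int(t)] = i % K
        return CVPartition(K, "random", fold_of)
    if mode != "block":
        raise ValueError(f"unknown mode {mode!r}")
    if block_of is None:
        raise ValueError("block mode needs a block assignment")
    pos_set = set(dataset.positives.tolist())
    blocks: dict[int, list[int]] = {}
    for t, b in block_of.items():
        blocks.setdefault(b, []).append(t)
    if K > len(blocks):
        raise ValueError(f"K={K} exceeds the number of blocks ({len(blocks)})")
    block_ids = sorted(blocks)
    shuffled = [block_ids[i] for i in rng.permutation(len(block_ids))]
    sizes = {b: sum(1 for t in blocks[b] if t in pos_set) for b in block_ids}
    shuffled.sort(key=lambda b: -sizes[b])  # stable: ties keep shuffle order
    fold_pos = np.zeros(K, dtype=int)
    for b in shuffled:
        k = int(np.argmin(fold_pos))
        fold_pos[k] += sizes[b]
        for t in blocks[b]:
            fold_of[int(t)] = k
    return CVPartition(K, "block", fold_of, block_of=dict(block_of))
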