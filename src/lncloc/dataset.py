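"""Labeled per-lncRNA datasets with distance-matched negative sampling.

Positives are the lncRNA's bound tiles.  Negatives are unbound cis tiles,
chosen so that genomic distance to the lncRNA gene cannot separate the
classes: every unbound tile is anchored to its nearest positive, at most
``cap`` candidates are kept per anchor (the nearest ones), and the final
negative set is drawn without replacement with importance weights that
reshape the candidates' distance distribution onto the positives'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import TiledGenome
from .interactome import LncRNA

__all__ = ["LabeledDataset", "build_candidate_negatives", "sample_negatives",
           "build_dataset", "qq_distance_report"]


@dataclass
class LabeledDataset:
    lncrna: str
    positives: np.ndarray          # tile ids
    negatives: np.ndarray          # tile ids (sampled)
    anchor: dict[int, int]         # negative id -> nearest positive id
    distance: dict[int, float]     # tile id -> bp to lncRNA gene
    ratio: float

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives overlap")

    @property
    def tile_ids(self) -> np.ndarray:
        return np.concatenate([self.positives, self.negatives])

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.positives), dtype=int),
                               np.zeros(len(self.negatives), dtype=int)])

    def to_frame(self) -> pd.DataFrame:
        rows = [(int(t), 1, -1, self.distance[int(t)]) for t in self.positives] + \
               [(int(t), 0, self.anchor[int(t)], self.distance[int(t)]) for t in self.negatives]
        return pd.DataFrame(rows, columns=["tile_id", "label", "anchor_id", "distance_bp"])


def build_candidate_negatives(positives: np.ndarray, tiling: TiledGenome,
                              cap: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Candidate negatives with nearest-positive anchors, capped per anchor.

    Every non-positive tile on the chromosomes carrying positives is
    assigned to its nearest positive (ties -> lower positive tile id); for
    anchors with more than ``cap`` candidates only the ``cap`` nearest are
    retained (ties -> lower candidate id).  Returns (candidate_ids,
    anchor_ids), candidate-sorted.
    """
    positives = np.unique(np.asarray(positives, dtype=np.int64))
    if len(positives) == 0:
        raise ValueError("need at least one positive")
    chroms = sorted(set(tiling.chrom_of(positives).tolist()))
    cand_list, anchor_list = [], []
    pos_set = set(positives.tolist())
    for chrom in chroms:
        tiles = tiling.chrom_tile_ids(chrom)
        pos_c = positives[(positives >= tiles[0]) & (positives <= tiles[-1])]
        cand = tiles[~np.isin(tiles, pos_c)]
        if len(cand) == 0 or len(pos_c) == 0:
            continue
        # nearest positive by tile index; tie -> lower positive id
        j = np.searchsorted(pos_c, cand)
        left = np.clip(j - 1, 0, len(pos_c) - 1)
        right = np.clip(j, 0, len(pos_c) - 1)
        dl = np.abs(cand - pos_c[left])
        dr = np.abs(cand - pos_c[right])
        anchor = np.where(dl <= dr, pos_c[left], pos_c[right])
        cand_list.append(cand)
        anchor_list.append(anchor)
    if not cand_list:
        raise ValueError("no candidate negatives available")
    cand = np.concatenate(cand_list)
    anchor = np.concatenate(anchor_list)
    # cap per anchor, keeping the nearest candidates (ties -> lower id)
    keep = np.zeros(len(cand), dtype=bool)
    order = np.lexsort((cand, np.abs(cand - anchor), anchor))
    seen: dict[int, int] = {}
    for idx in order:
        a = anchor[idx]
        c = seen.get(a, 0)
        if c < cap:
            keep[idx] = True
            seen[a] = c + 1
    return cand[keep], anchor[keep]


def _log_bins(tile_width: int, max_distance: float, n_bins: int = 50) -> np.ndarray:
    hi = max(max_distance, tile_width * 2)
    return np.logspace(np.log10(tile_width), np.log10(hi + 1), n_bins + 1)


def sample_negatives(candidates: np.ndarray, cand_distances: np.ndarray,
                     pos_distances: np.ndarray, n_positives: int,
                     ratio: float = 5.0, seed: int = 0,
                     tile_width: int = 1000, n_bins: int = 50) -> np.ndarray:
    """Distance-matched sampling of negatives without replacement.

    The positives' distance distribution is histogrammed over log-spaced
    bins and converted into per-bin sampling quotas for the candidates
    (largest-remainder rounding); quotas exceeding a bin's candidate supply
    are redistributed to bins that still have capacity, in proportion to
    the positives' mass there.  Within a bin candidates are drawn uniformly
    without replacement (seeded), so the draw is deterministic.  If no
    candidate shares a bin with any positive, falls back to uniform
    sampling with a warning.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    candidates = np.asarray(candidates, dtype=np.int64)
    cand_d = np.clip(np.asarray(cand_distances, dtype=float), tile_width, None)
    pos_d = np.clip(np.asarray(pos_distances, dtype=float), tile_width, None)
    k = int(round(ratio * n_positives))
    if len(candidates) <= k:
        return np.sort(candidates)
    bins = _log_bins(tile_width, max(pos_d.max(), cand_d.max()), n_bins)
    pos_mass = np.histogram(pos_d, bins=bins)[0].astype(float)
    bin_of = np.clip(np.digitize(cand_d, bins) - 1, 0, n_bins - 1)
    supply = np.bincount(bin_of, minlength=n_bins)
    usable = (supply > 0) & (pos_mass > 0)
    if not usable.any():
        warnings.warn("no distance overlap between candidates and positives; "
                      "falling back to uniform sampling")
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(candidates), size=k, replace=False)
        return np.sort(candidates[chosen])
    # per-bin quotas proportional to positive mass, capped by supply, with
    # overflow redistributed to bins that still have capacity
    quota = np.zeros(n_bins, dtype=np.int64)
    weight = np.where(usable, pos_mass, 0.0)
    remaining = k
    for _ in range(n_bins):
        if remaining <= 0 or weight.sum() == 0:
            break
        target = weight / weight.sum() * remaining
        add = np.minimum(np.floor(target).astype(np.int64), supply - quota)
        # largest-remainder top-up for the leftover units
        leftover = remaining - int(add.sum())
        frac_order = np.argsort(-(target - np.floor(target)), kind="stable")
        for b in frac_order:
            if leftover <= 0:
                break
            if quota[b] + add[b] < supply[b]:
                add[b] += 1
                leftover -= 1
        quota += add
        remaining = k - int(quota.sum())
        weight = np.where(quota < supply, np.where(usable, pos_mass, 0.0), 0.0)
    if remaining > 0:
        # positive-mass bins exhausted: spill uniformly into leftover supply
        weight = (supply - quota).astype(float)
        extra = np.minimum(np.ceil(weight / weight.sum() * remaining).astype(np.int64),
                           supply - quota)
        for b in np.argsort(-extra, kind="stable"):
            take = min(int(extra[b]), remaining)
            quota[b] += take
            remaining -= take
            if remaining == 0:
                break
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for b in range(n_bins):
        if quota[b] == 0:
            continue
        members = np.nonzero(bin_of == b)[0]
        take = rng.choice(members, size=int(quota[b]), replace=False)
        chosen.append(take)
    return np.sort(candidates[np.concatenate(chosen)])


def build_dataset(lncrna: LncRNA, positives: np.ndarray, tiling: TiledGenome,
                  ratio: float = 5.0, cap: int = 100, seed: int = 0) -> LabeledDataset:
    """Full labeled-dataset construction for one lncRNA."""
    positives = np.unique(np.asarray(positives, dtype=np.int64))
    cand, anchor = build_candidate_negatives(positives, tiling, cap=cap)

    def dists(ids: np.ndarray) -> np.ndarray:
        chroms = tiling.chrom_of(ids)
        out = np.empty(len(ids))
        for chrom in set(chroms.tolist()):
            m = chroms == chrom
            if chrom == lncrna.chrom:
                out[m] = tiling.gene_distances(ids[m], chrom,
                                               lncrna.gene_start, lncrna.gene_end)
            else:
                out[m] = np.inf
        return out

    pos_d = dists(positives)
    cand_d = dists(cand)
    finite = np.isfinite(cand_d)
    neg = sample_negatives(cand[finite], cand_d[finite], pos_d[np.isfinite(pos_d)],
                           len(positives), ratio=ratio, seed=seed,
                           tile_width=tiling.tile_width)
    anchor_of = dict(zip(cand.tolist(), anchor.tolist()))
    distance = {int(t): float(d) for t, d in zip(positives, pos_d)}
    distance.update({int(t): float(d) for t, d in zip(cand, cand_d)})
    return LabeledDataset(lncrna.name, positives, neg,
                          {int(t): anchor_of[int(t)] for t in neg},
                          distance, ratio)


def qq_distance_report(dataset: LabeledDataset, candidates: np.ndarray | None = None,
                       quantiles: np.ndarray | None = None) -> pd.DataFrame:
    """Matched quantiles (1..99 %) of positive vs negative gene distances.

    With a candidate set supplied, also reports the unmatched (all
    candidates) quantiles for comparison.
    """
    if len(dataset.negatives) == 0:
        raise ValueError("dataset has no negatives")
    q = quantiles if quantiles is not None else np.arange(1, 100) / 100.0
    pos_d = np.array([dataset.distance[int(t)] for t in dataset.positives])
    neg_d = np.array([dataset.distance[int(t)] for t in dataset.negatives])
    out = pd.DataFrame({"quantile": q,
                        "positive": np.quantile(pos_d, q),
                        "negative_sampled": np.quantile(neg_d, q)})
    if candidates is not None and len(candidates):
        cand_d = np.array([dataset.distance[int(t)] for t in candidates
                           if int(t) in dataset.distance])
        out["negative_all_candidates"] = np.quantile(cand_d, q)
    return out
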