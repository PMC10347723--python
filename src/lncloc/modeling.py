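"""Random-forest model ensembles over feature-family subsets.

For each lncRNA a forest is trained for every admissible combination of
feature families: all 2^n - 1 non-empty subsets of the primary (sequence)
families in raw representation, and all 2^n subsets of the secondary
(context) families, each on top of a principal-component block summarizing
the full sequence category.  Per-fold test AUROC (midrank Mann-Whitney),
AUPR and Gini importances feed the downstream family-importance analysis.

Forest hyperparameters follow the reference setup: probability forests with
minimum terminal-node size 10, depth limit 10, mtry = floor(sqrt(p)), and
minority-class upsampling to 1:1 in each training split.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score

from .cv import CVPartition
from .dataset import LabeledDataset
from .schema import FamilySchema, FeatureTable, PRIMARY, SECONDARY

__all__ = ["ModelSpec", "ModelResult", "enumerate_model_specs", "sequence_pca",
           "auroc_midrank", "train_and_eval", "derive_seed"]

RAW = "raw"
SEQUENCE_PC = "sequence_pc"


def derive_seed(seed: int, *parts) -> int:
    """Deterministic child seed below 2**31 from a base seed and labels."""
    tag = "|".join(str(p) for p in parts)
    return (int(seed) * 2654435761 + zlib.crc32(tag.encode())) % (2 ** 31)


@dataclass(frozen=True)
class ModelSpec:
    lncrna: str
    family_subset: tuple[str, ...]       # raw: primary subset; sequence_pc: secondary subset
    representation: str = RAW
    trees: int = 1000
    max_depth: int = 10
    min_leaf: int = 10
    n_pc: int = 100
    upsample: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.representation == RAW and not self.family_subset:
            raise ValueError("sequence-only models need a non-empty family subset")
        object.__setattr__(self, "family_subset", tuple(sorted(self.family_subset)))

    @property
    def key(self) -> str:
        rep = "seq" if self.representation == RAW else "ctx"
        return f"{self.lncrna}:{rep}:{'+'.join(self.family_subset) or '(pc-only)'}"


@dataclass
class ModelResult:
    spec: ModelSpec
    fold_auroc: list[float]               # NaN for undefined folds
    fold_aupr: list[float]
    fold_importances: list[pd.Series]     # Gini importance per (fold) forest

    @property
    def mean_auroc(self) -> float:
        return float(np.nanmean(self.fold_auroc))

    def fold_ranks(self, k: int) -> pd.Series:
        """Within-model importance ranks (1 = largest Gini, ties -> average)."""
        imp = self.fold_importances[k]
        from scipy.stats import rankdata
        return pd.Series(rankdata(-imp.to_numpy(), method="average"), index=imp.index)


def enumerate_model_specs(schema: FamilySchema, lncrna: str, **spec_kwargs) -> list[ModelSpec]:
    """All model specs for one lncRNA.

    Sequence-only set: the 2^n - 1 non-empty subsets of primary families,
    raw representation.  Sequence + context set: all 2^n subsets of
    secondary families (including the empty, PC-only model), each carrying
    the sequence-PC block.
    """
    primary = schema.family_names(PRIMARY)
    secondary = schema.family_names(SECONDARY)
    specs: list[ModelSpec] = []
    for subset in _subsets(primary, include_empty=False):
        specs.append(ModelSpec(lncrna, subset, RAW, **spec_kwargs))
    for subset in _subsets(secondary, include_empty=True):
        specs.append(ModelSpec(lncrna, subset, SEQUENCE_PC, **spec_kwargs))
    return specs


def _subsets(items: list[str], include_empty: bool) -> list[tuple[str, ...]]:
    out = []
    for mask in range(0 if include_empty else 1, 2 ** len(items)):
        out.append(tuple(items[i] for i in range(len(items)) if mask >> i & 1))
    return out


def sequence_pca(primary_matrix: pd.DataFrame, n_pc: int = 100,
                 fit_rows: np.ndarray | None = None) -> pd.DataFrame:
    """Principal-component block of the (standardized) sequence features.

    ``fit_rows`` selects the rows used to fit the rotation (the training
    fold by default, to keep the test fold out of the fit); the rotation is
    then applied to all rows.  Constant columns are dropped; if the data
    rank is below ``n_pc`` the block shrinks to the rank with a warning.
    """
    X = primary_matrix.to_numpy(dtype=float)
    fit = X if fit_rows is None else X[fit_rows]
    mu = fit.mean(axis=0)
    sd = fit.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    fit_s = Xs if fit_rows is None else Xs[fit_rows]
    max_pc = min(fit_s.shape[0], fit_s.shape[1])
    k = min(n_pc, max_pc)
    pca = PCA(n_components=k, svd_solver="randomized" if k < max_pc else "auto",
              random_state=0)
    pca.fit(fit_s)
    # numerical rank: drop components that carry no variance
    keep_pc = pca.explained_variance_ > 1e-9 * max(pca.explained_variance_[0], 1e-12)
    if keep_pc.sum() < n_pc:
        warnings.warn(f"rank caps sequence PCs at {int(keep_pc.sum())} (< {n_pc})")
    pcs = pca.transform(Xs)[:, keep_pc]
    return pd.DataFrame(pcs, index=primary_matrix.index,
                        columns=[f"seq_pc_{i + 1:03d}" for i in range(pcs.shape[1])])


def auroc_midrank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the midrank Mann-Whitney statistic (ties get 0.5 credit)."""
    from scipy.stats import rankdata
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    r = rankdata(scores, method="average")
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _design_matrix(spec: ModelSpec, features: FeatureTable, tile_ids: np.ndarray,
                   train_rows: np.ndarray, fold: int | None = None,
                   pc_cache: dict | None = None) -> pd.DataFrame:
    if spec.representation == RAW:
        return features.matrix(spec.family_subset, tile_ids)
    key = (fold, spec.n_pc)
    if pc_cache is not None and key in pc_cache:
        pcs = pc_cache[key]
    else:
        primary = features.matrix(features.schema.family_names(PRIMARY), tile_ids)
        pcs = sequence_pca(primary, n_pc=spec.n_pc, fit_rows=train_rows)
        if pc_cache is not None:
            pc_cache[key] = pcs
    if spec.family_subset:
        ctx = features.matrix(spec.family_subset, tile_ids)
        return pd.concat([pcs, ctx], axis=1)
    return pcs


def train_and_eval(spec: ModelSpec, dataset: LabeledDataset, partition: CVPartition,
                   features: FeatureTable, pc_cache: dict | None = None) -> ModelResult:
    """Fit and evaluate one model spec across all CV folds.

    ``pc_cache`` (optional) shares the per-fold sequence-PC rotation across
    the specs of one ensemble — the rotation depends only on the fold and
    ``n_pc``, not on the context-family subset.
    """
    tile_ids = dataset.tile_ids
    labels = dataset.labels
    fold = np.array([partition.fold_of[int(t)] for t in tile_ids])
    fold_auroc: list[float] = []
    fold_aupr: list[float] = []
    fold_imp: list[pd.Series] = []
    for k in range(partition.K):
        test = fold == k
        train = ~test
        X = _design_matrix(spec, features, tile_ids, np.nonzero(train)[0],
                           fold=k, pc_cache=pc_cache)
        Xtr, ytr = X.to_numpy(dtype=float)[train], labels[train]
        # seeds depend on (base seed, fold) but not the family subset:
        # paired models across the ensemble share bootstrap randomness
        # (common random numbers), which sharpens MPV's paired differences
        if spec.upsample:
            Xtr, ytr = _upsample(Xtr, ytr, derive_seed(spec.seed, "up", k))
        clf = RandomForestClassifier(
            n_estimators=spec.trees, max_depth=spec.max_depth,
            min_samples_leaf=spec.min_leaf, max_features="sqrt",
            random_state=derive_seed(spec.seed, "rf", k), n_jobs=1)
        clf.fit(Xtr, ytr)
        fold_imp.append(pd.Series(clf.feature_importances_, index=X.columns))
        ytest = labels[test]
        if len(np.unique(ytest)) < 2:
            warnings.warn(f"fold {k} has a single-class test split; AUROC undefined")
            fold_auroc.append(float("nan"))
            fold_aupr.append(float("nan"))
            continue
        prob = clf.predict_proba(X.to_numpy(dtype=float)[test])[:, list(clf.classes_).index(1)]
        fold_auroc.append(auroc_midrank(prob, ytest))
        fold_aupr.append(float(average_precision_score(ytest, prob)))
    return ModelResult(spec, fold_auroc, fold_aupr, fold_imp)


def _upsample(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Upsample the minority class with replacement to a 1:1 balance."""
    rng = np.random.default_rng(seed)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == n0 or n1 == 0 or n0 == 0:
        return X, y
    minority = 1 if n1 < n0 else 0
    need = abs(n0 - n1)
    idx = np.nonzero(y == minority)[0]
    extra = rng.choice(idx, size=need, replace=True)
    sel = np.concatenate([np.arange(len(y)), extra])
    return X[sel], y[sel]
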