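import numpy as np
import pandas as pd
import pytest

from lncloc.cv import assign_folds
from lncloc.dataset import LabeledDataset
from lncloc.kmers import canonical_kmers
from lncloc.modeling import (ModelSpec, RAW, SEQUENCE_PC, auroc_midrank,
                             enumerate_model_specs, sequence_pca, train_and_eval)
from lncloc.schema import Family, FamilySchema, FeatureTable, canonical_schema
from lncloc.features import synthetic_schema


def pair_count_auroc(scores, labels):
    """Exhaustive oracle: fraction of (pos, neg) pairs ranked correctly,
    ties worth half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEnumeration:
    def test_reference_schema_yields_31_plus_32_specs(self):
        specs = enumerate_model_specs(canonical_schema(), "lncX")
        seq_only = [s for s in specs if s.representation == RAW]
        seq_ctx = [s for s in specs if s.representation == SEQUENCE_PC]
        assert len(seq_only) == 31
        assert len(seq_ctx) == 32
        assert any(s.family_subset == () for s in seq_ctx)  # PC-only model
        assert len({s.key for s in specs}) == 63

    def test_reduced_two_primary_schema_yields_three_sequence_specs(self):
        schema = FamilySchema((Family("a", "primary", ("x",)),
                               Family("b", "primary", ("y",))))
        specs = enumerate_model_specs(schema, "l")
        assert len([s for s in specs if s.representation == RAW]) == 3

    def test_empty_sequence_subset_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("l", (), RAW)


class TestSequencePCA:
    def test_rank_cap_with_warning(self, rng):
        base = rng.normal(size=(40, 3))
        X = pd.DataFrame(base @ rng.normal(size=(3, 20)))  # rank 3
        with pytest.warns(UserWarning, match="rank caps"):
            pcs = sequence_pca(X, n_pc=10)
        assert pcs.shape[1] <= 4  # numerical rank ~3

    def test_component_variances_nonincreasing(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 30)))
        pcs = sequence_pca(X, n_pc=10)
        v = pcs.var(axis=0).to_numpy()
        assert (np.diff(v) <= 1e-9).all()

    def test_full_rank_projection_preserves_distances(self, rng):
        # with all PCs kept, the rotation is orthogonal on the standardized
        # data: pairwise distances are preserved (reconstruction error ~ 0)
        X = pd.DataFrame(rng.normal(size=(30, 8)))
        pcs = sequence_pca(X, n_pc=8).to_numpy()
        Xs = (X - X.mean()) / X.std(ddof=0)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(pcs), pdist(Xs.to_numpy()), rtol=1e-8)

    def test_rotation_fitted_on_training_rows_only(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 6)))
        fit_rows = np.arange(30)
        pcs = sequence_pca(X, n_pc=3, fit_rows=fit_rows)
        # training-row block must match a PCA fitted on those rows alone
        pcs_train_only = sequence_pca(X.iloc[:30], n_pc=3)
        np.testing.assert_allclose(np.abs(pcs.iloc[:30].to_numpy()),
                                   np.abs(pcs_train_only.to_numpy()), atol=1e-6)


class TestAUROC:
    def test_matches_pair_counting_oracle_exactly(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 200))
            scores = rng.integers(0, 10, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert auroc_midrank(scores, labels) == pytest.approx(
                pair_count_auroc(scores, labels), abs=1e-12)

    def test_single_class_undefined(self):
        assert np.isnan(auroc_midrank(np.array([1.0, 2.0]), np.array([1, 1])))


def _toy_problem(rng, n=400, separable=False):
    schema = FamilySchema((Family("f", "primary", ("x1", "x2")),))
    ids = np.arange(n)
    labels = np.concatenate([np.ones(n // 4, dtype=int),
                             np.zeros(n - n // 4, dtype=int)])
    X = rng.normal(size=(n, 2))
    if separable:
        X[:, 0] = labels * 10.0 + rng.normal(scale=0.01, size=n)
    pos = ids[labels == 1]
    neg = ids[labels == 0]
    ds = LabeledDataset("l", pos, neg, {int(t): int(pos[0]) for t in neg},
                        {int(t): 1000.0 for t in ids}, 3.0)
    ft = FeatureTable(pd.DataFrame(X, index=ids, columns=["x1", "x2"]), schema)
    part = assign_folds(ds, K=5, mode="random", seed=0)
    return ds, ft, part


class TestTrainAndEval:
    def test_null_features_score_near_half(self, rng):
        ds, ft, part = _toy_problem(rng, n=2000)
        spec = ModelSpec("l", ("f",), RAW, trees=100, seed=0)
        res = train_and_eval(spec, ds, part, ft)
        assert abs(res.mean_auroc - 0.5) < 0.05

    def test_separating_feature_scores_one(self, rng):
        ds, ft, part = _toy_problem(rng, n=300, separable=True)
        spec = ModelSpec("l", ("f",), RAW, trees=50, seed=0)
        res = train_and_eval(spec, ds, part, ft)
        assert all(a == pytest.approx(1.0) for a in res.fold_auroc)
        assert all(a == pytest.approx(1.0) for a in res.fold_aupr)

    def test_deterministic_under_seed(self, rng):
        ds, ft, part = _toy_problem(rng, n=200)
        spec = ModelSpec("l", ("f",), RAW, trees=30, seed=5)
        r1 = train_and_eval(spec, ds, part, ft)
        r2 = train_and_eval(spec, ds, part, ft)
        assert r1.fold_auroc == r2.fold_auroc
        for a, b in zip(r1.fold_importances, r2.fold_importances):
            pd.testing.assert_series_equal(a, b)

    def test_importance_ranks_are_average_tie_ranks(self, rng):
        ds, ft, part = _toy_problem(rng, n=200, separable=True)
        spec = ModelSpec("l", ("f",), RAW, trees=30, seed=1)
        res = train_and_eval(spec, ds, part, ft)
        ranks = res.fold_ranks(0)
        assert sorted(ranks.tolist()) in ([1.0, 2.0], [1.5, 1.5])
        assert ranks["x1"] == 1.0  # the separating feature leads
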