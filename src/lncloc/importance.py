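"""Family-level importance: MPV, MxPV, complementarity, rank aggregation.

The Marginal Predictive Value (MPV) of feature family A_i is the mean, over
all 2^(n-1) family subsets U containing A_i, of the fold-averaged test-AUROC
difference between the model trained on U and the model trained on
U \\ {A_i}.  MxPV replaces the mean over subsets with the maximum.  Primary
families are scored over the sequence-only model set, where removing the
last family leaves the empty model, scored as a random classifier
(M_k(empty) = 0.5); secondary families are scored over the
sequence + context set, where the empty-context model is the PC-only model.

The complementarity score of a family pair is the mean AUROC of the
pair-trained model minus the better of the two single-family models; it
surfaces families that are informative only jointly (e.g. XOR-like
structure), which MPV by design underweights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .modeling import ModelResult, ModelSpec, RAW, SEQUENCE_PC
from .schema import FamilySchema, PRIMARY, SECONDARY

__all__ = ["ResultSet", "mpv", "mxpv", "mpv_table", "complementarity",
           "aggregate_feature_ranks", "classify_ta"]

EMPTY_MODEL_AUROC = 0.5


class ResultSet:
    """Indexed collection of ModelResults for one lncRNA."""

    def __init__(self, results: list[ModelResult]):
        self.results = results
        self._index: dict[tuple[str, tuple[str, ...]], ModelResult] = {}
        for r in results:
            self._index[(r.spec.representation, r.spec.family_subset)] = r

    def get(self, representation: str, subset: tuple[str, ...]) -> ModelResult:
        key = (representation, tuple(sorted(subset)))
        if key not in self._index:
            raise KeyError(f"model {key} missing; ensemble incomplete")
        return self._index[key]

    def fold_aurocs(self, representation: str, subset: tuple[str, ...],
                    K: int) -> np.ndarray:
        """Per-fold AUROCs; the empty sequence-only model scores 0.5."""
        if representation == RAW and not subset:
            return np.full(K, EMPTY_MODEL_AUROC)
        return np.asarray(self.get(representation, subset).fold_auroc, dtype=float)


def _category_context(schema: FamilySchema, family: str) -> tuple[str, list[str]]:
    if family in schema.family_names(PRIMARY):
        return RAW, schema.family_names(PRIMARY)
    if family in schema.family_names(SECONDARY):
        return SEQUENCE_PC, schema.family_names(SECONDARY)
    raise KeyError(family)


def _pair_differences(results: ResultSet, schema: FamilySchema, family: str,
                      K: int) -> np.ndarray:
    """Fold-averaged AUROC differences for every (U, U - A_i) pair."""
    rep, families = _category_context(schema, family)
    others = [f for f in families if f != family]
    diffs = []
    for mask in range(2 ** len(others)):
        base = tuple(others[i] for i in range(len(others)) if mask >> i & 1)
        with_i = tuple(sorted(base + (family,)))
        m_with = results.fold_aurocs(rep, with_i, K)
        m_without = results.fold_aurocs(rep, base, K)
        valid = ~(np.isnan(m_with) | np.isnan(m_without))
        diffs.append(float(np.mean(m_with[valid] - m_without[valid])))
    return np.asarray(diffs)


def mpv(results: ResultSet, schema: FamilySchema, family: str, K: int = 5) -> float:
    """Marginal Predictive Value of a feature family."""
    return float(np.mean(_pair_differences(results, schema, family, K)))


def mxpv(results: ResultSet, schema: FamilySchema, family: str, K: int = 5) -> float:
    """Maximal Predictive Value: max (not mean) fold-averaged gain."""
    return float(np.max(_pair_differences(results, schema, family, K)))


def mpv_table(results_by_lncrna: dict[str, ResultSet], schema: FamilySchema,
              K: int = 5, statistic: str = "mpv") -> pd.DataFrame:
    """lncRNA x family matrix of MPV (or MxPV) values."""
    fn = mpv if statistic == "mpv" else mxpv
    fams = schema.family_names()
    rows = {lnc: {f: fn(res, schema, f, K) for f in fams}
            for lnc, res in results_by_lncrna.items()}
    return pd.DataFrame(rows).T[fams]


def complementarity(results: ResultSet, family_a: str, family_b: str) -> float:
    """Pair AUROC minus the better single-family AUROC.

    Expects the dedicated single-family and pair models (raw representation,
    families usable across categories) to be present in the result set.
    """
    pair = results.get(RAW, (family_a, family_b)).mean_auroc
    a = results.get(RAW, (family_a,)).mean_auroc
    b = results.get(RAW, (family_b,)).mean_auroc
    return float(pair - max(a, b))


def aggregate_feature_ranks(results: list[ModelResult], percentile: float = 20,
                            category: str | None = None,
                            schema: FamilySchema | None = None) -> pd.DataFrame:
    """Median within-model importance rank per feature over top models.

    Each (spec, fold) forest is one model, scored by its test AUROC; the top
    ``percentile`` % of models are kept and, within each, features are
    ranked by descending Gini importance (ties -> average rank).  Sequence
    feature ranks should be aggregated over sequence-only models and context
    ranks over sequence + context models (pass ``category``).  Features
    absent from every selected model get a missing median.
    """
    if category == PRIMARY:
        results = [r for r in results if r.spec.representation == RAW]
    elif category == SECONDARY:
        results = [r for r in results if r.spec.representation == SEQUENCE_PC]
    models = [(r, k) for r in results for k in range(len(r.fold_auroc))
              if not np.isnan(r.fold_auroc[k])]
    if not models:
        raise ValueError("no models available for rank aggregation")
    aurocs = np.array([r.fold_auroc[k] for r, k in models])
    cutoff = np.quantile(aurocs, 1 - percentile / 100.0)
    selected = [(r, k) for (r, k), a in zip(models, aurocs) if a >= cutoff]
    if not selected:
        raise ValueError("percentile selected zero models")
    ranks: dict[str, list[float]] = {}
    for r, k in selected:
        rk = r.fold_ranks(k)
        for feat, val in rk.items():
            ranks.setdefault(feat, []).append(float(val))
    rows = [(feat, float(np.median(v)), len(v)) for feat, v in sorted(ranks.items())]
    df = pd.DataFrame(rows, columns=["feature", "median_rank", "n_models"])
    if schema is not None:
        df["family"] = [_family_or_none(schema, f) for f in df["feature"]]
    return df.set_index("feature")


def _family_or_none(schema: FamilySchema, feature: str):
    try:
        return schema.family_of(feature)
    except KeyError:
        return None  # e.g. sequence-PC columns


def classify_ta(mpv_frame: pd.DataFrame, family: str = "transcription",
                threshold: float = 0.01,
                test_family: str | None = None) -> tuple[pd.Series, float | None]:
    """Transcription-associated (TA) calls plus an optional group test.

    A lncRNA is TA iff its MPV for the transcription family is >= threshold
    (inclusive).  With ``test_family`` given, a one-sided Mann-Whitney test
    compares that family's MPVs between non-TA and TA groups (alternative:
    larger in non-TA, the direction seen for triplex potential).
    """
    ta = mpv_frame[family] >= threshold
    pval = None
    if test_family is not None:
        a = mpv_frame.loc[~ta, test_family].to_numpy()
        b = mpv_frame.loc[ta, test_family].to_numpy()
        if len(a) and len(b):
            from scipy.stats import mannwhitneyu
            method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
            pval = float(mannwhitneyu(a, b, alternative="greater", method=method).pvalue)
    return ta, pval
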