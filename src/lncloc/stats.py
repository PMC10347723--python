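"""Bound-vs-unbound enrichment statistics and k-mer density correlations.

The workhorse is the signed two-sample Kolmogorov-Smirnov statistic: the
classical KS D carrying the sign of the ECDF difference at its maximizing
point, so the direction of enrichment is retained.  The convention here is
positive = enriched (stochastically larger) in the bound sample; it can be
flipped with ``sign_convention=-1``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .kmers import canonical, canonical_kmers

__all__ = ["signed_ks", "enrichment_battery", "kmer_density_correlation",
           "seed_to_kmers", "seed_enrichment_matrix"]


def signed_ks(bound: np.ndarray, unbound: np.ndarray,
              sign_convention: int = 1) -> tuple[float, float]:
    """Signed two-sample KS statistic and two-sided asymptotic p-value.

    D_signed = Delta(x*) with Delta(x) = F_unbound(x) - F_bound(x) and
    x* = argmax |Delta| over the pooled support (ties -> smallest x), so a
    positive value means the bound sample is stochastically larger.
    |D_signed| equals the classical two-sample KS D of the same samples.
    """
    bound = np.sort(np.asarray(bound, dtype=float))
    unbound = np.sort(np.asarray(unbound, dtype=float))
    n, m = len(bound), len(unbound)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    xs = np.unique(np.concatenate([bound, unbound]))
    f_b = np.searchsorted(bound, xs, side="right") / n
    f_u = np.searchsorted(unbound, xs, side="right") / m
    delta = f_u - f_b
    i = int(np.argmax(np.abs(delta)))  # first maximizer = smallest x
    d_signed = float(delta[i]) * sign_convention
    en = np.sqrt(n * m / (n + m))
    p = float(kolmogorov(en * abs(d_signed)))
    return d_signed, min(p, 1.0)


def enrichment_battery(value_sets: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
                       alpha: float = 0.05, sign_convention: int = 1) -> pd.DataFrame:
    """Signed-KS tests over a battery with BH correction.

    ``value_sets`` maps (lncRNA-or-group, item) -> (bound values, unbound
    values); constant comparisons are flagged with D = 0, p = 1.  Returns a
    long-format frame with BH-adjusted p-values across the whole battery.
    """
    rows = []
    for (lnc, item), (b, u) in value_sets.items():
        b = np.asarray(b, dtype=float)
        u = np.asarray(u, dtype=float)
        pooled = np.concatenate([b, u])
        if pooled.min() == pooled.max():
            rows.append((lnc, item, 0.0, 1.0, True))
        else:
            d, p = signed_ks(b, u, sign_convention)
            rows.append((lnc, item, d, p, False))
    df = pd.DataFrame(rows, columns=["lncrna", "item", "d_signed", "p", "constant"])
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), alpha=alpha, method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df


def kmer_density_correlation(median_ranks: pd.Series, density: pd.Series) -> tuple[float, float]:
    """Spearman correlation between 5-mer importance rank and density.

    ``median_ranks`` uses 1 = most important; an important-and-dense
    relationship therefore shows as a *negative* rho.  A zero-variance
    density returns (nan, nan).
    """
    common = median_ranks.index.intersection(density.index)
    r = median_ranks.loc[common].to_numpy(dtype=float)
    d = density.loc[common].to_numpy(dtype=float)
    if len(common) < 3 or np.all(d == d[0]) or np.all(r == r[0]):
        return float("nan"), float("nan")
    rho, p = spearmanr(r, d)
    return float(rho), float(p)


def seed_to_kmers(seed: str, k: int = 5) -> list[str]:
    """Constituent canonical k-mers of a miRNA seed (all overlapping windows)."""
    return [canonical(seed[i:i + k]) for i in range(len(seed) - k + 1)]


def seed_enrichment_matrix(kmer_counts: pd.DataFrame,
                           bound_ids: dict[str, np.ndarray],
                           unbound_ids: dict[str, np.ndarray],
                           seeds: dict[str, str],
                           sign_convention: int = 1) -> pd.DataFrame:
    """lncRNA x miRNA matrix of signed-KS seed-content enrichment.

    For each (lncRNA, miRNA): the per-tile sum of the counts of the seed's
    constituent canonical 5-mers is compared between bound and unbound
    tiles.  Seeds with no valid 5-mer column are dropped with a warning.
    Rows/columns are returned in average-linkage hierarchical-cluster order
    (computed on name-sorted input, so the ordering is invariant to input
    row order).
    """
    import warnings
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist

    valid_cols = set(kmer_counts.columns)
    mat: dict[str, dict[str, float]] = {}
    for mirna in sorted(seeds):
        cols = [km for km in seed_to_kmers(seeds[mirna]) if km in valid_cols]
        if not cols:
            warnings.warn(f"seed {mirna} has no valid 5-mers; dropped")
            continue
        content = kmer_counts[cols].sum(axis=1)
        for lnc in sorted(bound_ids):
            b = content.loc[bound_ids[lnc]].to_numpy()
            u = content.loc[unbound_ids[lnc]].to_numpy()
            if np.ptp(np.concatenate([b, u])) == 0:
                d = 0.0
            else:
                d, _ = signed_ks(b, u, sign_convention)
            mat.setdefault(lnc, {})[mirna] = d
    df = pd.DataFrame(mat).T.sort_index()
    df = df[sorted(df.columns)]
    if df.shape[0] > 2:
        order = leaves_list(average(pdist(df.to_numpy())))
        df = df.iloc[order]
    if df.shape[1] > 2:
        order = leaves_list(average(pdist(df.to_numpy().T)))
        df = df.iloc[:, order]
    return df
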