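"""Permutation and rank statistics.

The workhorse is an adonis-style PERMANOVA: sequential (Type I) partitioning
of a squared-distance matrix via the Gower-centered inner-product matrix
G = -1/2 J D^2 J, with pseudo-F per term and p-values from raw permutation
of sample identities.  Both continuous covariates and categorical factors
are supported; terms are fitted in the order given.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .core import OtuTable, ValidationError


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    BC(a, b) = sum_i |x_ai - x_bi| / sum_i (x_ai + x_bi).
    """
    X = table.counts.to_numpy(dtype=float)
    if (X.sum(axis=1) == 0).any():
        zero = table.counts.index[X.sum(axis=1) == 0].tolist()
        raise ValidationError(f"all-zero sample(s): {zero}")
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")), ids=table.sample_ids)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    row = d2.mean(axis=1, keepdims=True)
    return -0.5 * (d2 - row - row.T + d2.mean())


def _term_basis(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[int]]:
    """Orthonormal basis columns for the sequential model, intercept first.

    Returns the n x r basis Q and, per term, the number of basis vectors it
    contributes (its sequential degrees of freedom).
    """
    n = len(data)
    cols = [np.ones((n, 1))]
    sizes = []
    for term in terms:
        if term not in data.columns:
            raise ValidationError(f"unknown term: {term}")
        v = data[term]
        if pd.api.types.is_numeric_dtype(v):
            X = v.to_numpy(dtype=float).reshape(-1, 1)
        else:
            X = pd.get_dummies(v.astype(str), drop_first=True).to_numpy(dtype=float)
        cols.append(X)
        sizes.append(X.shape[1])
    full = np.column_stack([c for c in cols])
    Q, R = np.linalg.qr(full)
    keep = np.abs(np.diag(R)) > 1e-9 * max(1.0, np.abs(R).max())
    # map surviving basis vectors back to terms
    dfs, offset = [], 1
    for sz in sizes:
        dfs.append(int(keep[offset : offset + sz].sum()))
        offset += sz
    for term, df in zip(terms, dfs):
        if df == 0:
            raise ValidationError(f"term '{term}' is constant or confounded")
    return Q[:, keep], dfs


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms + Residual + Total
    n_perm: int | None
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return self.table


def permanova(
    dm,
    data: pd.DataFrame,
    terms: list[str],
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """Sequential multi-term PERMANOVA on a distance matrix.

    Parameters
    ----------
    dm
        skbio DistanceMatrix or square DataFrame; labels must match
        ``data.index``.
    data
        Covariate/factor table, one row per sample.
    terms
        Model terms fitted in this order (Type I sums of squares).
    n_perm
        Number of identity permutations; ``None`` enumerates all n!
        permutations exactly (p = count/total); otherwise
        p = (count + 1)/(n_perm + 1).
    """
    if isinstance(dm, DistanceMatrix):
        D = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    else:
        D = dm
    if not set(data.index.astype(str)) >= set(map(str, D.index)):
        raise ValidationError("distance labels not all present in data")
    data = data.loc[D.index]
    n = D.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 samples")
    G = _gower_center(np.asarray(D, dtype=float) ** 2)
    ss_total = float(np.trace(G))
    Q, dfs = _term_basis(data, terms)
    df_model = Q.shape[1] - 1
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise ValidationError("model is saturated: no residual degrees of freedom")

    # per-basis-vector SS under a permutation p: diag(Q' G_p Q)
    def term_ss(Gp: np.ndarray) -> np.ndarray:
        comp = np.einsum("ij,jk,ki->i", Q.T, Gp, Q)
        out, off = np.empty(len(terms)), 1
        for t, sz in enumerate(dfs):
            out[t] = comp[off : off + sz].sum()
            off += sz
        return out

    dfs_arr = np.array(dfs, dtype=float)

    def f_stats(ssp: np.ndarray, ssr: float) -> np.ndarray:
        # a perfectly separating model has zero residual SS: F = inf
        with np.errstate(divide="ignore"):
            return np.where(ssr > 0, (ssp / dfs_arr) / (ssr / df_res), np.inf)

    ss_obs = term_ss(G)
    ss_res = ss_total - ss_obs.sum()
    F_obs = f_stats(ss_obs, ss_res)

    rng = np.random.default_rng(seed)
    if n_perm is None:
        perms = list(itertools.permutations(range(n)))
        count = np.zeros(len(terms))
        for p in perms:
            Gp = G[np.ix_(p, p)]
            ssp = term_ss(Gp)
            Fp = f_stats(ssp, ss_total - ssp.sum())
            count += Fp >= F_obs - 1e-12
        pvals = count / len(perms)
        n_used = len(perms)
    else:
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            p = rng.permutation(n)
            Gp = G[np.ix_(p, p)]
            ssp = term_ss(Gp)
            Fp = f_stats(ssp, ss_total - ssp.sum())
            count += Fp >= F_obs - 1e-12
        pvals = (count + 1) / (n_perm + 1)
        n_used = n_perm

    rows = []
    for t, term in enumerate(terms):
        rows.append(
            dict(term=term, df=dfs[t], SS=ss_obs[t], F=F_obs[t],
                 R2=ss_obs[t] / ss_total, p=pvals[t])
        )
    rows.append(dict(term="Residual", df=df_res, SS=ss_res, F=np.nan,
                     R2=ss_res / ss_total, p=np.nan))
    rows.append(dict(term="Total", df=n - 1, SS=ss_total, F=np.nan, R2=1.0, p=np.nan))
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_used, seed)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    All-identical values yield H = 0, p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("kruskal_wallis needs >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValidationError("empty group")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    H, p = scipy.stats.kruskal(*samples)
    return float(H), float(p)


def spearman(x, y) -> float:
    """Spearman rank correlation; NaN (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("spearman needs equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("spearman undefined for constant vector; returning NaN")
        return math.nan
    return float(scipy.stats.spearmanr(x, y).statistic)
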