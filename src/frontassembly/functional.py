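"""Trait space and functional diversity.

Mixed-type traits (numeric sizes, categorical morphology, binary flags) are
compared with Gower's distance, embedded with PCoA, and community functional
richness is the convex-hull volume of a community's OTUs in the first few
PCoA axes, normalized by the hull of the whole OTU pool so values lie in
[0, 1].  Ecological strategies are complete-linkage clusters of the Gower
distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .core import NUMERIC_TRAITS, PHOTOTROPH_COLUMN, ValidationError

logger = logging.getLogger("frontassembly")


def gower_distance(traits: pd.DataFrame) -> DistanceMatrix:
    """Gower distance over mixed-type trait rows.

    Numeric traits contribute |x_a - x_b| / range(trait); categorical and
    binary traits contribute 1 if the values differ.  A trait missing in
    either row gets zero weight for that pair; the distance is the weighted
    mean over comparable traits.  A pair with no comparable trait raises.
    """
    cols = [c for c in traits.columns if c != PHOTOTROPH_COLUMN]
    if len(traits) < 2:
        raise ValidationError("gower_distance needs >= 2 rows")
    n = len(traits)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for c in cols:
        v = traits[c]
        if c in NUMERIC_TRAITS or pd.api.types.is_numeric_dtype(v):
            x = v.to_numpy(dtype=float)
            ok = np.isfinite(x)
            rng = np.nanmax(x) - np.nanmin(x) if ok.any() else 0.0
            if rng == 0:
                delta = np.zeros((n, n))
            else:
                delta = np.abs(x[:, None] - x[None, :]) / rng
        else:
            x = v.to_numpy(dtype=object)
            ok = pd.notna(v).to_numpy()
            delta = (x[:, None] != x[None, :]).astype(float)
        w = (ok[:, None] & ok[None, :]).astype(float)
        num += np.where(w > 0, delta, 0.0) * w
        den += w
    if (den == 0).any():
        i, j = np.argwhere(den == 0)[0]
        raise ValidationError(
            f"no comparable traits between rows "
            f"'{traits.index[i]}' and '{traits.index[j]}'"
        )
    G = num / den
    np.fill_diagonal(G, 0.0)
    G = 0.5 * (G + G.T)
    return DistanceMatrix(G, ids=list(traits.index.astype(str)))


@dataclass
class FunctionalSpace:
    """PCoA embedding of the trait-distance matrix.

    ``coordinates`` are the OTU scores on the retained positive-eigenvalue
    axes (scaled by sqrt(eigenvalue)); ``pool_hull_volume`` is the convex
    hull volume of the entire OTU pool in the first ``m`` axes and is the
    normalizer that maps functional richness into [0, 1].
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    m: int
    pool_hull_volume: float


def pcoa(dm: DistanceMatrix, m: int = 4) -> FunctionalSpace:
    """Principal coordinate analysis retaining ``m`` positive axes.

    Negative eigenvalues (from non-Euclidean Gower matrices) are dropped and
    their total magnitude logged; no Cailliez/Lingoes correction is applied.
    """
    n = dm.shape[0]
    if m < 2:
        raise ValidationError("m must be >= 2")
    if n <= m:
        raise ValidationError(f"need more than m={m} points, got {n}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    tol = 1e-9 * max(eig.max(), 1.0)
    neg = eig[eig < -tol]
    if len(neg):
        logger.info("dropping %d negative eigenvalues (total %.4g)", len(neg), neg.sum())
    keep = eig > -tol  # genuinely negative axes are dropped; ~zero axes kept
    if keep.sum() < m:
        raise ValidationError(
            f"only {int(keep.sum())} non-negative eigenvalues; reduce m below that"
        )
    eig = np.clip(eig[keep], 0.0, None)
    coords = res.samples.to_numpy()[:, keep][:, :m]
    coords = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PCo{i+1}" for i in range(m)]
    )
    try:
        pool_vol = _hull_volume(coords.to_numpy())
    except ValidationError:
        # degenerate pool (e.g. collinear points): the embedding itself is
        # still valid, only hull-based richness is unavailable
        logger.info("pool hull degenerate in %d axes; FRic unavailable", m)
        pool_vol = float("nan")
    return FunctionalSpace(coords, eig, m, pool_vol)


def _hull_volume(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:
        raise ValidationError(
            "degenerate point set (co-planar or too few points); "
            "reduce the number of retained axes m"
        ) from exc


def functional_richness(space: FunctionalSpace, presence: dict) -> pd.Series:
    """FRic per community: hull volume of its OTUs / pool hull volume.

    ``presence`` maps community labels to OTU-id sets; every OTU must be in
    the functional space.  FRic of the full pool is exactly 1.
    """
    if not np.isfinite(space.pool_hull_volume) or space.pool_hull_volume <= 0:
        raise ValidationError(
            "pool hull volume is degenerate; reduce the number of axes m"
        )
    out = {}
    pool = set(space.coordinates.index)
    for label, otus in presence.items():
        otus = sorted(set(otus))
        missing = set(otus) - pool
        if missing:
            raise ValidationError(
                f"community '{label}' has OTUs outside the space: {sorted(missing)[:5]}"
            )
        if len(otus) <= space.m:
            raise ValidationError(
                f"community '{label}' has {len(otus)} OTUs; need > m={space.m}"
            )
        if len(otus) == len(pool):
            out[label] = 1.0
            continue
        vol = _hull_volume(space.coordinates.loc[otus].to_numpy())
        out[label] = vol / space.pool_hull_volume
    return pd.Series(out, name="functional_richness")


def strategy_clustering(dm: DistanceMatrix, k: int = 9) -> pd.Series:
    """Cut a complete-linkage dendrogram of the trait distances into k clusters.

    Returns a Series mapping each OTU to a cluster id in 1..k.  Cluster ids
    are relabelled by order of first appearance so the partition, not the
    numbering, is the meaningful output.
    """
    n = dm.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds {n} rows")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        Z = sch.linkage(squareform(dm.data, checks=False), method="complete")
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
    # canonical relabelling: first-appearance order
    seen, remap = {}, np.empty_like(labels)
    for i, lab in enumerate(labels):
        remap[i] = seen.setdefault(lab, len(seen) + 1)
    return pd.Series(remap, index=list(dm.ids), name="strategy")


def strategy_distribution(
    assignment: pd.Series,
    presence: dict,
    all_otus: set | None = None,
) -> pd.DataFrame:
    """OTU counts per ecological strategy per station.

    ``presence`` maps station labels to the OTU sets present there (one
    season).  OTUs absent from ``assignment`` (insufficient trait data) are
    tallied in the ``unannotated`` row.  Column sums equal station richness.
    """
    strategies = sorted(assignment.unique())
    rows = [f"strategy_{s}" for s in strategies] + ["unannotated"]
    out = pd.DataFrame(0, index=rows, columns=sorted(presence), dtype=int)
    annotated = set(assignment.index)
    for station, otus in presence.items():
        otus = set(otus)
        if all_otus is not None:
            otus &= all_otus
        for otu in otus:
            if otu in annotated:
                out.loc[f"strategy_{assignment[otu]}", station] += 1
            else:
                out.loc["unannotated", station] += 1
    return out
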