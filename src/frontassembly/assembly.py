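"""Phylogenetic and compositional turnover null models and process inference.

The inference follows the now-standard two-stage null-model framework for
community assembly.  Phylogenetic turnover between two communities is the
β-mean-nearest-taxon-distance (βMNTD): the mean, over taxa of one community,
of the cophenetic distance to the closest taxon of the other community,
averaged over both directions (presence/absence weighting).  Its null
distribution comes from shuffling tip labels across the regional pool; the
standardized deviation is the β-nearest-taxon index (βNTI).  Compositional
turnover beyond richness and occupancy is measured by the Raup-Crick metric
(RC) on Jaccard dissimilarity, rescaled to [-1, 1].  Pairs are then
classified:

* βNTI < -2            -> homogeneous selection
* βNTI > +2            -> variable selection
* |βNTI| <= 2, RC > +0.95 -> dispersal limitation
* |βNTI| <= 2, RC < -0.95 -> homogenizing dispersal
* otherwise            -> ecological drift

Boundary values (|βNTI| = 2, |RC| = 0.95) fall through to the weaker
category, matching the strict inequalities of the framework.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .core import OtuTable, ValidationError, validate_tree


class Process(str, enum.Enum):
    HOMOGENEOUS_SELECTION = "HomogeneousSelection"
    VARIABLE_SELECTION = "VariableSelection"
    DISPERSAL_LIMITATION = "DispersalLimitation"
    HOMOGENIZING_DISPERSAL = "HomogenizingDispersal"
    DRIFT = "Drift"


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (cophenetic) distances of a rooted tree."""
    validate_tree(tree)
    return tree.tip_tip_distances()


def jaccard_dissimilarity(presence_a, presence_b) -> float:
    """1 - |A∩B| / |A∪B| for two non-empty presence sets."""
    a, b = set(presence_a), set(presence_b)
    if not a or not b:
        raise ValidationError("Jaccard dissimilarity of an empty community")
    return 1.0 - len(a & b) / len(a | b)


def bmntd(presence_a, presence_b, phylo: DistanceMatrix) -> float:
    """β-mean-nearest-taxon-distance between two presence sets.

    0.5 * [mean_{i in A} min_{j in B} d(i, j) + mean_{j in B} min_{i in A} d(i, j)].
    Taxa shared by both communities contribute zero (conspecific nearest
    neighbours are not excluded).
    """
    a, b = sorted(set(presence_a)), sorted(set(presence_b))
    if not a or not b:
        raise ValidationError("βMNTD of an empty community")
    idx = {t: k for k, t in enumerate(phylo.ids)}
    try:
        ia = np.array([idx[t] for t in a])
        ib = np.array([idx[t] for t in b])
    except KeyError as exc:
        raise ValidationError(f"taxon not on tree/distance matrix: {exc}") from exc
    sub = phylo.data[np.ix_(ia, ib)]
    return 0.5 * (sub.min(axis=1).mean() + sub.min(axis=0).mean())


# -- vectorized βMNTD over all sample pairs --------------------------------

def _bmntd_matrix(P: np.ndarray, D: np.ndarray) -> np.ndarray:
    """βMNTD for every pair of rows of the boolean presence matrix P.

    Uses the nearest-taxon matrix M[s, i] = min_{j in sample s} D[i, j]:
    βMNTD(a, b) = 0.5 * (mean_{i in a} M[b, i] + mean_{j in b} M[a, j]).
    """
    S, n = P.shape
    M = np.empty((S, n))
    for s in range(S):
        M[s] = D[:, P[s]].min(axis=1)
    rich = P.sum(axis=1).astype(float)
    half = (P @ M.T) / rich[:, None]  # half[a, b] = mean_{i in a} M[b, i]
    out = 0.5 * (half + half.T)
    np.fill_diagonal(out, 0.0)
    return out


def _pool_distances(table: OtuTable, tree: TreeNode) -> tuple[np.ndarray, np.ndarray]:
    """Cophenetic distances over the full regional-pool tree.

    Returns the pool distance matrix (every tip of the tree, whether or not
    it occurs in the table) and the column indices of the table's OTUs in
    it.  Null models shuffle labels across the whole pool, so taxa of the
    regional pool that never occur in the table still broaden the null.
    """
    dm = cophenetic_distances(tree)
    missing = set(table.otu_ids) - set(dm.ids)
    if missing:
        raise ValidationError(
            f"OTU(s) absent from the tree: {sorted(missing)[:5]} "
            f"({len(missing)} total)"
        )
    idx = {t: k for k, t in enumerate(dm.ids)}
    order = np.array([idx[o] for o in table.otu_ids])
    return dm.data, order


def bnti(
    table: OtuTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int | None = None,
    return_obs: bool = False,
    pool: str = "regional",
    missing_otus: str = "error",
):
    """βNTI matrix for all sample pairs of a table.

    Null βMNTD distributions are generated by shuffling tip labels across
    the full regional-pool tree (``pool="regional"``, the default) or, with
    ``pool="pairwise"``, across only the taxa of each pair; one permutation
    is shared by all pairs per null replicate in regional mode.  βNTI =
    (obs - null mean) / null sd, defined as 0 where the null sd vanishes
    (e.g. star trees).  OTUs absent from the tree raise by default;
    ``missing_otus="prune"`` drops them from the table instead.
    """
    if n_null < 2:
        raise ValidationError("n_null must be >= 2")
    if pool not in ("regional", "pairwise"):
        raise ValidationError(f"unknown null pool: {pool}")
    if missing_otus == "prune":
        tips = {t.name for t in tree.tips()}
        keep = [o for o in table.otu_ids if o in tips]
        if len(keep) < table.n_otus:
            warnings.warn(
                f"pruning {table.n_otus - len(keep)} OTU(s) absent from the tree"
            )
            table = table.subset_otus(keep)
    elif missing_otus != "error":
        raise ValidationError(f"unknown missing_otus policy: {missing_otus}")
    if pool == "pairwise":
        return _bnti_pairwise(table, tree, n_null, seed, return_obs)
    Dpool, cols = _pool_distances(table, tree)
    Ptab = table.presence().to_numpy()
    if (Ptab.sum(axis=1) == 0).any():
        raise ValidationError("empty community in table")
    # embed presence into pool coordinates
    P = np.zeros((Ptab.shape[0], Dpool.shape[0]), dtype=bool)
    P[:, cols] = Ptab
    obs = _bmntd_matrix(P, Dpool)
    S = P.shape[0]
    acc = np.zeros((S, S))
    acc2 = np.zeros((S, S))
    rng = np.random.default_rng(seed)
    n = Dpool.shape[0]
    for _ in range(n_null):
        perm = rng.permutation(n)
        Dp = Dpool[np.ix_(perm, perm)]
        bm = _bmntd_matrix(P, Dp)
        acc += bm
        acc2 += bm * bm
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    np.fill_diagonal(z, 0.0)
    ids = table.sample_ids
    zdf = pd.DataFrame(z, index=ids, columns=ids)
    if return_obs:
        stats = dict(
            obs=pd.DataFrame(obs, index=ids, columns=ids),
            null_mean=pd.DataFrame(mean, index=ids, columns=ids),
            null_sd=pd.DataFrame(sd, index=ids, columns=ids),
        )
        return zdf, stats
    return zdf


def _bnti_pairwise(table, tree, n_null, seed, return_obs):
    """Per-pair null pools: shuffle labels only over each pair's taxa."""
    Dpool, cols = _pool_distances(table, tree)
    Ptab = table.presence().to_numpy()
    if (Ptab.sum(axis=1) == 0).any():
        raise ValidationError("empty community in table")
    ids = table.sample_ids
    S = len(ids)
    rng = np.random.default_rng(seed)
    obs = np.zeros((S, S))
    mean = np.zeros((S, S))
    sd = np.zeros((S, S))
    z = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            union = np.flatnonzero(Ptab[i] | Ptab[j])
            sub = Dpool[np.ix_(cols[union], cols[union])]
            Pij = np.vstack([Ptab[i, union], Ptab[j, union]])
            o = _bmntd_matrix(Pij, sub)[0, 1]
            nulls = np.empty(n_null)
            for r in range(n_null):
                perm = rng.permutation(len(union))
                nulls[r] = _bmntd_matrix(Pij, sub[np.ix_(perm, perm)])[0, 1]
            m, s = nulls.mean(), nulls.std()
            obs[i, j] = obs[j, i] = o
            mean[i, j] = mean[j, i] = m
            sd[i, j] = sd[j, i] = s
            z[i, j] = z[j, i] = (o - m) / s if s > 0 else 0.0
    zdf = pd.DataFrame(z, index=ids, columns=ids)
    if return_obs:
        return zdf, dict(
            obs=pd.DataFrame(obs, index=ids, columns=ids),
            null_mean=pd.DataFrame(mean, index=ids, columns=ids),
            null_sd=pd.DataFrame(sd, index=ids, columns=ids),
        )
    return zdf


def raup_crick(
    table: OtuTable,
    n_null: int = 999,
    seed: int | None = None,
    weighted_occupancy: bool = False,
) -> pd.DataFrame:
    """Raup-Crick compositional turnover in [-1, 1] for all sample pairs.

    The species pool is every OTU in the table, weighted by occupancy (the
    fraction of samples occupied; optionally abundance-weighted).  For each
    pair, null community pairs preserving each sample's richness are drawn
    by occupancy-weighted sampling without replacement, the Jaccard
    dissimilarity of each null pair is compared with the observed one, and
    RC = 2 * [#(J_null < J_obs) + 0.5 #(J_null = J_obs)] / n_null - 1.

    Null communities are drawn once per sample (``n_null`` replicates each)
    and paired across samples, which is equivalent to drawing ``n_null``
    independent null pairs for every pair of samples.
    """
    if n_null < 2:
        raise ValidationError("n_null must be >= 2")
    P = table.presence().to_numpy()
    S, n_pool = P.shape
    if S < 2:
        raise ValidationError("need >= 2 samples")
    rich = P.sum(axis=1)
    if (rich == 0).any():
        raise ValidationError("empty community in table")
    if (rich > n_pool).any():  # pragma: no cover - impossible by construction
        raise ValidationError("sample richness exceeds pool size")
    if weighted_occupancy:
        w = table.counts.to_numpy(dtype=float).sum(axis=0)
    else:
        w = P.mean(axis=0).astype(float)
    logw = np.log(w)  # every pooled OTU occupies >= 1 sample, so w > 0

    rng = np.random.default_rng(seed)
    # Gumbel top-k: keys log(w) + G give weighted sampling without replacement
    nulls = np.zeros((S, n_null, n_pool), dtype=bool)
    rows = np.arange(n_null)[:, None]
    for s in range(S):
        keys = logw + rng.gumbel(size=(n_null, n_pool))
        top = np.argpartition(-keys, rich[s] - 1, axis=1)[:, : rich[s]]
        nulls[s, rows, top] = True
    packed = np.packbits(nulls, axis=2).view(np.uint8)

    Pi = P.astype(np.int64)
    inter_obs = Pi @ Pi.T
    union_obs = rich[:, None] + rich[None, :] - inter_obs
    rc = np.zeros((S, S))
    for a in range(S):
        for b in range(a + 1, S):
            inter = np.bitwise_count(packed[a] & packed[b]).sum(axis=1).astype(np.int64)
            union = rich[a] + rich[b] - inter
            # J_null < J_obs  <=>  inter * union_obs > inter_obs * union
            lhs = inter * union_obs[a, b]
            rhs = inter_obs[a, b] * union
            below = int((lhs > rhs).sum())
            ties = int((lhs == rhs).sum())
            rc[a, b] = rc[b, a] = 2.0 * (below + 0.5 * ties) / n_null - 1.0
    ids = table.sample_ids
    return pd.DataFrame(rc, index=ids, columns=ids)


def classify_process(bnti_value: float, rc_value: float) -> Process:
    """Map a (βNTI, RC) pair to its dominant assembly process."""
    if not (math.isfinite(bnti_value) and math.isfinite(rc_value)):
        raise ValidationError("non-finite βNTI or RC")
    if not -1.0 - 1e-12 <= rc_value <= 1.0 + 1e-12:
        raise ValidationError(f"RC out of [-1, 1]: {rc_value}")
    if bnti_value < -2:
        return Process.HOMOGENEOUS_SELECTION
    if bnti_value > 2:
        return Process.VARIABLE_SELECTION
    if rc_value > 0.95:
        return Process.DISPERSAL_LIMITATION
    if rc_value < -0.95:
        return Process.HOMOGENIZING_DISPERSAL
    return Process.DRIFT


@dataclass
class AssemblyResult:
    """Null-model inference for one pair of communities."""

    sample_a: str
    sample_b: str
    bmntd_obs: float
    null_mean: float
    null_sd: float
    bnti: float
    rc: float
    process: Process
    n_null: int


def infer_assembly(
    table: OtuTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int | None = None,
) -> list[AssemblyResult]:
    """Run βNTI + RC and classify every sample pair of a table."""
    ss = np.random.SeedSequence(seed)
    s_bnti, s_rc = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    z, stats = bnti(table, tree, n_null=n_null, seed=s_bnti, return_obs=True)
    rc = raup_crick(table, n_null=n_null, seed=s_rc)
    ids = table.sample_ids
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            out.append(
                AssemblyResult(
                    a, b,
                    float(stats["obs"].loc[a, b]),
                    float(stats["null_mean"].loc[a, b]),
                    float(stats["null_sd"].loc[a, b]),
                    float(z.loc[a, b]),
                    float(rc.loc[a, b]),
                    classify_process(float(z.loc[a, b]), float(rc.loc[a, b])),
                    n_null,
                )
            )
    return out


def results_to_frame(results: list[AssemblyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                sample_a=r.sample_a, sample_b=r.sample_b, bmntd_obs=r.bmntd_obs,
                null_mean=r.null_mean, null_sd=r.null_sd, bnti=r.bnti, rc=r.rc,
                process=r.process.value, n_null=r.n_null,
            )
            for r in results
        ]
    )


@dataclass
class ProcessSummary:
    counts: dict  # process value -> number of pairs
    edges: pd.DataFrame  # non-homogeneous-selection pairs, with multiplicity

    def to_frame(self) -> pd.DataFrame:
        return self.edges


def process_summary(
    results: list[AssemblyResult], node_map: pd.Series | None = None
) -> ProcessSummary:
    """Count processes over all pairs and list the non-HS edges.

    ``node_map`` maps sample ids to network node labels (e.g. station|season);
    edges between the same node pair with the same process accumulate a
    multiplicity, the convention used to widen repeated network edges.
    """
    if not results:
        raise ValidationError("no assembly results to summarize")
    counts = {p.value: 0 for p in Process}
    for r in results:
        counts[r.process.value] += 1
    rows = []
    for r in results:
        if r.process is Process.HOMOGENEOUS_SELECTION:
            continue
        a = str(node_map[r.sample_a]) if node_map is not None else r.sample_a
        b = str(node_map[r.sample_b]) if node_map is not None else r.sample_b
        a, b = sorted((a, b))
        rows.append((a, b, r.process.value))
    if rows:
        edges = (
            pd.DataFrame(rows, columns=["node_a", "node_b", "process"])
            .value_counts()
            .rename("multiplicity")
            .reset_index()
            .sort_values(["node_a", "node_b", "process"])
            .reset_index(drop=True)
        )
    else:
        edges = pd.DataFrame(columns=["node_a", "node_b", "process", "multiplicity"])
    return ProcessSummary(counts, edges)


def mantel(
    dm_x: DistanceMatrix,
    dm_y: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test: Pearson r of off-diagonal entries, one-sided permutation p.

    The second matrix's labels are permuted; p = (#(r_perm >= r_obs) + 1) /
    (n_perm + 1).
    """
    if list(dm_x.ids) != list(dm_y.ids):
        raise ValidationError("Mantel matrices must share labels and order")
    n = dm_x.shape[0]
    iu = np.triu_indices(n, k=1)
    x = dm_x.data[iu]
    Y = dm_y.data
    y = Y[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Mantel undefined for a constant matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = Y[np.ix_(p, p)][iu]
        if np.corrcoef(x, yp)[0, 1] >= r_obs - 1e-12:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


def phylo_trait_signal(
    phylo: DistanceMatrix,
    traits: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test of phylogenetic vs trait distances over the same taxa.

    A significantly positive correlation supports using phylogenetic
    turnover as a proxy for niche/trait turnover in the βNTI inference.
    """
    return mantel(phylo, traits, n_perm=n_perm, seed=seed)
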