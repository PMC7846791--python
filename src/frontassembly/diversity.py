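"""Richness, rarefaction, occurrence/abundance partitions and OTU-connectivity.

These are the bookkeeping analyses of a metabarcoding survey: filter the
table down to obligate phototrophs, count OTUs per sample and per merged
group, draw analytic rarefaction curves, estimate asymptotic richness
(Chao1), label OTUs as shared between stations or station-specific within a
season, partition them into abundant / low-abundance / rare classes, and
build the station x season network whose edge weights are numbers of shared
OTUs — together with a control that equalizes OTU numbers across seasons.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import OtuTable, ValidationError, merge_samples
from .stats import spearman

logger = logging.getLogger("frontassembly")

THETA_ABUNDANT = 1e-3  # >0.1% of season reads
THETA_LOW = 1e-4  # >0.01% of season reads


def filter_phototrophs(table: OtuTable, traits: pd.DataFrame) -> OtuTable:
    """Retain OTUs whose taxonomic reference is an obligate phototroph.

    References absent from the trait table count as non-phototrophs.
    """
    from .core import PHOTOTROPH_COLUMN

    if PHOTOTROPH_COLUMN not in traits.columns:
        raise ValidationError(f"trait table lacks '{PHOTOTROPH_COLUMN}' column")
    flag = traits[PHOTOTROPH_COLUMN].astype(bool)
    keep_mask = table.taxref.map(flag) == True  # noqa: E712 (NaN -> False)
    keep = [o for o, k in keep_mask.items() if k]
    if not keep:
        raise ValidationError(
            "no phototrophic OTUs retained; check the obligate_phototroph column"
        )
    total_reads = table.counts.to_numpy().sum()
    kept_reads = table.counts[keep].to_numpy().sum()
    logger.info(
        "phototroph filter: retained %d/%d OTUs (%.1f%%), %.1f%% of reads",
        len(keep), table.n_otus, 100 * len(keep) / table.n_otus,
        100 * kept_reads / max(total_reads, 1),
    )
    return table.subset_otus(keep)


def richness(table: OtuTable, per: list[str] | None = None) -> pd.Series:
    """Number of OTUs with count > 0, per sample or per merged group."""
    t = merge_samples(table, per) if per else table
    r = (t.counts > 0).sum(axis=1)
    if (r == 0).any():
        warnings.warn("sample(s) with zero richness present")
    return r.rename("richness")


def rarefaction_curve(counts, depths) -> pd.Series:
    """Analytic expected richness E[S_n] at each subsampling depth n.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)], evaluated with
    log-gamma combinatorics so arbitrarily deep samples do not overflow.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if (depths < 1).any() or (depths > N).any():
        raise ValidationError(f"rarefaction depths must lie in [1, {N}]")
    out = np.empty(len(depths), dtype=float)
    lgN = gammaln(N + 1)
    for k, n in enumerate(depths):
        lg_denom = lgN - gammaln(n + 1) - gammaln(N - n + 1)
        M = N - counts  # reads not belonging to OTU i
        ok = M >= n
        p_absent = np.zeros(len(counts))
        Mok = M[ok]
        p_absent[ok] = np.exp(
            gammaln(Mok + 1) - gammaln(n + 1) - gammaln(Mok - n + 1) - lg_denom
        )
        out[k] = float(np.sum(1.0 - p_absent))
    return pd.Series(out, index=pd.Index(depths, name="n"), name="expected_richness")


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 asymptotic richness estimate.

    Bias-corrected form S_obs + F1(F1 - 1) / (2(F2 + 1)); the classic form
    S_obs + F1^2 / (2 F2) is available with ``bias_corrected=False`` (and
    falls back to the corrected form when F2 = 0).
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    s_obs = len(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return s_obs + f1 * f1 / (2 * f2)


def occurrence_categories(table: OtuTable) -> pd.DataFrame:
    """Label each (OTU, season) as shared between stations or station-specific.

    Requires a table merged to one sample per (station, season).  ``shared``
    means present at >= 2 stations of that season; otherwise
    ``specific:<station>``.
    """
    meta = table.metadata
    if not {"season", "station"} <= set(meta.columns):
        raise ValidationError("occurrence_categories needs season and station metadata")
    if meta.duplicated(subset=["season", "station"]).any():
        raise ValidationError(
            "table must be merged to one sample per (station, season)"
        )
    records = []
    pres = table.presence()
    for season, idx in meta.groupby("season", observed=True).groups.items():
        block = pres.loc[idx]
        stations = meta.loc[idx, "station"]
        n_st = block.sum(axis=0)
        for otu in block.columns[n_st > 0]:
            col = block[otu]
            if int(n_st[otu]) >= 2:
                label = "shared"
            else:
                label = f"specific:{stations[col].iloc[0]}"
            records.append((otu, season, label))
    return pd.DataFrame(records, columns=["otu_id", "season", "category"])


@dataclass
class AbundanceClasses:
    """Per-OTU abundance class within one season.

    Classes partition the OTUs present in the season by read share p_i:
    abundant (p > 0.1%), low (0.01% < p <= 0.1%), rare (p <= 0.01%).
    Boundary shares go to the lower class (strict '>' thresholds).
    """

    season: str
    classes: pd.Series  # otu_id -> {"abundant", "low", "rare"}
    shares: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"season": self.season, "share": self.shares, "class": self.classes}
        ).rename_axis("otu_id")


def abundance_classes(table: OtuTable, season: str) -> AbundanceClasses:
    if "season" not in table.metadata.columns:
        raise ValidationError("abundance_classes needs season metadata")
    rows = table.metadata.index[table.metadata["season"] == season]
    reads = table.counts.loc[rows].sum(axis=0)
    total = int(reads.sum())
    if total == 0:
        raise ValidationError(f"no reads in season {season}")
    share = reads[reads > 0] / total
    cls = pd.Series(
        np.where(share > THETA_ABUNDANT, "abundant",
                 np.where(share > THETA_LOW, "low", "rare")),
        index=share.index, name="class",
    )
    return AbundanceClasses(season, cls, share.rename("share"))


@dataclass
class ConnectivityNetwork:
    """Station x season (x depth) network of shared-OTU counts."""

    nodes: pd.DataFrame  # index = node id, columns: node_keys... + richness
    edges: pd.DataFrame  # columns: node_a, node_b, shared_otus, intra_season
    presence: dict  # node id -> frozenset of OTU ids

    def to_frame(self) -> pd.DataFrame:
        return self.edges

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node, row in self.nodes.iterrows():
            g.add_node(node, **row.to_dict())
        for _, e in self.edges.iterrows():
            g.add_edge(e.node_a, e.node_b, weight=int(e.shared_otus),
                       intra_season=bool(e.intra_season))
        return g


def otu_connectivity(
    table: OtuTable, node_keys: tuple[str, ...] = ("station", "season")
) -> ConnectivityNetwork:
    """Number of OTUs shared between every pair of station/season groups."""
    meta = table.metadata
    missing = set(node_keys) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata lacks node key(s): {sorted(missing)}")
    pres = table.presence()
    groups = meta.groupby(list(node_keys), observed=True).groups
    node_presence = {}
    records = []
    for key, idx in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        node = "|".join(map(str, key))
        node_presence[node] = frozenset(pres.columns[pres.loc[idx].any(axis=0)])
        records.append(dict(zip(node_keys, key), node=node,
                            richness=len(node_presence[node])))
    nodes = pd.DataFrame(records).set_index("node").sort_index()
    if len(nodes) < 2:
        warnings.warn("single node: empty edge set")
    edges = []
    for a, b in itertools.combinations(sorted(node_presence), 2):
        shared = len(node_presence[a] & node_presence[b])
        intra = ("season" in node_keys and
                 nodes.loc[a, "season"] == nodes.loc[b, "season"])
        edges.append((a, b, shared, bool(intra)))
    edf = pd.DataFrame(edges, columns=["node_a", "node_b", "shared_otus", "intra_season"])
    return ConnectivityNetwork(nodes, edf, node_presence)


def curated_connectivity_control(
    table: OtuTable,
    node_keys: tuple[str, ...] = ("station", "season"),
    seed: int | None = None,
    unit: str = "otus",
) -> tuple[ConnectivityNetwork, float]:
    """Rebuild the connectivity network after equalizing seasons.

    With ``unit="otus"`` (default) each season's OTU *set* is uniformly
    subsampled (without replacement) down to the minimum seasonal richness;
    with ``unit="reads"`` each season's reads are rarefied to the minimum
    seasonal read total instead.  The network is recomputed on the curated
    table and the Spearman correlation between original and curated edge
    weights is returned; a high correlation indicates the connectivity
    pattern is not an artifact of unequal seasonal sampling.
    """
    if "season" not in table.metadata.columns:
        raise ValidationError("curated control needs season metadata")
    if unit not in ("otus", "reads"):
        raise ValidationError(f"unknown curation unit: {unit}")
    seasons = table.metadata["season"].unique()
    if len(seasons) < 2:
        raise ValidationError("curated control needs >= 2 seasons")
    pres = table.presence()
    season_sets = {}
    for s in seasons:
        idx = table.metadata.index[table.metadata["season"] == s]
        otus = pres.columns[pres.loc[idx].any(axis=0)]
        if len(otus) == 0:
            raise ValidationError(f"season {s} has zero OTUs")
        season_sets[s] = list(otus)
    rng = np.random.default_rng(seed)
    curated_counts = table.counts.copy()
    if unit == "otus":
        k_min = min(len(v) for v in season_sets.values())
        for s in sorted(season_sets, key=str):
            otus = season_sets[s]
            if len(otus) > k_min:
                keep = set(rng.choice(np.array(otus, dtype=object),
                                      size=k_min, replace=False))
                drop = [o for o in otus if o not in keep]
                rows = table.metadata.index[table.metadata["season"] == s]
                curated_counts.loc[rows, drop] = 0
    else:
        totals = {
            s: int(table.counts.loc[
                table.metadata.index[table.metadata["season"] == s]
            ].to_numpy().sum())
            for s in seasons
        }
        n_min = min(totals.values())
        for s in sorted(totals, key=str):
            if totals[s] > n_min:
                rows = table.metadata.index[table.metadata["season"] == s]
                flat = curated_counts.loc[rows].to_numpy().ravel()
                sub = rng.multivariate_hypergeometric(flat, n_min)
                curated_counts.loc[rows] = sub.reshape(len(rows), -1)
    curated = OtuTable(curated_counts, table.metadata.copy(), table.taxref)
    original = otu_connectivity(table, node_keys)
    control = otu_connectivity(curated, node_keys)
    merged = original.edges.merge(
        control.edges, on=["node_a", "node_b"], suffixes=("_orig", "_cur")
    )
    w_orig = merged["shared_otus_orig"].to_numpy(dtype=float)
    w_cur = merged["shared_otus_cur"].to_numpy(dtype=float)
    if np.ptp(w_orig) == 0 or np.ptp(w_cur) == 0:
        warnings.warn("constant connectivity weights: Spearman rho undefined")
        rho = float("nan")
    else:
        rho = spearman(w_orig, w_cur)
    return control, rho
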