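"""Synthetic metacommunity generator.

Emulates the statistical structure of a seasonal, multi-station plankton
metabarcoding survey across a tidal front: a Yule phylogeny whose tips carry
phylogenetically heritable (Brownian-motion) niche optima and trait
liabilities, an environmental gradient over stations and seasons with a
frontal station receiving pulsed nutrient input, and community sampling
under tunable selection, dispersal and drift:

* selection: sampling weight of OTU i in sample s includes a Gaussian niche
  factor exp(-(env_s - mu_i)^2 / (2 sigma_sel^2)); sigma_sel = inf is neutral;
* dispersal: station-specific regional pools mixed with the global pool at
  migration rate m (mass effects), or a single well-mixed pool;
* drift: the community is a multinomial draw of J individuals from the
  weights, so finite-size sampling noise is always present.

Scenario presets configure these knobs so that each of the five canonical
assembly processes dominates the downstream null-model classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import (
    BINARY_TRAITS,
    CATEGORICAL_TRAITS,
    OtuTable,
    PHOTOTROPH_COLUMN,
    SEASONS,
    SIZE_FRACTIONS,
    STATIONS,
    ValidationError,
    validate_tree,
)

_CATEGORY_VOCAB = {
    "Cell Cover": ("naked", "organic", "silica", "calcite"),
    "Cell Shape": ("spherical", "elongated", "flattened", "complex"),
    "Cell Symmetry": ("radial", "bilateral", "asymmetric"),
    "Cell Polarity": ("isopolar", "heteropolar"),
    "Ingestion method": ("none", "osmotrophy", "phagotrophy"),
    "Symbiosis type": ("none", "photosymbiont", "parasite"),
}

_STREAMS = ("tree", "traits", "abundance", "env", "community", "fractions", "phototroph")


@dataclass
class SyntheticConfig:
    """Parameters of the generative metacommunity model.

    Sizes default to the full survey design (3 seasons x 5 stations x up to
    2 depths x 3 size fractions x 3 replicates).  ``selection_strength`` is
    the niche-filter width sigma_sel in units of the (standardized) niche
    axis; ``math.inf`` disables selection.  ``migration_rate`` mixes
    station-specific pools with the global pool; ``community_size_gradient``
    spreads the per-sample number of individuals J on a log scale, producing
    nested sampling intensities (a mass-effect signature).
    """

    n_otus: int = 256
    seasons: tuple = SEASONS
    stations: tuple = STATIONS
    dcm_stations: tuple = ("O1", "O2", "F")
    replicates: int = 3
    size_fractions: int = 3
    community_size: int = 2000
    community_size_gradient: float = 0.0
    selection_strength: float = 1.0
    season_selection_scale: tuple = (1.6, 1.0, 0.7)
    niche_heritability: float = 1.0
    niche_conservatism: float = 0.0
    trait_signal: float = 1.0
    abundance_sigma: float = 1.2
    abundance_noise: float = 0.0
    migration_rate: float = 1.0
    station_isolation: bool = False
    front_station: str = "F"
    front_pulse: float = 0.0
    env_mode: str = "seasonal"  # seasonal | quantile | constant
    env_quantiles: tuple | None = None
    env_amplitude: float = 0.8
    env_station_spread: float = 0.5
    fraction_leakage: float = 0.1
    phototroph_fraction: float = 1.0
    scenario: str = "custom"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 4:
            raise ValidationError("n_otus must be >= 4")
        if self.community_size <= 0:
            raise ValidationError("community_size must be > 0")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValidationError("migration_rate must lie in [0, 1]")
        if self.selection_strength <= 0:
            raise ValidationError("selection_strength must be positive (or inf)")
        if not 1 <= self.size_fractions <= len(SIZE_FRACTIONS):
            raise ValidationError("size_fractions must be 1..3")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the root seed (component-level reproducibility)."""
        return np.random.default_rng([_STREAMS.index(stream), self.seed])


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated metacommunity."""

    niche_optima: pd.Series  # per-OTU mu_i on the standardized niche axis
    regional_log_abundance: pd.Series
    sample_env: pd.Series  # realized niche-axis value per sample
    scenario: str


# -- phylogeny -------------------------------------------------------------

def generate_tree(n_otus: int, seed: int | np.random.Generator = 0) -> TreeNode:
    """Pure-birth (Yule) ultrametric tree with exponential waiting times.

    Tips are labelled OTU0001... in ladderized order; deterministic for a
    given seed.
    """
    if n_otus < 2:
        raise ValidationError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = TreeNode()
    birth = {}
    t = 0.0
    first = [TreeNode(), TreeNode()]
    root.extend(first)
    for c in first:
        birth[id(c)] = 0.0
    active = list(first)
    while len(active) < n_otus:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node = active[i]
        node.length = t - birth.pop(id(node))
        kids = [TreeNode(), TreeNode()]
        node.extend(kids)
        for c in kids:
            birth[id(c)] = t
        active[i] = kids[0]
        active.append(kids[1])
    t += rng.exponential(1.0 / n_otus)
    for node in active:
        node.length = t - birth[id(node)]
    for k, tip in enumerate(root.tips()):
        tip.name = f"OTU{k + 1:04d}"
    root.length = None
    return validate_tree(root)


def _brownian(
    tree: TreeNode, rate: float, rng: np.random.Generator, decay: float = 0.0
) -> pd.Series:
    """Brownian-motion trait realization over the tips of a tree.

    ``decay`` > 0 gives an early-burst process: the instantaneous rate is
    rate * exp(-decay * depth), so divergence concentrates at deep splits
    and close relatives stay similar (strong niche conservatism).
    """
    vals = {id(tree): 0.0}
    depth = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        d0 = depth[id(node.parent)]
        length = node.length or 0.0
        depth[id(node)] = d0 + length
        if decay > 0:
            var = rate * (math.exp(-decay * d0) - math.exp(-decay * (d0 + length))) / decay
        else:
            var = rate * length
        vals[id(node)] = vals[id(node.parent)] + rng.normal(0.0, math.sqrt(max(var, 0.0)))
    tips = list(tree.tips())
    return pd.Series([vals[id(t)] for t in tips], index=[t.name for t in tips])


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x * 0.0


def _liability(tree: TreeNode, signal: float, rng: np.random.Generator) -> pd.Series:
    """Standardized liability mixing a BM component with independent noise.

    The phylogenetic variance share is signal / (signal + 0.5): zero signal
    gives pure noise, signal = 1 gives a 2/3 heritable liability.
    """
    w = signal / (signal + 0.5) if signal > 0 else 0.0
    bm = _zscore(_brownian(tree, 1.0, rng)) if w > 0 else 0.0
    tips = [t.name for t in tree.tips()]
    noise = pd.Series(rng.normal(size=len(tips)), index=tips)
    return math.sqrt(w) * bm + math.sqrt(1.0 - w) * noise


def generate_traits(tree: TreeNode, config: SyntheticConfig) -> pd.DataFrame:
    """Mixed-type trait table over the tree tips.

    Cell sizes are exponentiated Brownian liabilities (SizeMax = SizeMin *
    (1 + |liability|) so SizeMin <= SizeMax by construction); categorical
    and binary traits threshold independent liabilities into their
    controlled vocabularies.  Phylogenetic signal in every trait increases
    with ``trait_signal``.
    """
    if tree.count(tips=True) < 4:
        raise ValidationError("need >= 4 tips to generate traits")
    if config.trait_signal < 0:
        raise ValidationError("trait_signal must be >= 0")
    rng = config.rng("traits")
    s = config.trait_signal
    tips = [t.name for t in tree.tips()]
    out = pd.DataFrame(index=pd.Index(tips, name="taxref"))
    l_size = _liability(tree, s, rng)
    out["SizeMin"] = np.exp(1.5 + 0.8 * l_size)
    out["SizeMax"] = out["SizeMin"] * (1.0 + np.abs(_liability(tree, s, rng)))
    for trait in CATEGORICAL_TRAITS:
        vocab = _CATEGORY_VOCAB[trait]
        lia = _liability(tree, s, rng)
        cuts = np.quantile(lia, np.linspace(0, 1, len(vocab) + 1)[1:-1])
        out[trait] = np.array(vocab)[np.searchsorted(cuts, lia)]
    for trait in BINARY_TRAITS:
        lia = _liability(tree, s, rng)
        out[trait] = (lia > lia.median()).astype(int)
    p_rng = config.rng("phototroph")
    out[PHOTOTROPH_COLUMN] = p_rng.random(len(tips)) < config.phototroph_fraction
    return out


# -- environment and design ------------------------------------------------

def _environment_axis(config: SyntheticConfig, mu: pd.Series) -> dict:
    """Niche-axis environment value per (season, station)."""
    env = {}
    n_st = len(config.stations)
    if config.env_mode == "constant":
        for season in config.seasons:
            for st in config.stations:
                env[(season, st)] = 0.0
    elif config.env_mode == "peak":
        # shared environment at the densest point of the realized niche
        # distribution, at the scale of the selection filter
        m = mu.to_numpy()
        sig = config.selection_strength
        if not math.isfinite(sig):
            sig = 1.0
        mass = np.exp(-((m[:, None] - m[None, :]) ** 2) / (2.0 * sig**2)).sum(axis=0)
        peak = float(m[int(np.argmax(mass))])
        for season in config.seasons:
            for st in config.stations:
                env[(season, st)] = peak
    elif config.env_mode == "quantile":
        qs = config.env_quantiles or tuple(np.linspace(0.1, 0.9, n_st))
        vals = np.quantile(mu.to_numpy(), qs)
        for season in config.seasons:
            for st, v in zip(config.stations, vals):
                env[(season, st)] = float(v)
    elif config.env_mode == "seasonal":
        bases = np.linspace(-1, 1, len(config.seasons)) * config.env_amplitude
        offs = np.linspace(-1, 1, n_st) * config.env_station_spread
        for b, season in zip(bases, config.seasons):
            for o, st in zip(offs, config.stations):
                env[(season, st)] = float(b + o)
    else:
        raise ValidationError(f"unknown env_mode: {config.env_mode}")
    return env


def _design(config: SyntheticConfig) -> list[dict]:
    """Flattened list of community draws (before size-fraction splitting)."""
    rows = []
    stratified = [s for s in config.seasons if s in ("July", "September")]
    for season in config.seasons:
        for station in config.stations:
            depths = ["surface"]
            if season in stratified and station in config.dcm_stations:
                depths.append("DCM")
            for depth in depths:
                for rep in range(1, config.replicates + 1):
                    rows.append(dict(season=season, station=station,
                                     depth=depth, replicate=rep))
    return rows


def generate_metacommunity(config: SyntheticConfig):
    """Generate a cross-consistent (OtuTable, tree, traits, env, truth) tuple.

    Per community draw, OTU sampling weights are
    ``regional_i * exp(-(env_s - mu_i)^2 / (2 sigma^2)) * dispersal_i(station)``
    and the community is a multinomial draw of J individuals (drift).
    Counts are then split across size fractions by a per-OTU fraction
    affinity with 10% leakage, mimicking filtration cross-contamination.
    """
    tree = generate_tree(config.n_otus, config.rng("tree"))
    otus = [t.name for t in tree.tips()]
    # niche optima get their own substream so traits and niches are independent
    mu = _zscore(_brownian(tree, max(config.niche_heritability, 1e-12),
                           config.rng("env"), decay=config.niche_conservatism))
    traits = generate_traits(tree, config)

    ab_rng = config.rng("abundance")
    log_ab = pd.Series(ab_rng.normal(0.0, config.abundance_sigma, len(otus)), index=otus)
    regional = np.exp(log_ab.to_numpy())

    # station pools (dispersal limitation): disjoint partition of the pool
    pool_mask = {st: np.ones(len(otus)) for st in config.stations}
    if config.station_isolation:
        order = ab_rng.permutation(len(otus))
        for k, st in enumerate(config.stations):
            mask = np.zeros(len(otus))
            mask[order[k::len(config.stations)]] = 1.0
            pool_mask[st] = mask

    env = _environment_axis(config, mu)
    design = _design(config)
    n_draws = len(design)
    u = np.linspace(-1, 1, n_draws) if n_draws > 1 else np.zeros(1)

    comm_rng = config.rng("community")
    frac_rng = config.rng("fractions")
    fractions = SIZE_FRACTIONS[: config.size_fractions]
    if config.size_fractions > 1:
        dominant = frac_rng.integers(config.size_fractions, size=len(otus))
        leak = config.fraction_leakage
        frac_p = np.full((len(otus), config.size_fractions), leak / (config.size_fractions - 1))
        frac_p[np.arange(len(otus)), dominant] = 1.0 - leak

    scale = dict(zip(config.seasons, config.season_selection_scale))
    stratified = [s for s in config.seasons if s in ("July", "September")]
    counts_rows, meta_rows, env_rows, truth_env = [], [], [], []
    mu_arr = mu.to_numpy()
    season_idx = {s: i for i, s in enumerate(config.seasons)}
    for k, d in enumerate(design):
        season, station = d["season"], d["station"]
        e = env[(season, station)]
        at_front = (station == config.front_station and season in stratified)
        sigma = config.selection_strength * scale.get(season, 1.0)
        J = config.community_size
        if at_front and config.front_pulse > 0:
            sigma *= 1.0 + config.front_pulse
            J = int(round(J * (1.0 + config.front_pulse)))
        if config.community_size_gradient > 0:
            J = int(round(J * math.exp(config.community_size_gradient * u[k])))
        if math.isinf(sigma):
            niche = np.ones(len(otus))
        else:
            niche = np.exp(-((e - mu_arr) ** 2) / (2.0 * sigma**2))
        disp = config.migration_rate + (1.0 - config.migration_rate) * pool_mask[station]
        w = regional * niche * disp
        if config.abundance_noise > 0:
            w = w * np.exp(comm_rng.normal(0.0, config.abundance_noise, len(otus)))
        if w.sum() <= 0 or not np.isfinite(w.sum()):
            raise ValidationError(
                f"all-zero sampling weights for {season}|{station}; "
                "use a broader selection_strength"
            )
        counts = comm_rng.multinomial(J, w / w.sum())
        if config.size_fractions > 1:
            split = frac_rng.multinomial(counts, frac_p)
        for f_idx, frac in enumerate(fractions):
            row = counts if config.size_fractions == 1 else split[:, f_idx]
            sid = f"{season}|{station}|{d['depth']}|{frac}|r{d['replicate']}"
            counts_rows.append(pd.Series(row, index=otus, name=sid))
            meta_rows.append(dict(sample_id=sid, season=season, station=station,
                                  depth=d["depth"], size_fraction=frac,
                                  replicate=d["replicate"]))
            si = season_idx[season]
            e_rng = np.random.default_rng([7, config.seed, k, f_idx])
            noise = e_rng.normal(0.0, 0.05, 4)
            env_rows.append(dict(
                sample_id=sid,
                temperature=round(12.0 + 3.0 * e + noise[0], 4),
                NOx=round(max(0.05, 6.0 - 2.2 * si + (3.0 if at_front else 0.0) + noise[1]), 4),
                ammonium=round(max(0.02, 0.15 + 0.35 * si + noise[2]), 4),
                silicate=round(max(0.05, 2.5 - 0.8 * si + (1.2 if at_front else 0.0) + noise[3]), 4),
                PAR=round((30.0, 180.0, 120.0)[si % 3] * (1 + 0.02 * noise[0]), 4),
            ))
            truth_env.append((sid, e))

    counts = pd.DataFrame(counts_rows)
    counts.index.name = "sample_id"
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    table = OtuTable(counts, metadata, pd.Series(otus, index=otus, name="taxref"))
    env_table = pd.DataFrame(env_rows).set_index("sample_id")
    truth = SyntheticTruth(
        niche_optima=mu.rename("mu"),
        regional_log_abundance=log_ab.rename("log_abundance"),
        sample_env=pd.Series(dict(truth_env), name="env"),
        scenario=config.scenario,
    )
    return table, tree, traits, env_table, truth


# -- scenario presets ------------------------------------------------------

SCENARIOS = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


def scenario_preset(name: str, seed: int = 0, n_otus: int = 128,
                    replicates: int = 4, community_size: int = 2000) -> SyntheticConfig:
    """Single-season 5-station presets in which one assembly process dominates.

    Each preset yields 20 samples (5 stations x 4 replicates, one size
    fraction, surface only) of ``community_size`` individuals from
    ``n_otus`` OTUs — small enough for 999-replicate null models to run in
    seconds, large enough for the null calibration to hold.
    """
    base = dict(
        n_otus=n_otus, seasons=("March",), replicates=replicates,
        size_fractions=1, community_size=community_size, front_pulse=0.0,
        season_selection_scale=(1.0,), scenario=name, seed=seed,
    )
    if name == "homogeneous_selection":
        # one narrow, strongly conserved niche shared by every sample
        # (environment in the upper tail of the niche distribution, so the
        # filter passes a minority clade); bloom-like per-sample abundance
        # fluctuations then drive turnover among close relatives
        return SyntheticConfig(**base, selection_strength=0.05,
                               niche_conservatism=2.5, env_mode="quantile",
                               env_quantiles=(0.9,) * 5,
                               abundance_sigma=1.0, abundance_noise=3.0)
    if name == "variable_selection":
        # stations sit at well-separated quantiles of a conserved niche
        # axis, so different stations select different clades
        return SyntheticConfig(**base, selection_strength=0.25,
                               niche_conservatism=1.0, env_mode="quantile",
                               env_quantiles=(0.05, 0.275, 0.5, 0.725, 0.95))
    if name == "dispersal_limitation":
        return SyntheticConfig(**base, selection_strength=math.inf,
                               station_isolation=True, migration_rate=1e-4,
                               env_mode="constant")
    if name == "homogenizing_dispersal":
        # a common, strongly skewed source pool sampled at very different
        # intensities: communities are nested subsets, more similar than
        # the occupancy-weighted null expects
        return SyntheticConfig(**base, selection_strength=math.inf,
                               env_mode="constant", abundance_sigma=2.5,
                               community_size_gradient=math.log(8.0))
    if name == "drift":
        # well-mixed neutral limit: every taxon comfortably above the
        # detection threshold, so presence/absence is exchangeable and the
        # null models are calibrated
        return SyntheticConfig(**base, selection_strength=math.inf,
                               env_mode="constant", abundance_sigma=0.6)
    raise ValidationError(f"unknown scenario: {name}")


def default_survey_config(seed: int = 0) -> SyntheticConfig:
    """The default full-design survey scenario used by the pipeline.

    Moderate homogeneous selection on a seasonally shifting environment,
    tightening selection over the year (declining richness), and a frontal
    station with pulsed nutrients (relaxed selection, larger communities) —
    the qualitative structure of a tidal-front survey.
    """
    return SyntheticConfig(
        n_otus=256, community_size=2000, selection_strength=0.8,
        env_mode="seasonal", env_amplitude=0.6, env_station_spread=0.25,
        front_pulse=1.0, phototroph_fraction=0.85, trait_signal=1.0,
        scenario="default_survey", seed=seed,
    )
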