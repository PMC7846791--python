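"""End-to-end pipeline: simulate -> filter -> diversity -> assembly -> stats -> functional.

One YAML config drives a reproducible run: every stage writes its artifacts
into the run directory, a manifest records versions, seeds, parameters and
input checksums, and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    ValidationError,
    merge_samples,
    read_env_table,
    read_otu_table,
    read_trait_table,
    read_tree,
    write_otu_table,
)
from . import assembly as asm
from . import diversity as div
from . import functional as fun
from . import stats as st
from . import synthetic as syn

logger = logging.getLogger("frontassembly")

STAGES = ("simulate", "filter", "diversity", "assembly", "stats", "functional")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int = 0
    scenario: str = "default_survey"
    inputs: dict | None = None  # {otu, metadata, tree, traits, env} paths
    n_null: int = 999
    n_perm: int = 999
    m_axes: int = 4
    k_strategies: int = 9
    permanova_terms: tuple = ("NOx", "ammonium", "silicate", "PAR")
    strategy_season: str = "September"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config key(s): {sorted(bad)}")
        raw["outdir"] = Path(raw.get("outdir", "run"))
        if "permanova_terms" in raw:
            raw["permanova_terms"] = tuple(raw["permanova_terms"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.inputs:
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    raise ValidationError(f"input path for '{key}' does not exist: {p}")
        elif self.scenario != "default_survey" and self.scenario not in syn.SCENARIOS:
            raise ValidationError(f"unknown scenario: {self.scenario}")

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(ss[STAGES.index(stage)].generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Executes stages in dependency order inside one run directory."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "version": __version__,
            "seed": config.seed,
            "scenario": config.scenario,
            "parameters": {
                "n_null": config.n_null, "n_perm": config.n_perm,
                "m_axes": config.m_axes, "k_strategies": config.k_strategies,
                "permanova_terms": list(config.permanova_terms),
            },
            "stages": {},
            "inputs": {},
        }
        self._table = None
        self._filtered = None
        self._tree = None
        self._traits = None
        self._env = None
        self._assembly_obs = None

    # -- stage machinery ---------------------------------------------------
    def _record(self, stage: str, seed, outputs: list[Path], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "seed": seed,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        logger.info("stage %-10s done in %.1fs (%d artifacts)",
                    stage, time.time() - t0, len(outputs))

    def run(self, stages=STAGES) -> Path:
        for stage in stages:
            t0 = time.time()
            try:
                getattr(self, f"stage_{stage}")(t0)
            except Exception:
                self.manifest["stages"][stage] = {"failed": True}
                self._write_manifest()
                logger.error("stage %s failed; downstream stages not run", stage)
                raise
        self._write_manifest()
        return self.out

    def _write_manifest(self) -> None:
        (self.out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )

    # -- stages ------------------------------------------------------------
    def stage_simulate(self, t0: float) -> None:
        cfg = self.cfg
        if cfg.inputs:
            self._table = read_otu_table(cfg.inputs["otu"], cfg.inputs["metadata"],
                                         cfg.inputs.get("taxref"))
            self._tree = read_tree(cfg.inputs["tree"])
            self._traits = read_trait_table(cfg.inputs["traits"])
            self._env = read_env_table(cfg.inputs["env"])
            self.manifest["inputs"] = {
                k: _sha256(Path(p)) for k, p in cfg.inputs.items()
            }
            self._record("simulate", None, [], t0)
            return
        seed = cfg.stage_seed("simulate")
        if cfg.scenario == "default_survey":
            scfg = syn.default_survey_config(seed=seed)
        else:
            scfg = syn.scenario_preset(cfg.scenario, seed=seed)
        table, tree, traits, env, truth = syn.generate_metacommunity(scfg)
        self._table, self._tree, self._traits, self._env = table, tree, traits, env
        out = self.out
        write_otu_table(table, out / "otu_table.tsv", out / "sample_metadata.csv",
                        out / "taxref.csv")
        tree.write(str(out / "tree.nwk"), format="newick")
        traits.to_csv(out / "traits.csv")
        env.to_csv(out / "environment.csv", index_label="sample_id")
        truth_obj = {
            "scenario": truth.scenario,
            "niche_optima": truth.niche_optima.round(6).to_dict(),
            "regional_log_abundance": truth.regional_log_abundance.round(6).to_dict(),
            "sample_env": truth.sample_env.round(6).to_dict(),
        }
        (out / "truth.json").write_text(json.dumps(truth_obj, indent=2, sort_keys=True) + "\n")
        self._record("simulate", seed, [out / f for f in (
            "otu_table.tsv", "sample_metadata.csv", "taxref.csv", "tree.nwk",
            "traits.csv", "environment.csv", "truth.json")], t0)

    def stage_filter(self, t0: float) -> None:
        self._filtered = div.filter_phototrophs(self._table, self._traits)
        out = self.out / "phototroph_table.tsv"
        self._filtered.counts.to_csv(out, sep="\t", index_label="sample_id")
        self._record("filter", None, [out], t0)

    def stage_diversity(self, t0: float) -> None:
        cfg, out, table = self.cfg, self.out, self._filtered
        seed = cfg.stage_seed("diversity")
        rich = div.richness(table).to_frame()
        rich["chao1"] = [div.chao1(row) for _, row in table.counts.iterrows()]
        rich.to_csv(out / "richness.tsv", sep="\t", index_label="sample_id")
        merged = merge_samples(table, ["replicate", "depth", "size_fraction"])
        div.richness(merged).to_frame().to_csv(
            out / "richness_station_season.tsv", sep="\t", index_label="sample_id")
        deepest = table.counts.sum(axis=1).idxmax()
        counts = table.counts.loc[deepest]
        n = int(counts.sum())
        depths = np.unique(np.linspace(1, n, 20, dtype=int))
        div.rarefaction_curve(counts.to_numpy(), depths).to_frame().to_csv(
            out / "rarefaction_deepest.tsv", sep="\t")
        occ = div.occurrence_categories(merged)
        occ.to_csv(out / "occurrence_categories.tsv", sep="\t", index=False)
        classes = pd.concat(
            [div.abundance_classes(table, s).to_frame()
             for s in table.metadata["season"].unique()]
        )
        classes.to_csv(out / "abundance_classes.tsv", sep="\t")
        net = div.otu_connectivity(table)
        net.nodes.to_csv(out / "connectivity_nodes.tsv", sep="\t")
        net.edges.to_csv(out / "connectivity_edges.tsv", sep="\t", index=False)
        report = {}
        if table.metadata["season"].nunique() >= 2:
            _, rho = div.curated_connectivity_control(table, seed=seed)
            report["curated_spearman_rho"] = None if np.isnan(rho) else round(rho, 6)
        (out / "connectivity_control.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        self._record("diversity", seed, [out / f for f in (
            "richness.tsv", "richness_station_season.tsv", "rarefaction_deepest.tsv",
            "occurrence_categories.tsv", "abundance_classes.tsv",
            "connectivity_nodes.tsv", "connectivity_edges.tsv",
            "connectivity_control.json")], t0)

    def stage_assembly(self, t0: float) -> None:
        cfg, out = self.cfg, self.out
        seed = cfg.stage_seed("assembly")
        results = asm.infer_assembly(self._filtered, self._tree,
                                     n_null=cfg.n_null, seed=seed)
        frame = asm.results_to_frame(results)
        frame.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False,
                     float_format="%.6g")
        node_map = (self._filtered.metadata["station"].astype(str) + "|"
                    + self._filtered.metadata["season"].astype(str))
        summary = asm.process_summary(results, node_map)
        (out / "assembly_summary.json").write_text(
            json.dumps(summary.counts, indent=2, sort_keys=True) + "\n")
        summary.edges.to_csv(out / "assembly_network.tsv", sep="\t", index=False)
        obs = frame.pivot(index="sample_a", columns="sample_b", values="bmntd_obs")
        ids = self._filtered.sample_ids
        M = pd.DataFrame(0.0, index=ids, columns=ids)
        for r in results:
            M.loc[r.sample_a, r.sample_b] = M.loc[r.sample_b, r.sample_a] = r.bmntd_obs
        self._assembly_obs = M
        M.to_csv(out / "bmntd_observed.tsv", sep="\t", float_format="%.6g")
        self._record("assembly", seed, [out / f for f in (
            "assembly_pairs.tsv", "assembly_summary.json", "assembly_network.tsv",
            "bmntd_observed.tsv")], t0)

    def stage_stats(self, t0: float) -> None:
        cfg, out = self.cfg, self.out
        seed = cfg.stage_seed("stats")
        bc = st.bray_curtis(self._filtered)
        factors = [c for c in ("season", "station", "size_fraction")
                   if self._filtered.metadata[c].nunique() > 1]
        rows = []
        if factors:
            res = st.permanova(bc, self._filtered.metadata, factors,
                               n_perm=cfg.n_perm, seed=seed)
            rows.append(res.table.assign(model="bray_curtis~" + "+".join(factors)))
        env = self._env.loc[self._filtered.sample_ids]
        terms = [t for t in cfg.permanova_terms
                 if t in env.columns and env[t].nunique() > 1]
        fractions = self._filtered.metadata["size_fraction"].unique()
        for frac in fractions:
            ids = self._filtered.metadata.index[
                self._filtered.metadata["size_fraction"] == frac]
            if len(ids) < len(terms) + 3:
                continue
            D = self._assembly_obs.loc[ids, ids]
            res = st.permanova(D, env.loc[ids], terms, n_perm=cfg.n_perm, seed=seed)
            rows.append(res.table.assign(model=f"bmntd[{frac}]~" + "+".join(terms)))
        if rows:
            pd.concat(rows).to_csv(out / "permanova.tsv", sep="\t",
                                   float_format="%.6g")
        self._record("stats", seed, [out / "permanova.tsv"], t0)

    def stage_functional(self, t0: float) -> None:
        cfg, out = self.cfg, self.out
        table = self._filtered
        annotated = self._traits.loc[
            self._traits.index.intersection(table.taxref.unique())]
        otu_traits = pd.DataFrame(
            annotated.reindex(table.taxref).to_numpy(),
            index=table.otu_ids, columns=annotated.columns,
        ).dropna(how="all")
        gower = fun.gower_distance(otu_traits)
        space = fun.pcoa(gower, m=cfg.m_axes)
        space.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t",
                                 float_format="%.6g", index_label="otu_id")
        merged = merge_samples(table, ["replicate", "depth", "size_fraction"])
        pres = merged.presence()
        in_space = set(space.coordinates.index)
        presence = {
            sid: set(pres.columns[pres.loc[sid]]) & in_space
            for sid in merged.sample_ids
        }
        presence = {k: v for k, v in presence.items() if len(v) > cfg.m_axes}
        fric = fun.functional_richness(space, presence)
        fric.to_frame().to_csv(out / "functional_richness.tsv", sep="\t",
                               index_label="sample_id", float_format="%.6g")
        assign = fun.strategy_clustering(gower, k=cfg.k_strategies)
        assign.to_frame().to_csv(out / "strategies.tsv", sep="\t",
                                 index_label="otu_id")
        season = cfg.strategy_season
        if season in set(merged.metadata.get("season", pd.Series(dtype=str))):
            rows = merged.metadata.index[merged.metadata["season"] == season]
            by_station = {
                str(merged.metadata.loc[sid, "station"]):
                    set(pres.columns[pres.loc[sid]])
                for sid in rows
            }
            dist = fun.strategy_distribution(assign, by_station)
            dist.to_csv(out / f"strategy_distribution_{season}.tsv", sep="\t")
        self._record("functional", None,
                     sorted(out.glob("pcoa_*.tsv"))
                     + [out / "functional_richness.tsv", out / "strategies.tsv"], t0)


def run_pipeline(config: RunConfig, stages=STAGES) -> Path:
    """Run the pipeline and return the run directory."""
    return PipelineRun(config).run(stages)
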