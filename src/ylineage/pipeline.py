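"""Config-driven orchestration of the analysis stages.

A single YAML config describes the inputs, thresholds and stages; every
stochastic stage receives a sub-seed derived from the master seed so a
rerun with the same config is deterministic.  The run report is a plain
JSON object (stage counts and estimates only — timestamps go to the log,
never the report, so report bodies are byte-identical across reruns).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import amova as yamova
from . import assoc as yassoc
from . import dating, diversity, filtering, io, mjnet, phylo
from .simulate import (CALLABLE_LENGTH_BP, FAST_SNP_RATE, SLOW_SNP_RATE,
                       STR_RATE_PER_YEAR, MutationRateSpec, PopulationSpec,
                       generate_population_panel, write_panel)

logger = logging.getLogger("ylineage")

STAGES = ("simulate", "filter", "assign", "date", "diversity", "amova",
          "network", "assoc")


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_reads: int = Field(default=filtering.DEFAULT_MIN_READS, ge=0)
    max_missing: float = Field(default=filtering.DEFAULT_MAX_MISSING, ge=0.0, le=1.0)
    min_mean_depth: float = Field(default=filtering.DEFAULT_MIN_MEAN_DEPTH, ge=0.0)


class Rates(BaseModel):
    model_config = ConfigDict(extra="forbid")
    snp_fast: float = FAST_SNP_RATE
    snp_slow: float = SLOW_SNP_RATE
    str_rate: float = STR_RATE_PER_YEAR
    callable_length: int = CALLABLE_LENGTH_BP

    def spec(self, which: str = "fast") -> MutationRateSpec:
        rate = {"fast": self.snp_fast, "slow": self.snp_slow}[which]
        return MutationRateSpec(snp_rate=rate, callable_length=self.callable_length,
                                str_rate=self.str_rate)


class SimulatePop(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    n_samples: int = Field(ge=2)
    tmrca: float = Field(gt=0)
    longitude: float = 0.0
    topology: Literal["star", "coalescent_const", "coalescent_growth"] = "coalescent_const"
    growth_rate: float | None = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stages: list[Literal["simulate", "filter", "assign", "date", "diversity",
                         "amova", "network", "assoc"]] = Field(
        default=["filter", "assign", "date", "diversity"], min_length=1)
    seed: int | None = None
    outdir: str = "ylineage_out"
    vcf: str | None = None
    mask: str | None = None
    strs: str | None = None
    tree: str | None = None  # haplogroup definition TSV
    groups: dict[str, str] | None = None  # population -> group, for AMOVA
    thresholds: Thresholds = Thresholds()
    rates: Rates = Rates()
    epsilon: float = 0.0
    n_perm: int = Field(default=1000, ge=100)
    simulate_populations: list[SimulatePop] | None = None
    assoc_locus: str = "DYS458"
    assoc_clade: str | None = None

    @model_validator(mode="after")
    def _seed_for_stochastic_stages(self) -> "RunConfig":
        if self.seed is None and any(s in self.stages for s in ("simulate", "amova")):
            raise ValueError("seed is mandatory when stochastic stages are configured")
        return self


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected and
    every referenced input path must exist."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig.model_validate(raw)
    for name in ("vcf", "mask", "strs", "tree"):
        value = getattr(cfg, name)
        if value is not None and not Path(value).exists():
            raise FileNotFoundError(f"config field {name!r}: no such file {value}")
    return cfg


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write artifacts plus a report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seeds = dict(zip(("simulate", "amova", "pipeline"),
                     _subseeds(cfg.seed if cfg.seed is not None else 0, 3)))
    report: dict = {"config": json.loads(cfg.model_dump_json()), "stages": {}}
    vm = None
    strs = None
    current_stage = None
    try:
        for stage in cfg.stages:
            current_stage = stage
            t0 = time.perf_counter()
            if stage == "simulate":
                pops = [PopulationSpec(**p.model_dump())
                        for p in (cfg.simulate_populations or [])]
                if not pops:
                    raise ValueError("simulate stage requires simulate_populations")
                panel = generate_population_panel(
                    pops, cfg.rates.spec("fast"), seed=seeds["simulate"])
                paths = write_panel(panel, out / "panel")
                cfg.vcf = paths["variants"]
                cfg.strs = paths["strs"]
                report["stages"]["simulate"] = {
                    "n_samples": panel.variants.n_samples,
                    "n_sites": panel.variants.n_sites,
                    "true_tmrca": panel.truth["tmrca"],
                }
            elif stage == "filter":
                if cfg.vcf is None:
                    raise ValueError("filter stage requires a vcf input")
                vm, cascade = filtering.run_filter_cascade(
                    cfg.vcf, cfg.mask,
                    min_reads=cfg.thresholds.min_reads,
                    max_missing=cfg.thresholds.max_missing,
                    min_mean_depth=cfg.thresholds.min_mean_depth)
                io.write_vcf(vm, out / "filtered.vcf")
                cascade.to_frame().to_csv(out / "filter_report.tsv", sep="\t",
                                          index=False)
                report["stages"]["filter"] = {
                    "thresholds": cfg.thresholds.model_dump(),
                    "cascade": cascade.stages,
                }
            elif stage == "assign":
                vm = _require_vm(vm, cfg)
                tree = (io.read_haplogroup_defs(cfg.tree) if cfg.tree
                        else phylo.default_haplogroup_tree())
                snp_tree = phylo.build_perfect_phylogeny(vm, missing="majority")
                (out / "snp_tree.nwk").write_text(
                    snp_tree.to_newick(mutations=True, lengths=False) + "\n")
                report["stages"]["assign"] = {
                    "n_tips": snp_tree.n_leaves,
                    "hierarchy": [r[0] for r in tree.edge_rows()],
                }
            elif stage == "date":
                vm = _require_vm(vm, cfg)
                snp_tree = phylo.build_perfect_phylogeny(vm, missing="majority")
                results = {}
                for which in ("fast", "slow"):
                    est = dating.tmrca_from_rho(
                        dating.rho_snp(snp_tree), cfg.rates.spec(which), mode="snp")
                    results[f"snp_{which}"] = _est_dict(est)
                if strs is None and cfg.strs:
                    strs = io.read_str_table(cfg.strs)
                if strs is not None:
                    est = dating.tmrca_from_rho(
                        dating.rho_str(strs), cfg.rates.spec("fast"), mode="str")
                    results["str"] = _est_dict(est)
                (out / "dating.json").write_text(json.dumps(results, indent=2,
                                                            sort_keys=True))
                report["stages"]["date"] = results
            elif stage == "diversity":
                strs = _require_strs(strs, cfg)
                table = diversity.diversity_by(strs, by="population")
                table.to_csv(out / "diversity.csv")
                entry = {"per_population": json.loads(table.to_json(orient="index"))}
                if "longitude" in table.columns and table["longitude"].notna().sum() >= 4:
                    rho, p = diversity.spearman_longitude(
                        table, "mean_locus_heterozygosity")
                    entry["spearman_heterozygosity_longitude"] = {"rho": rho, "p": p}
                report["stages"]["diversity"] = entry
            elif stage == "amova":
                strs = _require_strs(strs, cfg)
                design = yamova.AmovaDesign(
                    populations=dict(zip(strs.samples, strs.populations)),
                    groups=cfg.groups)
                res = yamova.amova_with_pvalues(strs, design, n_perm=cfg.n_perm,
                                                seed=seeds["amova"])
                res.to_frame().to_csv(out / "amova.tsv", sep="\t", index=False)
                report["stages"]["amova"] = {
                    "percent_variation": res.percent_variation,
                    "phi": res.phi_statistics,
                    "p_values": res.p_values,
                    "n_permutations": res.n_permutations,
                }
            elif stage == "network":
                strs = _require_strs(strs, cfg)
                net = mjnet.median_joining(strs, epsilon=cfg.epsilon)
                mjnet.write_graphml(net, out / "network.graphml")
                report["stages"]["network"] = {
                    "n_nodes": net.number_of_nodes(),
                    "n_medians": sum(1 for _, d in net.nodes(data=True)
                                     if d["type"] == "median"),
                    "star_index": mjnet.star_index(net),
                }
            elif stage == "assoc":
                strs = _require_strs(strs, cfg)
                target = cfg.assoc_clade or str(strs.populations.iloc[0])
                splits = yassoc.allele_split(strs, list(strs.populations),
                                             cfg.assoc_locus, target)
                yassoc.allele_split_frame(splits).to_csv(
                    out / "allele_split.csv", index=False)
                report["stages"]["assoc"] = {
                    "locus": cfg.assoc_locus, "target": target,
                    "n_alleles": len(splits),
                }
            logger.info("stage %s finished in %.2fs", stage,
                        time.perf_counter() - t0)
    except Exception as exc:
        _write_report(report, out)  # keep partial outputs for debugging
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def _est_dict(est) -> dict:
    return {"rho": est.rho, "sigma_rho": est.sigma_rho, "tmrca": est.tmrca,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "n_tips": est.n_tips}


def _require_vm(vm, cfg: RunConfig):
    if vm is not None:
        return vm
    if cfg.vcf is None:
        raise ValueError("stage needs genotypes: run 'filter' first or set vcf")
    return io.read_vcf(cfg.vcf)


def _require_strs(strs, cfg: RunConfig):
    if strs is not None:
        return strs
    if cfg.strs is None:
        raise ValueError("stage needs STR haplotypes: set strs in the config")
    return io.read_str_table(cfg.strs)
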