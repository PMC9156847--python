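"""End-to-end pipeline: simulate -> call -> phase -> cluster -> stats.

The pipeline mirrors a trio-WGS DNM study on synthetic data: a cohort of
trios is simulated, high-confidence DNMs are called per trio, phased to a
parental haplotype, scanned for 20-kb clusters, and the per-child counts
are regressed on parental ages.  Everything is driven by one
:class:`PipelineConfig` and a single seed; a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cluster_finder, cohort_stats, io, origin_phaser, simkit, trio_caller
from .models import CallerConfig, PhaserConfig, RateModel, SimulationConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rate_model: RateModel = field(default_factory=RateModel)
    caller: CallerConfig = field(default_factory=CallerConfig)
    phaser: PhaserConfig = field(default_factory=PhaserConfig)
    cluster_max_gap: int = 20_000
    cluster_linkage: str = "single"
    replicate: bool = False
    seed: int = 0
    out_dir: Optional[str] = None
    log_level: str = "INFO"
    write_vcfs: bool = False


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "rate_model": RateModel,
    "caller": CallerConfig,
    "phaser": PhaserConfig,
}


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a nested dict; unknown keys rejected."""
    d = dict(d or {})
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        sub = d.pop(section, {}) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sub) - known
        if unknown:
            raise ValueError(
                f"unknown keys in config section {section!r}: "
                f"{sorted(unknown)}")
        if section == "simulation" and "genome_windows" in sub:
            sub["genome_windows"] = [tuple(w) for w in sub["genome_windows"]]
        kwargs[section] = cls(**sub)
    top_known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(d) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return PipelineConfig(**kwargs, **d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_to_dict(cfg: PipelineConfig) -> dict:
    out = {}
    for section, cls in _SECTION_TYPES.items():
        sub = dataclasses.asdict(getattr(cfg, section))
        sub.pop("father_age_sampler", None)
        sub.pop("mother_age_sampler", None)
        if "genome_windows" in sub:
            sub["genome_windows"] = [list(w) for w in sub["genome_windows"]]
        out[section] = sub
    for f in dataclasses.fields(PipelineConfig):
        if f.name not in _SECTION_TYPES:
            out[f.name] = getattr(cfg, f.name)
    return out


def dump_config(cfg: PipelineConfig, path) -> None:
    pathlib.Path(path).write_text(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-cohort analysis; returns the summary dict.

    When ``config.out_dir`` is set, calls, origin assignments, clusters
    (BED), the summary JSON and the resolved config are written there.
    Deterministic given ``config.seed``.
    """
    t0 = time.time()
    seed = int(config.seed)
    sim = dataclasses.replace(config.simulation, seed=seed)
    log.info("simulating %d trios (seed %d)", sim.n_trios, seed)
    trios = simkit.generate_cohort(sim, config.rate_model)

    margin = int(sim.insert_size_mean + 4 * sim.insert_size_sd)
    calls_by_trio, sites_by_trio, frags_by_trio = {}, {}, {}
    per_child = []
    for i, trio in enumerate(trios):
        calls = trio_caller.consensus_calls(trio.sites, config.caller)
        if config.replicate:
            rng_rep = np.random.default_rng([seed, 7001, i])
            sites2 = resample_depths(trio, sim, rng_rep)
            calls2 = trio_caller.consensus_calls(sites2, config.caller)
            calls = trio_caller.replicate_intersect(calls, calls2)
        rng_reads = np.random.default_rng([seed, 7002, i])
        regions = simkit.dnm_regions(trio, config.phaser.window, margin)
        frags = simkit.simulate_reads(trio, sim, rng_reads,
                                      individual="child", regions=regions)
        calls_by_trio[trio.trio_id] = calls
        sites_by_trio[trio.trio_id] = trio.sites
        frags_by_trio[trio.trio_id] = frags
        per_child.append({"trio": trio.trio_id,
                          "father_age": trio.father_age,
                          "mother_age": trio.mother_age,
                          "n_dnms_called": len(calls),
                          "n_dnms_true": len(trio.truth)})
    log.info("calling+read simulation done in %.1fs", time.time() - t0)

    assignments, phase_summary = origin_phaser.phase_cohort(
        calls_by_trio, sites_by_trio, frags_by_trio, config.phaser)

    all_calls = [c for t in sorted(calls_by_trio) for c in calls_by_trio[t]]
    clusters = cluster_finder.detect_clusters(
        all_calls, max_gap=config.cluster_max_gap,
        linkage=config.cluster_linkage)
    clusters = cluster_finder.annotate_same_allele(clusters, assignments)
    csum = cluster_finder.cluster_summary(clusters, len(all_calls),
                                          assignments)

    cohort = pd.DataFrame(per_child)
    regression = None
    if len(cohort) >= 4 and cohort["n_dnms_called"].sum() > 0:
        fit = cohort_stats.ols_regression(
            cohort, formula="n_dnms_called ~ father_age + mother_age")
        regression = {
            "beta_paternal": fit.params["father_age"],
            "beta_paternal_se": fit.bse["father_age"],
            "beta_maternal": fit.params["mother_age"],
            "beta_maternal_se": fit.bse["mother_age"],
            "r_squared": fit.r_squared,
            "n": fit.n,
        }

    summary = {
        "seed": seed,
        "n_trios": len(trios),
        "n_calls": len(all_calls),
        "mean_dnms_per_child": (float(cohort["n_dnms_called"].mean())
                                if len(cohort) else None),
        "per_child": per_child,
        "phasing": phase_summary,
        "clusters": csum,
        "regression": regression,
        "runtime_s": round(time.time() - t0, 2),
    }

    if config.out_dir:
        out = pathlib.Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_calls(trio_caller.calls_to_frame(all_calls),
                       out / "calls.tsv")
        adf = pd.DataFrame(
            [{"trio": a.trio, "chrom": a.chrom, "pos": a.pos,
              "verdict": a.verdict,
              "paternal_fragments": a.paternal_fragments,
              "maternal_fragments": a.maternal_fragments,
              "chain_length": a.chain_length} for a in assignments])
        adf.to_csv(out / "assignments.tsv", sep="\t", index=False)
        io.write_clusters_bed(clusters, out / "clusters.bed")
        summary_for_file = dict(summary)
        summary_for_file.pop("runtime_s")  # keep files byte-identical
        io.write_json(summary_for_file, out / "summary.json")
        dump_config(config, out / "config_resolved.yaml")
        if config.write_vcfs:
            simkit.write_cohort(trios, out / "cohort")
    return summary


def resample_depths(trio: simkit.Trio, config: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Fresh allele-depth realisation for a trio's sites (an independent
    sequencing run of the same genomes)."""
    sites = trio.sites.copy()
    for m, gcol in (("f", "gt_f"), ("m", "gt_m"), ("c", "gt_c")):
        k_alt = np.char.count(sites[gcol].to_numpy().astype(str), "1")
        ad_ref, ad_alt, dp = simkit._sample_allele_depths(
            k_alt, config.coverage, config.base_error_rate, rng)
        sites[f"ad_{m}_ref"] = ad_ref
        sites[f"ad_{m}_alt"] = ad_alt
        sites[f"dp_{m}"] = dp
    return sites
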