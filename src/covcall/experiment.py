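"""Experiment orchestration: configs, presets, manifests and headline metrics.

``run_experiment`` wires the full study together — truth simulation, per
sample pileups, full-coverage calling, benchmark construction, the DP
threshold sweep, single- and multi-sample coverage titrations, the genome
depth histogram and region-stratified calling rates — and writes every table
and VCF plus a replayable manifest.

``headline_metrics`` computes the study's headline numbers (calling-rate and
precision envelopes over coverage, sweep accuracies, multi-sample 15x
figures) directly in memory under the default simulation conditions.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calling import FilterPolicy, apply_filters, call_samples
from .config import SimConfig
from .evaluate import (
    ALL_SAMPLES,
    PER_SAMPLE,
    DepthOnlyRule,
    build_benchmark,
    calling_rate,
    depth_histogram,
    dp_sweep,
    genotype_precision,
    stratified_calling_rate,
)
from .io import (
    write_calls_vcf,
    write_depth_histogram_tsv,
    write_dp_sweep_tsv,
    write_pileups_tsv,
    write_regions_bed,
    write_stratified_tsv,
    write_titration_tsv,
    write_truth_vcf,
)
from .simulate import simulate_cohort
from .titrate import TitrationPlan, cell_seed, downsample, run_titration, titration_means

logger = logging.getLogger("covcall")


PRESETS: dict[str, dict] = {
    # small smoke configuration
    "quick": {
        "seed": 0,
        "simulation": {"n_sites": 5_000},
        "titration": {"coverages": [5, 8, 10, 15], "replicates": 2},
        "filters": {"gq_min": 20, "dp_min": 10},
        "dp_sweep": {"evaluation_coverages": [5, 10], "dp_min": 5, "dp_max": 15, "gq_fixed": 20},
        "stratify_coverages": [10, 15],
    },
    # the study's design: 5x..18x step 1, five replicates, GQ 20 / DP 10
    "paper_like": {
        "seed": 0,
        "simulation": {"n_sites": 50_000},
        "titration": {"coverages": list(range(5, 19)), "replicates": 5},
        "filters": {"gq_min": 20, "dp_min": 10},
        "dp_sweep": {"evaluation_coverages": [5, 10], "dp_min": 5, "dp_max": 15, "gq_fixed": 20},
        "stratify_coverages": [10, 15],
    },
    # deep-source titration from a ~104x dataset, targets 5x..20x
    "deep_source": {
        "seed": 0,
        "simulation": {"n_sites": 50_000, "source_coverage": 104.0},
        "titration": {"coverages": list(range(5, 21)), "replicates": 5},
        "filters": {"gq_min": 20, "dp_min": 10},
        "dp_sweep": {"evaluation_coverages": [5, 10], "dp_min": 5, "dp_max": 15, "gq_fixed": 20},
        "stratify_coverages": [10, 15],
    },
}


def load_config(source) -> dict:
    """A config dict from a preset name, YAML path, or mapping."""
    if isinstance(source, dict):
        return dict(source)
    if isinstance(source, (str, Path)):
        if str(source) in PRESETS:
            return json.loads(json.dumps(PRESETS[str(source)]))
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ValueError("config: document must be a mapping")
        return cfg
    raise ValueError(f"config: cannot interpret {source!r}")


def _parse_config(cfg: dict, seed_override: int | None):
    seed = int(cfg.get("seed", 0) if seed_override is None else seed_override)
    sim = SimConfig(seed=seed, **cfg.get("simulation", {}))
    tit_cfg = dict(cfg.get("titration", {}))
    plan = TitrationPlan(
        coverages=tuple(tit_cfg.get("coverages", tuple(range(5, 19)))),
        replicates=int(tit_cfg.get("replicates", 5)),
        mode=tit_cfg.get("mode", "exact_without_replacement"),
        seed=seed,
    )
    policy = FilterPolicy(**cfg.get("filters", {"gq_min": 20, "dp_min": 10}))
    sw = cfg.get("dp_sweep", {})
    sweep_cfg = {
        "evaluation_coverages": tuple(sw.get("evaluation_coverages", (5, 10))),
        "dp_range": tuple(range(int(sw.get("dp_min", 5)), int(sw.get("dp_max", 15)) + 1)),
        "gq_fixed": int(sw.get("gq_fixed", 20)),
    }
    strat = tuple(cfg.get("stratify_coverages", (10, 15)))
    return seed, sim, plan, policy, sweep_cfg, strat


@dataclass
class RunManifest:
    """Everything needed to replay a run byte-for-byte."""

    version: str
    config: dict
    seed: int
    seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)
    failed_stage: str | None = None
    elapsed_seconds: float | None = None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_experiment(config, outdir: str | Path, seed: int | None = None) -> RunManifest:
    """Execute the full experiment and write its output tree.

    Any stage failure aborts with the stage name and cause; the manifest is
    still written with the partial outputs flagged.
    """
    t0 = time.time()
    cfg = load_config(config)
    seed, sim, plan, policy, sweep_cfg, strat_covs = _parse_config(cfg, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(version=__version__, config=cfg, seed=seed,
                           seeds={"simulation": sim.seed, "titration": plan.seed})
    logger.info("[config] covcall %s seed=%d n_sites=%d source=%.1fx model=%s "
                "coverages=%s replicates=%d filters GQ>=%d DP>=%d",
                __version__, seed, sim.n_sites, sim.source_coverage,
                sim.depth_model.name, list(plan.coverages), plan.replicates,
                policy.gq_min, policy.dp_min)

    def run_stage(name, fn):
        try:
            logger.info("[%s] start", name)
            out = fn()
            manifest.completed_stages.append(name)
            return out
        except Exception as exc:
            manifest.failed_stage = name
            manifest.write(outdir / "manifest.json")
            logger.error("[%s] FAILED: %s (partial outputs flagged in manifest)", name, exc)
            raise StageError(name, exc) from exc

    def _sim():
        truth, samples = simulate_cohort(sim)
        write_truth_vcf(truth, outdir / "truth.vcf")
        write_regions_bed(truth.region_map, outdir / "regions.bed", truth.chrom)
        for s in samples:
            write_pileups_tsv(s, outdir / f"pileups_{s.sample_id}.tsv")
        hists = {s.sample_id: depth_histogram(s) for s in samples}
        write_depth_histogram_tsv(hists, outdir / "depth_histogram.tsv")
        return truth, samples

    truth, samples = run_stage("simulate", _sim)

    def _call():
        single = call_samples(samples, "single")
        multi = call_samples(samples, "multi")
        write_calls_vcf(truth, single, outdir / "calls_single_full.vcf")
        write_calls_vcf(truth, multi, outdir / "calls_multi_full.vcf")
        return single, multi

    full_single, full_multi = run_stage("call_full", _call)

    def _bench():
        b_single = build_benchmark(full_single, policy, PER_SAMPLE)
        b_multi = build_benchmark(full_multi, policy, ALL_SAMPLES)
        b_depth = build_benchmark(
            full_single, DepthOnlyRule(dp_gt=20, gq_min=policy.gq_min), PER_SAMPLE
        )
        return b_single, b_multi, b_depth

    bench_single, bench_multi, bench_depth = run_stage("benchmark", _bench)

    def _sweep():
        pts = dp_sweep(samples, bench_depth, sweep_cfg["evaluation_coverages"],
                       sweep_cfg["dp_range"], sweep_cfg["gq_fixed"],
                       mode=plan.mode, seed=seed)
        write_dp_sweep_tsv(pts, outdir / "dp_sweep.tsv")

    run_stage("dp_sweep", _sweep)

    def _titrate(pipeline, bench):
        def inner():
            pts = run_titration(samples, plan, pipeline, policy, bench)
            write_titration_tsv(pts, outdir / f"titration_{pipeline}.tsv")
            titration_means(pts).to_csv(
                outdir / f"titration_{pipeline}_means.tsv", sep="\t", index=False
            )
        return inner

    run_stage("titrate_single", _titrate("single", bench_single))
    run_stage("titrate_multi", _titrate("multi", bench_multi))

    def _strat():
        rows = []
        for pipeline, bench in (("single", bench_single), ("multi", bench_multi)):
            for cov in strat_covs:
                if cov not in plan.coverages:
                    continue
                ci = plan.coverages.index(cov)
                downs = [downsample(s, cov, plan.mode, cell_seed(plan, ci, 0, si))
                         for si, s in enumerate(samples)]
                calls = apply_filters(call_samples(downs, pipeline), policy)
                for region, rate in stratified_calling_rate(bench, calls, truth).items():
                    rows.append((pipeline, cov, region, rate))
        write_stratified_tsv(rows, outdir / "stratified_calling_rate.tsv")

    run_stage("stratify", _strat)

    manifest.artifacts = {
        p.name: str(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.json"
    }
    manifest.elapsed_seconds = round(time.time() - t0, 2)
    manifest.write(outdir / "manifest.json")
    logger.info("[done] %d stages in %.1fs -> %s",
                len(manifest.completed_stages), manifest.elapsed_seconds, outdir)
    return manifest


# ---------------------------------------------------------------------------
# headline metrics (in-memory, shared by the test suite and acceptance script)
# ---------------------------------------------------------------------------

def headline_metrics(seed: int, n_sites: int = 50_000, replicates: int = 5) -> dict:
    """The study's headline numbers under the default simulation.

    Conditions: 3 diploid samples, Poisson 20x source depth, Q20 errors,
    1.3% polymorphism, 60% heterozygous SNPs, GQ >= 20 / DP >= 10 filters,
    downsampling without replacement with the given replicate count.

    Returns percentages: single-sample calling rate at 5/10/15x and
    precision at 8x, DP-sweep accuracy at thresholds 5 and 11 (evaluated at
    10x), and multi-sample calling rate / accuracy at 15x.
    """
    sim = SimConfig(n_sites=n_sites, seed=int(seed))
    policy = FilterPolicy(gq_min=20, dp_min=10)
    truth, samples = simulate_cohort(sim, with_depth_track=False)

    full_single = call_samples(samples, "single")
    full_multi = call_samples(samples, "multi")
    bench_single = build_benchmark(full_single, policy, PER_SAMPLE)
    bench_multi = build_benchmark(full_multi, policy, ALL_SAMPLES)
    bench_depth = build_benchmark(full_single, DepthOnlyRule(dp_gt=20, gq_min=20), PER_SAMPLE)

    plan_single = TitrationPlan(coverages=(5, 8, 10, 15), replicates=replicates, seed=int(seed))
    pts_single = run_titration(samples, plan_single, "single", policy, bench_single)
    means_s = titration_means(pts_single).set_index("coverage")

    plan_multi = TitrationPlan(coverages=(15,), replicates=replicates, seed=int(seed))
    pts_multi = run_titration(samples, plan_multi, "multi", policy, bench_multi)
    means_m = titration_means(pts_multi).set_index("coverage")

    sweep = dp_sweep(samples, bench_depth, evaluation_coverages=(10,),
                     dp_range=(5, 11), gq_fixed=20, seed=int(seed))
    acc = {p.dp_threshold: p.accuracy for p in sweep}

    return {
        "n_sites": n_sites,
        "single_calling_rate_5x": 100.0 * means_s.loc[5, "calling_rate"],
        "single_calling_rate_8x": 100.0 * means_s.loc[8, "calling_rate"],
        "single_calling_rate_10x": 100.0 * means_s.loc[10, "calling_rate"],
        "single_calling_rate_15x": 100.0 * means_s.loc[15, "calling_rate"],
        "single_precision_8x": 100.0 * means_s.loc[8, "precision"],
        "dp_sweep_accuracy_dp5_10x": 100.0 * acc[5],
        "dp_sweep_accuracy_dp11_10x": 100.0 * acc[11],
        "multi_calling_rate_15x": 100.0 * means_m.loc[15, "calling_rate"],
        "multi_precision_15x": 100.0 * means_m.loc[15, "precision"],
    }


def setup_logging(verbose: bool = True) -> None:
    """Stage-tagged logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s", "%H:%M:%S"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
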