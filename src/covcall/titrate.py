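"""Coverage titration: downsample pileups to a grid of target depths.

Downsampling emulates sequencing less deeply by discarding mapped reads from
the full-coverage data. The retained fraction ``f`` is computed against the
sample's realised (not configured) mean coverage. Two modes:

``exact_without_replacement``
    Retain exactly ``round(f * N)`` of the N observations, chosen uniformly
    without replacement; per-site retained depths are then multivariate
    hypergeometric. This is the default.
``binomial_thinning``
    Keep each observation independently with probability ``f``; with a
    Poisson source depth the retained depth is exactly Poisson(f * mean)
    (thinning theorem), which makes this mode analytically checkable.

Replicate cells of the titration grid draw their seeds from the plan seed by
a counter scheme ``(plan.seed, coverage_index, replicate, sample_index)`` so
any single cell is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calling import CallSet, FilterPolicy, apply_filters, call_samples
from .simulate import SampleData

logger = logging.getLogger("covcall")

MODES = ("exact_without_replacement", "binomial_thinning")


@dataclass(frozen=True)
class TitrationPlan:
    """Coverage grid (default 5x..18x, step 1), replicates (default 5), mode."""

    coverages: tuple[float, ...] = tuple(range(5, 19))
    replicates: int = 5
    mode: str = "exact_without_replacement"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates: must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode: must be one of {MODES}")
        if any(c <= 0 for c in self.coverages):
            raise ValueError("coverages: must be > 0")


@dataclass(frozen=True)
class TitrationPoint:
    """One cell of the coverage-accuracy curve."""

    coverage: float
    replicate: int
    pipeline: str
    calling_rate: float
    precision: float | None   # None when no passing call overlaps the benchmark


def downsample(
    data: SampleData,
    target_coverage: float,
    mode: str = "exact_without_replacement",
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> SampleData:
    """Reduce one sample to a target mean coverage.

    Bases and qualities are untouched; only the set of retained observations
    changes. The depth track, if present, is binomially thinned by the same
    fraction. ``f == 1`` returns an identity copy.
    """
    if mode not in MODES:
        raise ValueError(f"mode: must be one of {MODES}")
    realised = data.mean_coverage()
    if target_coverage > realised * (1 + 1e-9):
        raise ValueError(
            f"target_coverage: {target_coverage} exceeds realised mean coverage {realised:.3f}"
        )
    f = target_coverage / realised
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if f >= 1.0 - 1e-12:
        return SampleData(
            sample_id=data.sample_id,
            truth=data.truth,
            site_index=data.site_index.copy(),
            bases=data.bases.copy(),
            quals=data.quals.copy(),
            depth_track=None if data.depth_track is None else data.depth_track.copy(),
        )

    n = data.n_observations
    if mode == "exact_without_replacement":
        k = int(round(f * n))
        keep = rng.choice(n, size=k, replace=False)
        keep.sort()
    else:
        keep = np.flatnonzero(rng.random(n) < f)

    track = None
    if data.depth_track is not None:
        track = rng.binomial(data.depth_track, f).astype(np.int32)

    return SampleData(
        sample_id=data.sample_id,
        truth=data.truth,
        site_index=data.site_index[keep],
        bases=data.bases[keep],
        quals=data.quals[keep],
        depth_track=track,
    )


def cell_seed(plan: TitrationPlan, coverage_index: int, replicate: int, sample_index: int) -> np.random.SeedSequence:
    """Counter-based seed for one (coverage, replicate, sample) cell."""
    return np.random.SeedSequence((plan.seed, coverage_index, replicate, sample_index))


def run_titration(
    samples: Sequence[SampleData],
    plan: TitrationPlan,
    pipeline: str,
    policy: FilterPolicy,
    benchmark,
) -> list[TitrationPoint]:
    """Score calling rate and precision over the coverage x replicate grid.

    For each cell: every sample is downsampled to the target coverage,
    genotypes are re-called with the chosen pipeline (``"single"`` or
    ``"multi"``), the GQ/DP policy is applied, and the filtered calls are
    scored against the benchmark built from the full-coverage data.
    """
    from .evaluate import calling_rate, genotype_precision  # local to avoid cycle

    if benchmark is None or benchmark.entries.sum() == 0:
        raise ValueError("benchmark: must be non-empty")
    realised = [s.mean_coverage() for s in samples]
    for cov in plan.coverages:
        for sm, r in zip(samples, realised):
            if cov > r * (1 + 1e-9):
                raise ValueError(
                    f"coverages: target {cov} exceeds realised coverage "
                    f"{r:.3f} of sample {sm.sample_id}"
                )

    points: list[TitrationPoint] = []
    for ci, cov in enumerate(plan.coverages):
        for rep in range(plan.replicates):
            downs = [
                downsample(s, cov, plan.mode, cell_seed(plan, ci, rep, si))
                for si, s in enumerate(samples)
            ]
            calls = apply_filters(call_samples(downs, pipeline), policy)
            cr = calling_rate(benchmark, calls)
            prec = genotype_precision(benchmark, calls)
            points.append(TitrationPoint(cov, rep, pipeline, cr, prec))
        logger.info(
            "[titrate] %s pipeline coverage %gx: mean calling rate %.4f",
            pipeline, cov, float(np.mean([p.calling_rate for p in points[-plan.replicates:]])),
        )
    return points


def titration_means(points: Sequence[TitrationPoint]):
    """Across-replicate mean calling rate and precision per coverage (DataFrame)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "coverage": [p.coverage for p in points],
            "replicate": [p.replicate for p in points],
            "pipeline": [p.pipeline for p in points],
            "calling_rate": [p.calling_rate for p in points],
            "precision": [np.nan if p.precision is None else p.precision for p in points],
        }
    )
    return (
        df.groupby(["pipeline", "coverage"], as_index=False)
        .agg(calling_rate=("calling_rate", "mean"), precision=("precision", "mean"))
    )
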