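"""Benchmark construction and the coverage-study metrics.

The benchmark stands in for truth: genotypes confidently called from the
full-coverage data (GQ >= 20 and DP >= 10, or a depth-only "more than 20
reads" rule). Reduced-coverage call sets are then scored by

calling rate
    fraction of benchmark entries (or, for the all-samples scope, benchmark
    sites) that receive a passing call, and
precision
    fraction of passing calls whose genotype matches the benchmark genotype.

Non-calls are charged to the calling rate only, never to precision; zero
overlap between passing calls and the benchmark is a distinct undefined
state (``None``/NaN), never silently 0 or 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calling import CallSet, FilterPolicy, NO_CALL
from .simulate import REGION_CLASSES, SampleData, TruthPanel

logger = logging.getLogger("covcall")

PER_SAMPLE = "per_sample"
ALL_SAMPLES = "all_samples_required"
SCOPES = (PER_SAMPLE, ALL_SAMPLES)


class BenchmarkError(ValueError):
    """Raised when admission rules leave an unusable (empty) benchmark."""


@dataclass(frozen=True)
class DepthOnlyRule:
    """Admission by depth: DP strictly greater than ``dp_gt`` (GQ fixed).

    Matches the sweep benchmark: sites with more than 20 reads in the full
    data, genotypes taken from full-coverage calls at GQ >= ``gq_min``.
    """

    dp_gt: int = 20
    gq_min: int = 20


@dataclass
class BenchmarkSet:
    """High-confidence genotypes from full-coverage calls.

    ``entries`` is a (n_samples, n_sites) mask of admitted (site, sample)
    cells; ``gt`` holds the benchmark genotype codes wherever admitted.
    """

    sample_ids: tuple[str, ...]
    entries: np.ndarray          # bool (n_samples, n_sites)
    gt: np.ndarray               # int8 (n_samples, n_sites)
    criteria: FilterPolicy | DepthOnlyRule
    scope: str

    @property
    def n_entries(self) -> int:
        return int(self.entries.sum())

    @property
    def site_mask(self) -> np.ndarray:
        """Sites admitted in every sample (the all-samples benchmark sites)."""
        return self.entries.all(axis=0)


def build_benchmark(
    full_calls: CallSet,
    criteria: FilterPolicy | DepthOnlyRule = FilterPolicy(),
    scope: str = PER_SAMPLE,
) -> BenchmarkSet:
    """Admit confidently-called genotypes from full-coverage calls.

    ``scope=all_samples_required`` additionally drops any site lacking an
    admitted genotype in some sample (the multi-sample benchmark rule).
    """
    if scope not in SCOPES:
        raise ValueError(f"scope: must be one of {SCOPES}")
    called = full_calls.gt != NO_CALL
    if isinstance(criteria, DepthOnlyRule):
        mask = called & (full_calls.dp > criteria.dp_gt) & (full_calls.gq >= criteria.gq_min)
    else:
        mask = called & (full_calls.gq >= criteria.gq_min) & (full_calls.dp >= criteria.dp_min)
    if scope == ALL_SAMPLES:
        mask = mask & mask.all(axis=0)[None, :]
    if not mask.any():
        raise BenchmarkError("benchmark empty: no call satisfies the admission criteria")
    return BenchmarkSet(
        sample_ids=full_calls.sample_ids,
        entries=mask,
        gt=full_calls.gt.copy(),
        criteria=criteria,
        scope=scope,
    )


def _check_filtered(calls: CallSet) -> np.ndarray:
    if calls.passed is None:
        raise ValueError("filtered_calls: apply_filters must be run first")
    return calls.passed


def calling_rate(benchmark: BenchmarkSet, filtered_calls: CallSet) -> float:
    """Fraction of the benchmark recovered by passing calls.

    Per-sample scope counts (site, sample) entries; all-samples scope counts
    benchmark sites with a passing call in every sample.
    """
    passed = _check_filtered(filtered_calls)
    if benchmark.n_entries == 0:
        raise BenchmarkError("benchmark empty")
    if benchmark.scope == ALL_SAMPLES:
        sites = benchmark.site_mask
        return float(passed[:, sites].all(axis=0).mean())
    return float((benchmark.entries & passed).sum() / benchmark.n_entries)


def genotype_precision(benchmark: BenchmarkSet, filtered_calls: CallSet) -> float | None:
    """Concordance among benchmark entries that received a passing call.

    Entries without a passing call are excluded (they lower the calling rate
    instead). Returns ``None`` when no passing call overlaps the benchmark.
    """
    passed = _check_filtered(filtered_calls)
    overlap = benchmark.entries & passed
    n = int(overlap.sum())
    if n == 0:
        return None
    return float((filtered_calls.gt[overlap] == benchmark.gt[overlap]).mean())


# ---------------------------------------------------------------------------
# DP-threshold sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DPSweepPoint:
    evaluation_coverage: float
    dp_threshold: int
    accuracy: float | None       # None when nothing is evaluated
    n_evaluated: int


def dp_sweep(
    samples: Sequence[SampleData],
    benchmark: BenchmarkSet,
    evaluation_coverages: Sequence[float] = (5.0, 10.0),
    dp_range: Sequence[int] = tuple(range(5, 16)),
    gq_fixed: int = 20,
    mode: str = "exact_without_replacement",
    seed: int = 0,
) -> list[DPSweepPoint]:
    """Genotype accuracy as a function of the DP threshold at fixed GQ.

    Each evaluation coverage is downsampled once (seeded), called with the
    single-sample pipeline, and scored against the depth-only benchmark for
    every DP threshold in ``dp_range``.
    """
    from .calling import apply_filters, call_samples
    from .titrate import downsample

    points: list[DPSweepPoint] = []
    for ci, cov in enumerate(evaluation_coverages):
        downs = [
            downsample(s, cov, mode, np.random.SeedSequence((seed, ci, si)))
            for si, s in enumerate(samples)
        ]
        calls = call_samples(downs, "single")
        for dp_min in dp_range:
            filtered = apply_filters(calls, FilterPolicy(gq_min=gq_fixed, dp_min=dp_min))
            overlap = benchmark.entries & filtered.passed
            n = int(overlap.sum())
            acc = None if n == 0 else float((filtered.gt[overlap] == benchmark.gt[overlap]).mean())
            points.append(DPSweepPoint(cov, int(dp_min), acc, n))
    return points


# ---------------------------------------------------------------------------
# depth histogram and region stratification
# ---------------------------------------------------------------------------

DEPTH_BIN_LABELS = ("0", "1-9", "10-100", ">100")


@dataclass(frozen=True)
class DepthHistogram:
    """Genome fraction in depth bins {0}, {1..9}, {10..100}, {>100}."""

    fractions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions: must sum to 1 (tolerance 1e-9)")


def depth_histogram(data: SampleData) -> DepthHistogram:
    track = data.depth_track
    if track is None or track.size == 0:
        raise ValueError("depth_track: must be non-empty")
    bins = np.array([0, 1, 10, 101], dtype=np.int64)
    idx = np.searchsorted(bins, track, side="right") - 1
    counts = np.bincount(idx, minlength=4)
    return DepthHistogram(fractions=tuple((counts / track.size).tolist()))


def stratified_calling_rate(
    benchmark: BenchmarkSet,
    filtered_calls: CallSet,
    truth: TruthPanel,
) -> dict[str, float]:
    """Calling rate within each region class; empty classes are omitted."""
    passed = _check_filtered(filtered_calls)
    out: dict[str, float] = {}
    for code, name in enumerate(REGION_CLASSES):
        sites = truth.region == code
        entries = benchmark.entries[:, sites]
        if entries.sum() == 0:
            logger.info("[evaluate] region class %r has no benchmark sites; omitted", name)
            continue
        if benchmark.scope == ALL_SAMPLES:
            bench_sites = benchmark.site_mask & sites
            if not bench_sites.any():
                logger.info("[evaluate] region class %r has no benchmark sites; omitted", name)
                continue
            out[name] = float(passed[:, bench_sites].all(axis=0).mean())
        else:
            out[name] = float((entries & passed[:, sites]).sum() / entries.sum())
    return out
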