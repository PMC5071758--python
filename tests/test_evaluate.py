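"""Benchmark admission, calling rate, precision, sweep, histogram, regions."""

import numpy as np
import pytest

from covcall import (
    FilterPolicy,
    DepthOnlyRule,
    SimConfig,
    apply_filters,
    build_benchmark,
    build_truth,
    call_samples,
    calling_rate,
    depth_histogram,
    dp_sweep,
    genotype_precision,
    simulate_cohort,
    simulate_sample,
    stratified_calling_rate,
)
from covcall.calling import CallSet
from covcall.evaluate import ALL_SAMPLES, PER_SAMPLE, BenchmarkError
from covcall.simulate import SampleData
from covcall.titrate import downsample


def make_callset(gt, dp, gq, passed=None, pipeline="single"):
    gt = np.asarray(gt, dtype=np.int8)
    out = CallSet(
        sample_ids=tuple(f"S{i+1}" for i in range(gt.shape[0])),
        gt=gt,
        dp=np.asarray(dp, dtype=np.int64),
        gq=np.asarray(gq, dtype=np.int16),
        pl=np.zeros((*gt.shape, 3), dtype=np.int64),
        pipeline=pipeline,
        passed=None if passed is None else np.asarray(passed, dtype=bool),
    )
    return out


class TestBuildBenchmark:
    def test_all_passing_keeps_every_site(self):
        calls = make_callset([[0, 1, 2]], [[20, 20, 20]], [[99, 99, 99]])
        bench = build_benchmark(calls, FilterPolicy(), PER_SAMPLE)
        assert bench.n_entries == 3

    def test_scope_semantics(self):
        # sample 2 fails at site 0: per-sample keeps it for sample 1,
        # all-samples drops the site entirely
        gt = [[1, 1], [1, 1]]
        dp = [[20, 20], [5, 20]]
        gq = [[99, 99], [99, 99]]
        per = build_benchmark(make_callset(gt, dp, gq), FilterPolicy(), PER_SAMPLE)
        alls = build_benchmark(make_callset(gt, dp, gq), FilterPolicy(), ALL_SAMPLES)
        assert per.entries.tolist() == [[True, True], [False, True]]
        assert alls.entries.tolist() == [[False, True], [False, True]]
        assert alls.site_mask.tolist() == [False, True]

    def test_depth_only_rule_is_strictly_greater(self):
        calls = make_callset([[1, 1]], [[20, 21]], [[99, 99]])
        bench = build_benchmark(calls, DepthOnlyRule(dp_gt=20, gq_min=20), PER_SAMPLE)
        assert bench.entries.tolist() == [[False, True]]

    def test_empty_benchmark_raises(self):
        calls = make_callset([[1]], [[3]], [[5]])
        with pytest.raises(BenchmarkError):
            build_benchmark(calls, FilterPolicy(), PER_SAMPLE)


class TestMetrics:
    def _bench(self):
        gt = [[1, 0, 2, 1]]
        dp = [[20] * 4]
        gq = [[99] * 4]
        return build_benchmark(make_callset(gt, dp, gq), FilterPolicy(), PER_SAMPLE)

    def test_calling_rate_hand_count(self):
        bench = self._bench()
        calls = make_callset([[1, 0, 2, 1]], [[20] * 4], [[99] * 4],
                             passed=[[True, True, False, False]])
        assert calling_rate(bench, calls) == 0.5

    def test_identical_calls_rate_one(self):
        bench = self._bench()
        calls = make_callset([[1, 0, 2, 1]], [[20] * 4], [[99] * 4],
                             passed=[[True] * 4])
        assert calling_rate(bench, calls) == 1.0
        assert genotype_precision(bench, calls) == 1.0

    def test_no_passing_calls(self):
        bench = self._bench()
        calls = make_callset([[1, 0, 2, 1]], [[20] * 4], [[99] * 4],
                             passed=[[False] * 4])
        assert calling_rate(bench, calls) == 0.0
        assert genotype_precision(bench, calls) is None  # undefined, not 0

    def test_precision_hand_count(self):
        bench = self._bench()
        calls = make_callset([[1, 2, 2, 1]], [[20] * 4], [[99] * 4],
                             passed=[[True, True, True, False]])
        assert genotype_precision(bench, calls) == pytest.approx(2.0 / 3.0)

    def test_unfiltered_calls_rejected(self):
        bench = self._bench()
        calls = make_callset([[1, 0, 2, 1]], [[20] * 4], [[99] * 4])
        with pytest.raises(ValueError, match="apply_filters"):
            calling_rate(bench, calls)

    def test_metrics_invariant_under_site_reordering(self, small_cohort):
        _, _, samples = small_cohort
        policy = FilterPolicy()
        full = call_samples(samples, "single")
        bench = build_benchmark(full, policy, PER_SAMPLE)
        calls = apply_filters(call_samples(
            [downsample(s, 10.0, seed=i) for i, s in enumerate(samples)], "single"), policy)
        rate, prec = calling_rate(bench, calls), genotype_precision(bench, calls)
        perm = np.random.default_rng(0).permutation(calls.n_sites)
        bench.entries, bench.gt = bench.entries[:, perm], bench.gt[:, perm]
        shuffled = CallSet(calls.sample_ids, calls.gt[:, perm], calls.dp[:, perm],
                           calls.gq[:, perm], calls.pl[:, perm], calls.pipeline,
                           passed=calls.passed[:, perm])
        assert calling_rate(bench, shuffled) == rate
        assert genotype_precision(bench, shuffled) == prec

    def test_benchmark_self_precision_is_exactly_one(self, small_cohort):
        _, _, samples = small_cohort
        policy = FilterPolicy()
        full = apply_filters(call_samples(samples, "single"), policy)
        bench = build_benchmark(full, policy, PER_SAMPLE)
        assert genotype_precision(bench, full) == 1.0
        assert calling_rate(bench, full) == 1.0


class TestDPSweep:
    def test_threshold_above_max_depth_is_undefined(self, small_cohort):
        _, _, samples = small_cohort
        bench = build_benchmark(call_samples(samples, "single"),
                                DepthOnlyRule(20, 20), PER_SAMPLE)
        pts = dp_sweep(samples, bench, evaluation_coverages=(5.0,),
                       dp_range=(500,), seed=0)
        assert pts[0].n_evaluated == 0 and pts[0].accuracy is None

    def test_noiseless_discordance_only_from_one_allele_pileups(self, noiseless_cohort):
        # error-free reads: the only possible miscall is a het site whose
        # downsampled pileup happens to contain a single allele
        _, _, samples = noiseless_cohort
        policy = FilterPolicy(gq_min=20, dp_min=5)
        bench = build_benchmark(call_samples(samples, "single"),
                                DepthOnlyRule(20, 20), PER_SAMPLE)
        down = downsample(samples[0], 10.0, seed=1)
        calls = apply_filters(call_samples([down], "single"), policy)
        overlap = bench.entries & calls.passed
        discordant = overlap & (calls.gt != bench.gt)
        for i in np.flatnonzero(discordant[0]):
            observed = {b for b, _ in down.pileup(int(i)).observations}
            assert len(observed) == 1
        acc = genotype_precision(bench, calls)
        assert acc is not None and acc > 0.99

    def test_accuracy_does_not_degrade_with_stricter_depth(self, small_cohort):
        _, _, samples = small_cohort
        bench = build_benchmark(call_samples(samples, "single"),
                                DepthOnlyRule(20, 20), PER_SAMPLE)
        pts = dp_sweep(samples, bench, evaluation_coverages=(10.0,),
                       dp_range=(5, 10), seed=2)
        acc = {p.dp_threshold: p.accuracy for p in pts}
        assert acc[10] >= acc[5] - 0.005


class TestDepthHistogram:
    def _sample_with_track(self, track):
        cfg = SimConfig(n_sites=10, genome_length=1000, seed=0, n_samples=1)
        truth = build_truth(cfg)
        s = simulate_sample(truth, cfg, "S1", seed=0, with_depth_track=False)
        s.depth_track = np.asarray(track, dtype=np.int32)
        return s

    def test_all_zero_track(self):
        h = depth_histogram(self._sample_with_track([0] * 100))
        assert h.fractions == (1.0, 0.0, 0.0, 0.0)

    def test_hand_binned_track(self):
        h = depth_histogram(self._sample_with_track([0, 5, 10, 101]))
        assert h.fractions == (0.25, 0.25, 0.25, 0.25)

    def test_bin_edges(self):
        h = depth_histogram(self._sample_with_track([1, 9, 10, 100, 101, 0]))
        assert h.fractions == pytest.approx((1 / 6, 2 / 6, 2 / 6, 1 / 6))

    def test_zero_inflated_preset_puts_fifth_of_genome_at_zero(self):
        cfg = SimConfig(n_sites=1_000, genome_length=200_000, n_samples=1,
                        depth_model={"name": "mixture", "zero_fraction": 0.20}, seed=29)
        truth = build_truth(cfg)
        s = simulate_sample(truth, cfg, "S1", seed=29)
        h = depth_histogram(s)
        assert h.fractions[0] == pytest.approx(0.20, abs=0.01)
        assert sum(h.fractions) == pytest.approx(1.0, abs=1e-12)


class TestStratifiedCallingRate:
    def test_single_class_genome_equals_global_rate(self):
        cfg = SimConfig(n_sites=3_000, n_samples=1, seed=37,
                        region_fractions={"coding": 1.0, "intron": 0.0, "intergenic": 0.0})
        truth, samples = simulate_cohort(cfg, with_depth_track=False)
        policy = FilterPolicy()
        bench = build_benchmark(call_samples(samples, "single"), policy, PER_SAMPLE)
        calls = apply_filters(call_samples(
            [downsample(samples[0], 10.0, seed=0)], "single"), policy)
        rates = stratified_calling_rate(bench, calls, truth)
        assert set(rates) == {"coding"}
        assert rates["coding"] == pytest.approx(calling_rate(bench, calls))

    def test_retention_gradient_orders_region_rates(self):
        retention = {"coding": 1.0, "intron": 0.8, "intergenic": 0.55}
        cfg = SimConfig(n_sites=30_000, n_samples=1, seed=41,
                        region_retention=retention)
        truth, samples = simulate_cohort(cfg, with_depth_track=False)
        policy = FilterPolicy()
        bench = build_benchmark(call_samples(samples, "single"), policy, PER_SAMPLE)
        calls = apply_filters(call_samples(
            [downsample(samples[0], 12.0, seed=1)], "single"), policy)
        rates = stratified_calling_rate(bench, calls, truth)
        assert rates["coding"] > rates["intron"] > rates["intergenic"]

    def test_uniform_retention_gives_exchangeable_rates(self, small_cohort):
        _, truth, samples = small_cohort
        policy = FilterPolicy()
        bench = build_benchmark(call_samples(samples, "single"), policy, PER_SAMPLE)
        calls = apply_filters(call_samples(
            [downsample(s, 12.0, seed=i) for i, s in enumerate(samples)], "single"), policy)
        rates = stratified_calling_rate(bench, calls, truth)
        assert max(rates.values()) - min(rates.values()) < 0.06
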