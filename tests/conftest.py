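"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from covcall import SimConfig, simulate_cohort
from covcall.simulate import BASES, PileupColumn, TruthSite


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_pl(bases, quals, ref, alt):
    """Per-read product likelihood over the three diploid genotypes.

    Enumerates each genotype as an unordered allele pair and multiplies the
    per-read base probabilities directly; independent of the package's
    vectorised log-space engine.
    """
    genotypes = [(ref, ref), (ref, alt), (alt, alt)]
    lik = []
    for a1, a2 in genotypes:
        p = 1.0
        for b, q in zip(bases, quals):
            e = 10.0 ** (-q / 10.0)

            def pb(a):
                return 1.0 - e if b == a else e / 3.0

            p *= 0.5 * pb(a1) + 0.5 * pb(a2)
        lik.append(p)
    best = max(lik)
    return tuple(int(round(-10.0 * math.log10(p / best))) for p in lik)


def grid_search_alt_freq(log10_liks, step=1e-4):
    """Maximum-likelihood alt frequency by brute grid search over [0, 1]."""
    afs = np.arange(0.0, 1.0 + step, step)
    liks = np.power(10.0, np.asarray(log10_liks))  # (n_samples, 3)
    prior = np.stack([(1 - afs) ** 2, 2 * afs * (1 - afs), afs ** 2], axis=-1)  # (A, 3)
    per_sample = liks @ prior.T  # (n_samples, A)
    joint = np.sum(np.log(np.maximum(per_sample, 1e-300)), axis=0)
    return float(afs[np.argmax(joint)])


def gof_pvalue(values, probs):
    """Chi-square goodness-of-fit p-value against pmf over k = 0..len(probs)-1.

    The tail mass beyond the support is folded into the last bin and bins
    are greedily merged so every expected count is >= 5.
    """
    values = np.asarray(values)
    n = values.size
    k = len(probs)
    obs = np.bincount(np.minimum(values, k - 1), minlength=k).astype(float)
    probs = np.asarray(probs, dtype=float).copy()
    probs[-1] += max(0.0, 1.0 - probs.sum())
    merged_o, merged_p = [], []
    o_acc = p_acc = 0.0
    for o, p in zip(obs, probs):
        o_acc += o
        p_acc += p
        if p_acc * n >= 5.0:
            merged_o.append(o_acc)
            merged_p.append(p_acc)
            o_acc = p_acc = 0.0
    if merged_o and (o_acc or p_acc):
        merged_o[-1] += o_acc
        merged_p[-1] += p_acc
    exp = np.asarray(merged_p) * n
    exp *= np.sum(merged_o) / exp.sum()
    return float(stats.chisquare(merged_o, exp).pvalue)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def snp_site():
    return TruthSite(chrom="chr1", pos=100, ref="A", alt="C", genotypes=(0,), region="coding")


@pytest.fixture
def make_pileup(snp_site):
    def _make(bases: str, qual: int = 20, site=None):
        return PileupColumn(
            site=site or snp_site,
            sample_id="S1",
            observations=tuple((b, qual) for b in bases),
        )

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """3 samples x 4,000 sites at the default Poisson 20x / Q20 conditions."""
    cfg = SimConfig(n_sites=4_000, seed=7)
    truth, samples = simulate_cohort(cfg, with_depth_track=False)
    return cfg, truth, samples


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Error-free single-sample cohort for exact self-consistency checks."""
    cfg = SimConfig(n_sites=2_000, n_samples=1, base_error_rate=0.0, seed=11)
    truth, samples = simulate_cohort(cfg, with_depth_track=False)
    return cfg, truth, samples
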