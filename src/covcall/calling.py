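"""Bayesian biallelic genotype calling from pileups.

Model. At an evaluated SNP site with ref allele r and alt allele a, a read
with base b and per-base error probability e (from its phred quality)
contributes

    P(b | hom g)  = 1 - e          if b == g else e/3
    P(b | het)    = [P(b | hom r) + P(b | hom a)] / 2

Reads are independent, so the genotype log-likelihood is the sum of per-read
log terms. PL is the phred-scaled likelihood triple (hom_ref, het, hom_alt)
normalised so the best genotype is 0 (VCF convention).

Single-sample mode uses a flat prior over the three genotypes: the call is
the argmin-PL genotype and GQ is the gap to the second-best PL, capped at
99; exact PL ties give a no-call. Multi-sample mode estimates the site's
alt-allele frequency by EM across samples and scores genotype posteriors
under a Hardy-Weinberg prior; GQ is then -10*log10(1 - posterior of the
called genotype).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .simulate import BASES, HET, HOM_ALT, HOM_REF, NO_CALL, PileupColumn, SampleData

GQ_CAP = 99
_AF_TOL = 1e-6
_AF_MAX_ITER = 100


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """Phred-scaled likelihood triple for (hom_ref, het, hom_alt)."""

    pl: tuple[int, int, int]
    log10_likelihoods: tuple[float, float, float]
    has_data: bool = True

    @classmethod
    def empty(cls) -> "GenotypeLikelihoods":
        """No-likelihood result for an empty pileup (caller emits no_call)."""
        return cls(pl=(0, 0, 0), log10_likelihoods=(0.0, 0.0, 0.0), has_data=False)

    def __post_init__(self) -> None:
        if self.has_data and min(self.pl) != 0:
            raise ValueError("pl: best genotype must be normalised to 0")
        if any(p < 0 for p in self.pl):
            raise ValueError("pl: must be >= 0")


@dataclass(frozen=True)
class FilterPolicy:
    """GQ/DP hard-filter thresholds (defaults GQ >= 20, DP >= 10)."""

    gq_min: int = 20
    dp_min: int = 10

    def __post_init__(self) -> None:
        if self.gq_min < 0 or self.dp_min < 0:
            raise ValueError("gq_min/dp_min: must be >= 0")


@dataclass(frozen=True)
class GenotypeCall:
    """A called genotype with its depth, quality and likelihoods."""

    gt: int                      # HOM_REF/HET/HOM_ALT or NO_CALL
    dp: int
    gq: int
    pl: GenotypeLikelihoods
    passed: bool | None = None   # set by apply_filters

    def __post_init__(self) -> None:
        if not 0 <= self.gq <= GQ_CAP:
            raise ValueError("gq: must be in [0, 99]")
        if self.dp < 0:
            raise ValueError("dp: must be >= 0")
        if self.dp == 0 and self.gt != NO_CALL:
            raise ValueError("gt: must be no_call at dp == 0")


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------

def _channel_log10(bases: np.ndarray, quals: np.ndarray, ref: np.ndarray, alt: np.ndarray):
    """Per-read log10 probabilities under the three genotypes."""
    e = np.power(10.0, -0.1 * quals.astype(np.float64))
    p_rr = np.where(bases == ref, 1.0 - e, e / 3.0)
    p_aa = np.where(bases == alt, 1.0 - e, e / 3.0)
    p_ra = 0.5 * (p_rr + p_aa)
    return np.log10(p_rr), np.log10(p_ra), np.log10(p_aa)


def likelihood_matrix(sample: SampleData) -> tuple[np.ndarray, np.ndarray]:
    """Site-by-genotype log10-likelihoods and depths for one sample.

    Returns ``(ll, dp)`` where ``ll`` has shape (n_sites, 3); rows of
    zero-depth sites are all-zero and must be gated on ``dp``.
    """
    truth = sample.truth
    n = len(truth)
    si = sample.site_index
    logs = _channel_log10(sample.bases, sample.quals, truth.ref[si], truth.alt[si])
    ll = np.empty((n, 3), dtype=np.float64)
    for j, lg in enumerate(logs):
        ll[:, j] = np.bincount(si, weights=lg, minlength=n)
    dp = np.bincount(si, minlength=n).astype(np.int64)
    return ll, dp


def pl_from_log10(ll: np.ndarray) -> np.ndarray:
    """Integer PL triple(s): phred-scaled, normalised so the best is 0."""
    ll = np.asarray(ll, dtype=np.float64)
    return np.rint(-10.0 * (ll - ll.max(axis=-1, keepdims=True))).astype(np.int64)


def site_likelihoods(pileup: PileupColumn, ref: str | None = None, alt: str | None = None) -> GenotypeLikelihoods:
    """Genotype likelihoods for a single pileup column.

    ``ref``/``alt`` default to the pileup's site alleles. An empty pileup
    yields :meth:`GenotypeLikelihoods.empty`.
    """
    ref = ref if ref is not None else pileup.site.ref
    alt = alt if alt is not None else pileup.site.alt
    if ref == alt:
        raise ValueError("alt: must differ from ref")
    if pileup.depth == 0:
        return GenotypeLikelihoods.empty()
    bases = np.array([BASES.index(b) for b, _ in pileup.observations], dtype=np.int8)
    quals = np.array([q for _, q in pileup.observations], dtype=np.int16)
    logs = _channel_log10(
        bases, quals,
        np.int8(BASES.index(ref)), np.int8(BASES.index(alt)),
    )
    ll = np.array([lg.sum() for lg in logs])
    pl = pl_from_log10(ll)
    return GenotypeLikelihoods(pl=tuple(int(p) for p in pl), log10_likelihoods=tuple(ll))


# ---------------------------------------------------------------------------
# single-sample calling
# ---------------------------------------------------------------------------

def call_single(gl: GenotypeLikelihoods, dp: int) -> GenotypeCall:
    """Flat-prior call: argmin PL; GQ = runner-up PL gap (cap 99); ties -> no_call."""
    if dp == 0 or not gl.has_data:
        return GenotypeCall(gt=NO_CALL, dp=dp, gq=0, pl=gl)
    pl = np.asarray(gl.pl)
    order = np.sort(pl)
    gq = int(order[1] - order[0])
    if gq == 0:
        return GenotypeCall(gt=NO_CALL, dp=dp, gq=0, pl=gl)
    return GenotypeCall(gt=int(np.argmin(pl)), dp=dp, gq=min(gq, GQ_CAP), pl=gl)


@dataclass
class CallSet:
    """Vectorised genotype calls for a cohort: arrays shaped (n_samples, n_sites)."""

    sample_ids: tuple[str, ...]
    gt: np.ndarray               # int8; NO_CALL = -1
    dp: np.ndarray               # int64
    gq: np.ndarray               # int16
    pl: np.ndarray               # int64, (n_samples, n_sites, 3)
    pipeline: str                # "single" | "multi"
    alt_freq: np.ndarray | None = None   # multi mode: EM allele frequency per site
    passed: np.ndarray | None = None     # bool, set by apply_filters

    @property
    def n_sites(self) -> int:
        return self.gt.shape[1]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    def call(self, sample_idx: int, site_idx: int) -> GenotypeCall:
        pl = self.pl[sample_idx, site_idx]
        gl = (
            GenotypeLikelihoods(pl=tuple(int(p) for p in pl),
                                log10_likelihoods=tuple(-0.1 * pl))
            if self.dp[sample_idx, site_idx] > 0
            else GenotypeLikelihoods.empty()
        )
        p = None if self.passed is None else bool(self.passed[sample_idx, site_idx])
        return GenotypeCall(
            gt=int(self.gt[sample_idx, site_idx]),
            dp=int(self.dp[sample_idx, site_idx]),
            gq=int(self.gq[sample_idx, site_idx]),
            pl=gl,
            passed=p,
        )


def _single_from_ll(ll: np.ndarray, dp: np.ndarray):
    pl = pl_from_log10(ll)
    part = np.partition(pl, 1, axis=-1)
    gq = (part[..., 1] - part[..., 0]).astype(np.int64)
    gt = np.argmin(pl, axis=-1).astype(np.int8)
    nocall = (gq == 0) | (dp == 0)
    gt[nocall] = NO_CALL
    gq = np.minimum(gq, GQ_CAP).astype(np.int16)
    gq[nocall] = 0
    return gt, gq, pl


def call_samples_single(samples: Sequence[SampleData]) -> CallSet:
    """Single-sample pipeline over a cohort (each sample called independently)."""
    lls, dps = zip(*(likelihood_matrix(s) for s in samples))
    ll = np.stack(lls)
    dp = np.stack(dps)
    gt, gq, pl = _single_from_ll(ll, dp)
    return CallSet(
        sample_ids=tuple(s.sample_id for s in samples),
        gt=gt, dp=dp, gq=gq, pl=pl, pipeline="single",
    )


# ---------------------------------------------------------------------------
# multi-sample calling
# ---------------------------------------------------------------------------

def _hwe_prior(af: np.ndarray) -> np.ndarray:
    return np.stack(((1.0 - af) ** 2, 2.0 * af * (1.0 - af), af ** 2), axis=-1)


def estimate_alt_freq_set(ll: np.ndarray, dp: np.ndarray):
    """EM maximum-likelihood alt-allele frequency per site under HWE.

    ``ll``: (n_samples, n_sites, 3) log10-likelihoods; samples with dp == 0
    are excluded from the M-step. Returns ``(af, posterior)`` with the
    posterior evaluated at the converged frequency; sites with no data in any
    sample get ``af = nan``.
    """
    like = np.power(10.0, ll - ll.max(axis=-1, keepdims=True))
    has = dp > 0
    n_eff = has.sum(axis=0)
    ok = n_eff > 0
    af = np.where(ok, 0.5, np.nan)
    denom = 2.0 * np.maximum(n_eff, 1)
    post = None
    for _ in range(_AF_MAX_ITER):
        prior = _hwe_prior(np.where(ok, af, 0.5))
        post = like * prior[None, :, :]
        z = post.sum(axis=-1, keepdims=True)
        np.divide(post, z, out=post, where=z > 0)
        dosage = post[..., 1] + 2.0 * post[..., 2]
        new = np.where(ok, (dosage * has).sum(axis=0) / denom, np.nan)
        delta = float(np.max(np.abs(new - af), initial=0.0, where=ok)) if ok.any() else 0.0
        af = new
        if delta < _AF_TOL:
            break
    prior = _hwe_prior(np.where(ok, af, 0.5))
    post = like * prior[None, :, :]
    z = post.sum(axis=-1, keepdims=True)
    np.divide(post, z, out=post, where=z > 0)
    return af, post


def estimate_alt_freq(gls: Iterable[GenotypeLikelihoods]) -> float:
    """Alt-allele frequency at one site from per-sample likelihoods.

    Raises ``ValueError`` if every sample is empty (undefined frequency).
    """
    gls = list(gls)
    ll = np.array([g.log10_likelihoods for g in gls])[:, None, :]
    dp = np.array([1 if g.has_data else 0 for g in gls])[:, None]
    if not dp.any():
        raise ValueError("gls: all samples empty, alt frequency undefined")
    af, _ = estimate_alt_freq_set(ll, dp)
    return float(af[0])


def call_multi_from_ll(ll: np.ndarray, dp: np.ndarray):
    """Joint calls from stacked log10-likelihoods; returns (gt, gq, pl, af)."""
    af, post = estimate_alt_freq_set(ll, dp)
    gt = np.argmax(post, axis=-1).astype(np.int8)
    p_best = np.take_along_axis(post, gt[..., None].astype(np.int64), axis=-1)[..., 0]
    gq = np.rint(-10.0 * np.log10(np.maximum(1.0 - p_best, 1e-10)))
    gq = np.minimum(gq, GQ_CAP).astype(np.int16)
    nocall = (dp == 0) | np.isnan(af)[None, :]
    gt[nocall] = NO_CALL
    gq[nocall] = 0
    return gt, gq, pl_from_log10(ll), af


def call_multi(gls: Sequence[GenotypeLikelihoods], dps: Sequence[int]) -> list[GenotypeCall]:
    """Joint HWE-prior calls at one site (record interface over the engine)."""
    if len(gls) != len(dps):
        raise ValueError("dps: must align with gls")
    ll = np.array([g.log10_likelihoods for g in gls])[:, None, :]
    dp = np.asarray(dps, dtype=np.int64)[:, None]
    if not (dp > 0).any():
        raise ValueError("gls: all samples empty, alt frequency undefined")
    gt, gq, _, _ = call_multi_from_ll(ll, dp)
    return [
        GenotypeCall(gt=int(gt[i, 0]), dp=int(dp[i, 0]), gq=int(gq[i, 0]), pl=gls[i])
        for i in range(len(gls))
    ]


def call_samples_multi(samples: Sequence[SampleData]) -> CallSet:
    """Multi-sample pipeline: shared EM allele frequency + HWE prior per site."""
    lls, dps = zip(*(likelihood_matrix(s) for s in samples))
    ll = np.stack(lls)
    dp = np.stack(dps)
    gt, gq, pl, af = call_multi_from_ll(ll, dp)
    return CallSet(
        sample_ids=tuple(s.sample_id for s in samples),
        gt=gt, dp=dp, gq=gq, pl=pl, pipeline="multi", alt_freq=af,
    )


def call_samples(samples: Sequence[SampleData], pipeline: str) -> CallSet:
    if pipeline == "single":
        return call_samples_single(samples)
    if pipeline == "multi":
        return call_samples_multi(samples)
    raise ValueError(f"pipeline: must be 'single' or 'multi', got {pipeline!r}")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def apply_filters(call, policy: FilterPolicy):
    """Set the pass flag: pass = called AND gq >= gq_min AND dp >= dp_min.

    Accepts a single :class:`GenotypeCall` or a :class:`CallSet`; the input
    is otherwise unchanged (a new object is returned).
    """
    if isinstance(call, GenotypeCall):
        ok = call.gt != NO_CALL and call.gq >= policy.gq_min and call.dp >= policy.dp_min
        return replace(call, passed=bool(ok))
    passed = (call.gt != NO_CALL) & (call.gq >= policy.gq_min) & (call.dp >= policy.dp_min)
    return replace(call, passed=passed)
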