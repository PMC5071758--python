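"""Truth panels, region annotations and synthetic per-sample pileups.

The generator produces, for each configured individual, the observation a
genotype caller actually consumes after alignment and read filtering: at
every simulated SNP site, a pileup of base calls with phred qualities. Site
depths follow the configured depth model, thinned per region class by a
read-retention probability; base calls follow the diploid genotype through a
symmetric error channel (a wrong base is any of the other three, each with
probability e/3).

Data live in columnar numpy arrays for speed; :class:`TruthSite` and
:class:`PileupColumn` views provide the per-site record interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .config import REGION_CLASSES, ConfigError, SimConfig, phred_quality

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(BASES.encode(), dtype=np.uint8)

#: Genotype codes used throughout: 0 hom-ref, 1 het, 2 hom-alt, -1 no-call.
HOM_REF, HET, HOM_ALT, NO_CALL = 0, 1, 2, -1
GT_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", NO_CALL: "no_call"}

_SS_TRUTH, _SS_SAMPLE = 101, 202  # seed-stream tags


# ---------------------------------------------------------------------------
# region annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMap:
    """Disjoint half-open intervals tiling [0, genome_length) with a class each."""

    starts: np.ndarray     # int64, ascending, starts[0] == 0
    ends: np.ndarray       # int64, ends[-1] == genome_length
    classes: np.ndarray    # int8 codes into REGION_CLASSES

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def genome_length(self) -> int:
        return int(self.ends[-1])

    def class_of(self, positions0: np.ndarray) -> np.ndarray:
        """Class code of each 0-based position."""
        idx = np.searchsorted(self.starts, positions0, side="right") - 1
        return self.classes[idx]

    def class_lengths(self) -> np.ndarray:
        """Total bp per class, in REGION_CLASSES order."""
        spans = self.ends - self.starts
        return np.bincount(self.classes, weights=spans, minlength=len(REGION_CLASSES)).astype(np.int64)

    def class_track(self) -> np.ndarray:
        """Per-position class codes over the whole genome (int8)."""
        return np.repeat(self.classes, self.ends - self.starts)

    def intervals(self) -> Iterator[tuple[int, int, str]]:
        for s, e, c in zip(self.starts, self.ends, self.classes):
            yield int(s), int(e), REGION_CLASSES[c]


def assign_regions(config: SimConfig) -> RegionMap:
    """Tile the genome with coding/intron/intergenic intervals.

    Class totals are allocated exactly by largest remainder and the classes
    are interleaved in fixed-size pieces (gene-like alternation), so the
    tiling is deterministic, disjoint and covers [0, genome_length) exactly.
    """
    length = config.genome_length
    fracs = config.fractions_array
    raw = fracs * length
    totals = np.floor(raw).astype(np.int64)
    short = length - totals.sum()
    # distribute the remainder to the largest fractional parts
    order = np.argsort(-(raw - totals))
    totals[order[: int(short)]] += 1

    piece = max(1, length // 150)
    starts, ends, classes = [], [], []
    remaining = totals.copy()
    pos = 0
    while pos < length:
        moved = False
        for ci in range(len(REGION_CLASSES)):
            if remaining[ci] > 0:
                take = int(min(piece, remaining[ci]))
                starts.append(pos)
                ends.append(pos + take)
                classes.append(ci)
                pos += take
                remaining[ci] -= take
                moved = True
        if not moved:  # pragma: no cover - defensive; totals sum to length
            break
    return RegionMap(
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        classes=np.asarray(classes, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# truth panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthSite:
    """One simulated biallelic SNP with per-sample true genotypes."""

    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    genotypes: tuple[int, ...]    # per-sample codes (HOM_REF/HET/HOM_ALT)
    region: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref: must differ from alt")
        if self.pos < 1:
            raise ValueError("pos: must be >= 1")


@dataclass
class TruthPanel:
    """Columnar collection of truth sites for one simulated cohort.

    Iterating yields :class:`TruthSite` records; the numpy attributes are the
    fast path used by the caller and the evaluator.
    """

    chrom: str
    pos: np.ndarray          # int64, 1-based, ascending
    ref: np.ndarray          # int8 base codes 0..3
    alt: np.ndarray          # int8 base codes 0..3
    genotypes: np.ndarray    # int8, shape (n_samples, n_sites)
    region: np.ndarray       # int8 class codes
    sample_ids: tuple[str, ...]
    genome_length: int
    region_map: RegionMap | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    def site(self, i: int) -> TruthSite:
        return TruthSite(
            chrom=self.chrom,
            pos=int(self.pos[i]),
            ref=BASES[self.ref[i]],
            alt=BASES[self.alt[i]],
            genotypes=tuple(int(g) for g in self.genotypes[:, i]),
            region=REGION_CLASSES[self.region[i]],
        )

    def __iter__(self) -> Iterator[TruthSite]:
        return (self.site(i) for i in range(len(self)))

    def het_fraction(self) -> float:
        """Realised fraction of heterozygous sample-genotypes."""
        return float(np.mean(self.genotypes == HET))


def build_truth(config: SimConfig, sample_ids: Sequence[str] | None = None) -> TruthPanel:
    """Draw a panel of polymorphic biallelic SNP sites.

    Per sample and site, the genotype is heterozygous with probability
    ``het_fraction``; otherwise hom-alt with probability ``hom_alt_fraction``
    (default 2:1 hom_alt:hom_ref). Sites where no sample carries the alt
    allele are redrawn so every site is polymorphic in the panel. Site
    positions are uniform without collision; the region label is inherited
    from the containing annotation interval. Deterministic under
    ``config.seed``.
    """
    config.validate()
    if config.het_fraction == 0.0 and config.hom_alt_fraction == 0.0:
        raise ConfigError(
            "het_fraction: het_fraction and hom_alt_fraction cannot both be 0 "
            "(no site could carry the alt allele)"
        )
    if sample_ids is None:
        sample_ids = tuple(f"S{i + 1}" for i in range(config.n_samples))
    elif len(sample_ids) != config.n_samples:
        raise ConfigError("sample_ids: length must equal n_samples")

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _SS_TRUTH)))
    n, s = config.n_sites, config.n_samples

    regions = assign_regions(config)
    pos0 = rng.choice(config.genome_length, size=n, replace=False)
    pos0.sort()

    ref = rng.integers(0, 4, size=n, dtype=np.int8)
    alt = ((ref + rng.integers(1, 4, size=n)) % 4).astype(np.int8)

    genotypes = _draw_genotypes(rng, s, n, config.het_fraction, config.hom_alt_fraction)
    # every site must carry the alt allele in at least one sample
    mono = ~(genotypes > HOM_REF).any(axis=0)
    while mono.any():
        genotypes[:, mono] = _draw_genotypes(
            rng, s, int(mono.sum()), config.het_fraction, config.hom_alt_fraction
        )
        mono = ~(genotypes > HOM_REF).any(axis=0)

    return TruthPanel(
        chrom="chr1",
        pos=(pos0 + 1).astype(np.int64),
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        region=regions.class_of(pos0).astype(np.int8),
        sample_ids=tuple(sample_ids),
        genome_length=config.genome_length,
        region_map=regions,
    )


def _draw_genotypes(rng, n_samples: int, n_sites: int, het_frac: float, hom_alt_frac: float) -> np.ndarray:
    u = rng.random((n_samples, n_sites))
    v = rng.random((n_samples, n_sites))
    gt = np.where(u < het_frac, HET, np.where(v < hom_alt_frac, HOM_ALT, HOM_REF))
    return gt.astype(np.int8)


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PileupColumn:
    """Base/quality observations at one site for one sample."""

    site: TruthSite
    sample_id: str
    observations: tuple[tuple[str, int], ...]   # (base, phred quality)

    @property
    def depth(self) -> int:
        return len(self.observations)

    def __post_init__(self) -> None:
        for b, q in self.observations:
            if b not in BASES:
                raise ValueError(f"observations: base {b!r} not in {BASES}")
            if q < 2:
                raise ValueError("observations: quality must be >= 2")


@dataclass
class SampleData:
    """All pileups of one sample plus its genome-wide depth track.

    Observations are stored flat, grouped by ascending site index:
    ``site_index[j]`` is the truth-panel index of observation ``j``.
    ``depth_track`` (optional) holds per-position depths over the whole
    genome for the depth histogram.
    """

    sample_id: str
    truth: TruthPanel
    site_index: np.ndarray   # int64, ascending
    bases: np.ndarray        # int8 base codes
    quals: np.ndarray        # int16 phred
    depth_track: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.truth)

    @property
    def n_observations(self) -> int:
        return len(self.bases)

    def depths(self) -> np.ndarray:
        """Per-site depth vector."""
        return np.bincount(self.site_index, minlength=self.n_sites).astype(np.int64)

    def mean_coverage(self) -> float:
        """Realised mean depth over sites (the downsampling denominator)."""
        return self.n_observations / self.n_sites

    def pileup(self, i: int) -> PileupColumn:
        lo = np.searchsorted(self.site_index, i, side="left")
        hi = np.searchsorted(self.site_index, i, side="right")
        obs = tuple(
            (BASES[b], int(q)) for b, q in zip(self.bases[lo:hi], self.quals[lo:hi])
        )
        return PileupColumn(site=self.truth.site(i), sample_id=self.sample_id, observations=obs)


def simulate_sample(
    truth: TruthPanel,
    config: SimConfig,
    sample_id: str,
    seed: int | np.random.SeedSequence,
    with_depth_track: bool = True,
) -> SampleData:
    """Simulate one sample's pileups at every truth site.

    Raw site depth is drawn from the depth model with mean
    ``source_coverage`` and binomially thinned by the region's retention
    probability. Each retained read carries the true allele — for
    heterozygotes, ref or alt with probability 1/2 each — pushed through the
    symmetric error channel at ``base_error_rate``; qualities are phred of
    that rate (optionally jittered).
    """
    if len(truth) == 0:
        raise ValueError("truth: must be non-empty")
    config.validate()
    if sample_id in truth.sample_ids:
        s_idx = truth.sample_ids.index(sample_id)
    else:
        raise ConfigError(f"sample_id: {sample_id!r} not in truth panel {truth.sample_ids}")

    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence((int(seed), _SS_SAMPLE))
    rng = np.random.default_rng(seed)

    n = len(truth)
    raw_depth = config.depth_model.sample(rng, config.source_coverage, n)
    retention = config.retention_array[truth.region]
    if np.all(retention >= 1.0):
        depth = raw_depth
    else:
        depth = rng.binomial(raw_depth, retention)

    site_index = np.repeat(np.arange(n, dtype=np.int64), depth)
    total = site_index.size

    gt_per_obs = truth.genotypes[s_idx][site_index]
    ref_per_obs = truth.ref[site_index]
    alt_per_obs = truth.alt[site_index]
    # haplotype pick for het reads
    pick_alt = rng.random(total) < 0.5
    source = np.where(
        gt_per_obs == HOM_REF,
        ref_per_obs,
        np.where(gt_per_obs == HOM_ALT, alt_per_obs, np.where(pick_alt, alt_per_obs, ref_per_obs)),
    ).astype(np.int8)

    e = config.base_error_rate
    bases = source.copy()
    if e > 0:
        err = rng.random(total) < e
        n_err = int(err.sum())
        if n_err:
            bases[err] = ((source[err] + rng.integers(1, 4, size=n_err)) % 4).astype(np.int8)

    q0 = phred_quality(e)
    if config.quality_jitter_sd > 0:
        quals = np.clip(
            np.rint(rng.normal(q0, config.quality_jitter_sd, size=total)), 2, 99
        ).astype(np.int16)
    else:
        quals = np.full(total, q0, dtype=np.int16)

    depth_track = None
    if with_depth_track:
        region_map = truth.region_map or assign_regions(config)
        track_raw = config.depth_model.sample(rng, config.source_coverage, config.genome_length)
        if np.all(config.retention_array >= 1.0):
            depth_track = track_raw.astype(np.int32)
        else:
            p_track = config.retention_array[region_map.class_track()]
            depth_track = rng.binomial(track_raw, p_track).astype(np.int32)

    return SampleData(
        sample_id=sample_id,
        truth=truth,
        site_index=site_index,
        bases=bases,
        quals=quals,
        depth_track=depth_track,
    )


def simulate_cohort(
    config: SimConfig, with_depth_track: bool = True
) -> tuple[TruthPanel, list[SampleData]]:
    """Truth panel plus one :class:`SampleData` per configured individual.

    Per-sample seeds are derived from ``config.seed`` by sample index so any
    sample is independently reproducible.
    """
    truth = build_truth(config)
    samples = [
        simulate_sample(
            truth,
            config,
            sid,
            np.random.SeedSequence((config.seed, _SS_SAMPLE, i)),
            with_depth_track=with_depth_track,
        )
        for i, sid in enumerate(truth.sample_ids)
    ]
    return truth, samples
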