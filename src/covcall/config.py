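"""Simulation configuration and per-position depth models.

The simulated organism is a highly heterozygous diploid (the motivating case
is the Pacific oyster *Crassostrea gigas*): ~1.3% of genome positions are
polymorphic and roughly 60% of an individual's SNPs are heterozygous. Pileups
are generated directly at the post-alignment level; read mapping, duplicate
removal and mapping-quality filters are summarised by per-region read
retention probabilities and, optionally, by a zero-inflated depth model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

#: Genomic region classes, in the order used for integer codes everywhere.
REGION_CLASSES = ("coding", "intron", "intergenic")


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


# ---------------------------------------------------------------------------
# depth models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoissonDepth:
    """Uniform-coverage model: per-position depth ~ Poisson(mean).

    The analytic default: closed forms exist for the callable-site fraction
    (e.g. P(depth >= 10 | mean 10) = 1 - F_Poisson(9; 10) = 0.5421) and
    binomial thinning of a Poisson depth is again Poisson.
    """

    name: str = field(default="poisson", init=False)

    def sample(self, rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
        return rng.poisson(mean, size)


@dataclass(frozen=True)
class NegBinDepth:
    """Overdispersed coverage: depth ~ NegBin with var = mean + mean^2/dispersion."""

    dispersion: float = 2.0
    name: str = field(default="negbin", init=False)

    def sample(self, rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
        k = self.dispersion
        if k <= 0:
            raise ConfigError("depth_model: negbin dispersion must be > 0")
        return rng.negative_binomial(k, k / (k + mean), size)


@dataclass(frozen=True)
class MixtureDepth:
    """Zero-inflated coverage: a zero_fraction of positions get no reads at all.

    Real short-read coverage of a diverged genome leaves a large fraction of
    positions with zero mapped reads (~20% in the motivating data). The body
    model's mean is scaled by 1/(1 - zero_fraction) so that the overall mean
    still equals the requested coverage.
    """

    zero_fraction: float = 0.20
    body: Union[PoissonDepth, NegBinDepth] = field(default_factory=PoissonDepth)
    name: str = field(default="mixture", init=False)

    def sample(self, rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ConfigError("depth_model: mixture zero_fraction must be in [0, 1)")
        body_mean = mean / (1.0 - self.zero_fraction)
        depth = self.body.sample(rng, body_mean, size)
        depth[rng.random(size) < self.zero_fraction] = 0
        return depth


DepthModel = Union[PoissonDepth, NegBinDepth, MixtureDepth]


def depth_model_from_spec(spec) -> DepthModel:
    """Build a depth model from a name, mapping, or model instance.

    Accepted forms: ``"poisson"``, ``{"name": "negbin", "dispersion": 2.0}``,
    ``{"name": "mixture", "zero_fraction": 0.2, "body": "poisson"}``.
    """
    if isinstance(spec, (PoissonDepth, NegBinDepth, MixtureDepth)):
        return spec
    if isinstance(spec, str):
        spec = {"name": spec}
    if not isinstance(spec, Mapping):
        raise ConfigError(f"depth_model: cannot interpret {spec!r}")
    name = spec.get("name")
    if name == "poisson":
        return PoissonDepth()
    if name == "negbin":
        return NegBinDepth(dispersion=float(spec.get("dispersion", 2.0)))
    if name == "mixture":
        body = depth_model_from_spec(spec.get("body", "poisson"))
        if isinstance(body, MixtureDepth):
            raise ConfigError("depth_model: mixture body must not itself be a mixture")
        return MixtureDepth(zero_fraction=float(spec.get("zero_fraction", 0.20)), body=body)
    raise ConfigError(f"depth_model: unknown model name {name!r}")


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

def _default_region_fractions() -> dict:
    # Rough gene-architecture split for a compact invertebrate genome.
    return {"coding": 0.10, "intron": 0.25, "intergenic": 0.65}


def _default_region_retention() -> dict:
    # Retention 1.0 keeps the default model analytically checkable; region
    # presets lower intron/intergenic retention to emulate mappability loss.
    return {"coding": 1.0, "intron": 1.0, "intergenic": 1.0}


@dataclass
class SimConfig:
    """Parameters of one synthetic sequencing experiment.

    Parameters
    ----------
    n_sites
        Number of polymorphic (biallelic SNP) sites simulated.
    genome_length
        Genome size in bp; defaults to ``round(n_sites / polymorphism_rate)``
        so the realised polymorphism rate matches the configured one. Used as
        the denominator of depth histograms.
    polymorphism_rate
        Fraction of genome positions that are SNPs (default 0.013).
    het_fraction
        Per-individual probability that a SNP site is heterozygous
        (default 0.60).
    n_samples
        Number of diploid individuals (default 3).
    source_coverage
        Mean mapped depth of the full ("source") dataset (default 20.0).
    depth_model
        Per-position raw depth distribution; see :func:`depth_model_from_spec`.
    base_error_rate
        Per-base miscall probability; 0.01 corresponds to Q20 reads.
    region_fractions
        Genome proportion of each class in ``REGION_CLASSES``; must sum to 1.
    region_retention
        Per-class probability that a read overlapping the region survives
        mapping filters; in [0, 1].
    hom_alt_fraction
        Among non-heterozygous sample genotypes, the probability of hom-alt
        (default 2/3, i.e. a 2:1 hom_alt:hom_ref split).
    quality_jitter_sd
        Standard deviation of integer phred jitter added per read; 0 disables.
    seed
        Base seed for truth generation.
    """

    n_sites: int = 50_000
    genome_length: int | None = None
    polymorphism_rate: float = 0.013
    het_fraction: float = 0.60
    n_samples: int = 3
    source_coverage: float = 20.0
    depth_model: DepthModel = field(default_factory=PoissonDepth)
    base_error_rate: float = 0.01
    region_fractions: dict = field(default_factory=_default_region_fractions)
    region_retention: dict = field(default_factory=_default_region_retention)
    hom_alt_fraction: float = 2.0 / 3.0
    quality_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.depth_model = depth_model_from_spec(self.depth_model)
        if not 0.0 < self.polymorphism_rate < 1.0:
            raise ConfigError("polymorphism_rate: must be in (0, 1)")
        if self.genome_length is None:
            self.genome_length = int(round(self.n_sites / self.polymorphism_rate))
        self.validate()

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites: must be >= 1")
        if not 0.0 < self.polymorphism_rate < 1.0:
            raise ConfigError("polymorphism_rate: must be in (0, 1)")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ConfigError("het_fraction: must be in [0, 1]")
        if self.n_samples < 1:
            raise ConfigError("n_samples: must be >= 1")
        if not self.source_coverage > 0:
            raise ConfigError("source_coverage: must be > 0")
        if not 0.0 <= self.base_error_rate < 0.75:
            raise ConfigError("base_error_rate: must be in [0, 0.75)")
        if not 0.0 <= self.hom_alt_fraction <= 1.0:
            raise ConfigError("hom_alt_fraction: must be in [0, 1]")
        if self.quality_jitter_sd < 0:
            raise ConfigError("quality_jitter_sd: must be >= 0")
        if self.genome_length < self.n_sites:
            raise ConfigError("genome_length: must be >= n_sites")
        if set(self.region_fractions) != set(REGION_CLASSES):
            raise ConfigError(f"region_fractions: keys must be {REGION_CLASSES}")
        total = sum(self.region_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError("region_fractions: must sum to 1 (tolerance 1e-9)")
        if any(v < 0 for v in self.region_fractions.values()):
            raise ConfigError("region_fractions: must be >= 0")
        if set(self.region_retention) != set(REGION_CLASSES):
            raise ConfigError(f"region_retention: keys must be {REGION_CLASSES}")
        if any(not 0.0 <= v <= 1.0 for v in self.region_retention.values()):
            raise ConfigError("region_retention: probabilities must be in [0, 1]")

    @property
    def fractions_array(self) -> np.ndarray:
        return np.array([self.region_fractions[c] for c in REGION_CLASSES], dtype=float)

    @property
    def retention_array(self) -> np.ndarray:
        return np.array([self.region_retention[c] for c in REGION_CLASSES], dtype=float)


def phred_quality(error_rate: float) -> int:
    """Phred score for a per-base error probability, clipped to [2, 99]."""
    e = max(float(error_rate), 1e-10)
    return int(np.clip(round(-10.0 * math.log10(e)), 2, 99))
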