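# Methods

## Scope and model

`covcall` studies genotype calling accuracy as a function of sequencing
coverage for a highly heterozygous diploid. Everything operates at the
**pileup level**: the unit of data is the set of (base, phred quality)
observations overlapping one known SNP site in one sample. Read alignment,
PCR-duplicate removal and mapping-quality filters are not modelled read by
read; their aggregate effect is captured by (a) per-region read-retention
probabilities and (b) optionally a zero-inflated depth model. This is
deliberate: every downstream quantity (likelihoods, DP, GQ, calling rate,
precision) depends on the data only through post-filter per-site bases and
depths.

### Synthetic cohort

A cohort is defined by `SimConfig`. Defaults describe an oyster-like
genome and a standard resequencing design:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 50,000 | biallelic SNP sites simulated |
| `polymorphism_rate` | 0.013 | SNPs per bp; sets `genome_length = n_sites / rate` |
| `het_fraction` | 0.60 | P(site is heterozygous) per individual |
| `hom_alt_fraction` | 2/3 | among non-het genotypes, share that is hom-alt |
| `n_samples` | 3 | diploid individuals |
| `source_coverage` | 20.0 | mean mapped depth of the full data (×) |
| `depth_model` | poisson | also `negbin(dispersion)`, `mixture(zero_fraction, body)` |
| `base_error_rate` | 0.01 | per-base miscall probability (Q20) |
| `region_fractions` | 0.10 / 0.25 / 0.65 | coding / intron / intergenic share of the genome |
| `region_retention` | 1.0 each | P(read survives mapping filters), per class |

Genotypes are drawn i.i.d. per sample and site; sites where no sample
carries the alt allele are redrawn, so the panel is polymorphic by
construction. This conditioning shifts the realised het fraction upward by
≈ 0.0014 at the defaults (P(all-hom-ref) = (0.4/3)³ ≈ 0.0024), well inside
the tolerance of every check that uses it.

Each retained read carries one true allele (heterozygotes: ref or alt with
probability ½) pushed through a symmetric error channel: with probability
`base_error_rate` the base becomes one of the other three, uniformly.
Qualities are uniform at phred(`base_error_rate`) by default; integer
Gaussian jitter is available but off, since uniform Q20 keeps the GQ-pass
probabilities enumerable. `base_error_rate = 0` maps to the quality cap
Q99.

Region annotation tiles the genome deterministically: class totals are
allocated exactly by largest remainder, then interleaved in pieces of
`genome_length/150` bp so regions alternate gene-like instead of forming
three monolithic blocks. Sites inherit the class of their containing
interval. Site positions are uniform without collision; linkage
disequilibrium is deliberately absent — for the organisms this package
models, LD decays too fast to help genotyping, and simulating it would
only complicate the depth/accuracy question being asked.

The `mixture` depth model zeroes a fraction of positions and scales the
body mean by 1/(1 − zero_fraction) so the *overall* mean still equals
`source_coverage`; the depth-track mean therefore always satisfies
E[depth] = source_coverage × Σ fractions·retention.

### Genotype likelihoods and calling

Per read with error probability *e* (from its own quality):
P(b | hom g) = 1 − *e* if b = g else *e*/3; P(b | het) is the equal mixture
of the two homozygous channels. Site log-likelihoods are per-read sums; PL
is the phred-scaled triple normalised so min PL = 0 and rounded to
integers. Single-sample calls take argmin PL under a flat prior over the
three genotypes (the sites are known polymorphisms, so a variant-discovery
prior weighted by θ would only suppress heterozygotes at low depth);
GQ = second PL − best PL, capped at 99. An exact PL tie is an unfilterable
coin flip and becomes a no-call rather than contaminating precision.

Multi-sample calling estimates each site's alt-allele frequency by EM over
genotype posteriors under Hardy–Weinberg equilibrium (E-step: posteriors
at the current frequency; M-step: frequency = mean expected alt dosage / 2;
converged at |Δp| < 1e-6 or 100 iterations, initialised at 0.5; samples
with zero depth are excluded from the M-step). Calls are posterior argmax
with GQ = −10·log10(1 − posterior), floored via max(1 − posterior, 1e-10)
and capped at 99. Likelihoods are exponentiated after per-site max
normalisation, so underflow cannot occur for any realistic depth.

### Titration and evaluation

Downsampling retains a fraction f = target / **realised** mean coverage of
the observations (the realised mean is the right denominator because it is
the mapped reads that get subsampled). Default mode retains exactly
round(f·N) observations uniformly without replacement (per-site depths
multivariate hypergeometric); `binomial_thinning` keeps observations
independently, which turns a Poisson source depth into an exactly Poisson
target depth and is used by the closed-form tests. Replicate cells derive
their seeds from the plan seed by the counter
(plan.seed, coverage_index, replicate, sample_index), so any cell is
reproducible in isolation.

Benchmarks are built from full-coverage calls: GQ ≥ 20 ∧ DP ≥ 10 (the
standard rule), or DP > 20 at GQ ≥ 20 (the depth-only rule used for the DP
sweep). Multi-sample evaluation uses the `all_samples_required` scope: a
benchmark site must be admitted in every sample, and calling rate counts
sites with passing calls in *all* samples — matching how a joint-calling
study would count a site as genotyped. Per-sample scope is available
because the two conventions genuinely differ and both are defensible.

Calling rate and precision are kept strictly separate: precision is
concordance **among passing calls only**; benchmark entries without a
passing call affect the calling rate and nothing else. When no passing
call overlaps the benchmark, precision is an explicit undefined state
(`None`, NaN in tables), never 0 or 1.

## Problem sizes

The headline experiment (tests and `scripts/acceptance.py`) uses 50,000
sites × 3 samples × 5 replicates — about 1M observations per sample and
roughly a minute on one CPU. At this size the binomial standard error of a
calling-rate estimate is ≤ 0.3 percentage points, an order of magnitude
below the tolerances of interest; larger panels change nothing but
runtime. Unit and property tests use 2,000–50,000 sites depending on the
statistical resolution each check needs.

## What the generator does and does not emulate

Passing tests show that, under independent-site sampling with the stated
depth and error models, the coverage/accuracy envelopes hold. Real data
differ in ways the defaults do not model: coverage is overdispersed and
spatially autocorrelated (GC, repeats), error rates vary along reads and
cluster on strands, nearby SNPs share reads, and mapping loss is
haplotype-dependent rather than an independent per-read coin flip. The
negbin/mixture depth models and per-region retention probabilities bound
the first and last effects; the others are out of scope. Consequently the
absolute calling rates here are best-case figures for a given mean depth;
the *shape* of the curves and the filter behaviour are the robust outputs.

## Numerical and design notes

- PL rounding to integers happens once, at the end; ties are detected on
  the rounded values (a 0-phred gap is meaningless to a GQ filter anyway).
- With error-free reads a heterozygous site can still be drawn as a
  one-allele pileup and pass filters as a confident homozygote; this is a
  property of sampling, not a caller bug, and the tests pin it down
  exactly (every discordance in the error-free run is such a pileup).
- Depth histograms bin per-position depth as {0}, {1–9}, {10–100}, {>100}
  over the whole genome track, not just SNP sites.
- The depth track is regenerated from the depth model rather than
  aggregated from site pileups, since SNP sites are a 1.3% sample of
  positions; both draw from the same model, keeping the histogram
  consistent with site depths in distribution.
- Exit codes of the CLI: 0 success, 2 configuration/validation error, 1
  runtime failure; every stage logs to stderr with a stage tag, and
  `manifest.json` records config, seeds, artifacts and completed stages so
  a run can be replayed byte-for-byte.

## Known limitations

Biallelic SNPs only (no indels, no multiallelics); no BAQ, strand-bias or
mapping-quality recalibration machinery; pileup-level only (no FASTQ/BAM
round trip); joint calling assumes Hardy–Weinberg within the cohort, which
is the textbook assumption but wrong for structured or inbred panels.
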