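# covcall

How much sequencing coverage do you need to genotype a **highly heterozygous
diploid** reliably? For organisms like the Pacific oyster *Crassostrea
gigas* — polymorphism rate ≈ 1.3%, ≈ 60% of an individual's SNPs
heterozygous, and linkage disequilibrium that decays within tens of bases —
imputation from neighbouring sites is useless, and low-coverage genotypes of
heterozygous sites collapse to homozygous calls. The practical question is
where the coverage/accuracy trade-off flattens out.

`covcall` answers it by simulation, for people planning resequencing studies
of high-diversity, low-LD species:

1. **Simulate** post-alignment pileups for a cohort of diploid individuals:
   biallelic SNP sites with configurable heterozygosity, per-position depth
   from Poisson / negative-binomial / zero-inflated models, Q20-style base
   errors, and coding/intron/intergenic regions with per-region read
   retention emulating mappability.
2. **Call genotypes** with a Bayesian biallelic model. Per read with error
   probability *e*: P(b | hom g) = 1 − *e* if b = g else *e*/3, and
   P(b | het) = ½[P(b | hom ref) + P(b | hom alt)]. Single-sample mode uses a
   flat genotype prior (GT = argmin PL, GQ = PL gap, capped at 99);
   multi-sample mode estimates the site's alt-allele frequency *p* by EM
   across samples and applies the Hardy–Weinberg prior
   ((1−p)², 2p(1−p), p²).
3. **Titrate coverage**: downsample the full-coverage reads without
   replacement to a grid of target depths (default 5×–18×, five replicates)
   and re-call.
4. **Evaluate** against benchmark genotypes taken from the full-coverage
   calls (GQ ≥ 20 and DP ≥ 10, or a depth > 20 rule): **calling rate** (the
   fraction of benchmark genotypes recovered by passing calls) and
   **precision** (concordance among passing calls).

## Worked example

```sh
covcall run-all --preset quick --outdir out/   # 5,000 sites, ~5 s
covcall report --indir out/
cat out/summary.txt
```

```
single	5x	calling_rate=3.0%	precision=99.79%
single	8x	calling_rate=27.1%	precision=99.93%
single	10x	calling_rate=52.0%	precision=99.92%
single	15x	calling_rate=92.2%	precision=99.99%
multi	5x	calling_rate=0.0%	precision=99.79%
multi	8x	calling_rate=2.1%	precision=99.85%
multi	10x	calling_rate=15.2%	precision=99.90%
multi	15x	calling_rate=79.2%	precision=99.99%
```

Reading this: at 5× a single sample recovers only ~3% of its benchmark
genotypes under GQ ≥ 20 / DP ≥ 10 — the depth filter alone removes almost
everything (P(depth ≥ 10 | mean 5) ≈ 0.03). At 10× about half the genotypes
are callable; by 15× more than 90% are, and precision stays above 99.7%
throughout because the GQ filter removes ambiguous heterozygote pileups.
Joint calling is stricter — a site only counts when *all* samples pass — so
its curve rises later, reaching ~79% at 15×. This is the quantitative basis
for recommending ~15× per individual for species with this diversity
profile.

The same machinery is available as a library:

```python
from covcall import SimConfig, simulate_cohort, call_samples, build_benchmark
cfg = SimConfig(n_sites=20_000, seed=1)          # 20x Poisson source, Q20
truth, samples = simulate_cohort(cfg)
calls = call_samples(samples, "single")
```

Presets: `quick` (smoke), `paper_like` (50,000 sites, 5×–18×, five
replicates), `deep_source` (titration from a 104× source). Any preset field
can be overridden with a YAML config (`covcall run-all --config my.yaml`).

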