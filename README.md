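# multisnp

Screening, error-corrected allele calling and mixture evaluation for
**multi-SNP markers** (microhaplotype-style loci: 1–5 closely linked SNPs
inside a 75 bp window), aimed at forensic DNA mixture analysis with
short-amplicon deep sequencing.

Forensic casework routinely meets mixed DNA traces in which a minor
contributor supplies well under 1% of the template. Conventional CE-STR
profiles saturate and overlap at such ratios, while raw sequencing of SNP
amplicons drowns sub-percent alleles in the ~0.1%/base error floor of the
instrument. This package implements the full computational chain that makes
sub-percent minor alleles callable:

1. **Panel screening** (`multisnp.panel`) — scan phased population
   genotypes in fixed windows and score each window with the *D-value*

   *D = t / C(N, 2)*,

   where *t* counts the pairs of individuals whose diploid genotypes differ
   at ≥ 2 SNVs inside the window. Windows with D ≥ 0.6, free of
   homopolymers and tandem repeats, become panel loci wrapped in < 140 bp
   amplicons.
2. **Allele extraction** (`multisnp.extraction`) — the allele of a locus is
   the concatenated base calls at its SNP positions. Only fully mapped
   mates spanning every SNP count; SNPs within 2 bp of indels, repeat
   tracts or runs of ≥ 2 consecutive mismatches are masked; and **only read
   pairs whose two mates agree** are retained, which suppresses independent
   sequencing errors to O(e²).
3. **Error profile** (`multisnp.errors`) — from single-source samples,
   every allele beyond the top two is an artifact; *e_l(n)* is the mean
   fraction of a locus's reads carried by artifacts at Hamming distance *n*
   from a true allele, forced non-increasing in *n*.
4. **Iterative binomial caller** (`multisnp.caller`) — at each locus the
   top allele is the major; a candidate with *c* reads against a template
   with *C_T* reads at distance *n* is tested with the exact tail
   *P(X ≥ c)*, *X ~ Binomial(C_T + c, e_l(n))*; Benjamini–Hochberg-corrected
   q-values below the FDR threshold (0.5%) accept true minor alleles;
   later rounds re-template the remainder on the nearest accepted allele.
5. **Genotyping and statistics** (`multisnp.genotype`, `multisnp.popstats`)
   — depth (> 50) and α-ratio rules for single-source genotypes; He, Ho,
   MP/DP, PE, exact Hardy–Weinberg tests and their panel-wide combinations
   (CMP/TDP/CPE, Bonferroni threshold).
6. **Mixture evaluation** (`multisnp.mixture`) — detection rates against
   known contributor panels and the distinguishability of minor-unique
   alleles.
7. **Simulator** (`multisnp.sim`) — a fully seeded generator for panels,
   populations, single-source samples and mixtures with a two-layer error
   model (molecule-level PCR errors that *survive* concordance filtering,
   per-mate sequencing errors that mostly do not), template-copy dropout at
   nanogram inputs, the complete 75-mixture and 60-dilution design grids,
   and ground truth for every emitted read pair.

## Worked example

Simulate a 100-locus panel and a 50-person population, estimate the error
profile from 20 single-source samples, then deconvolve a 95:5 two-person
mixture at 2 ng:

```python
import numpy as np
import multisnp as m

cfg = m.SimConfig(seed=7, n_loci=100, population_size=50)
pop = m.simulate_population(cfg)
rng = np.random.default_rng(7)

err = m.validation.build_error_profile(pop, pop.sample_ids[:20], rng)

major, minor = pop.sample_ids[30], pop.sample_ids[31]
profiles, truth = m.simulate_sample_profiles(
    pop, [(major, 0.95), (minor, 0.05)], rng=rng, total_input_ng=2.0
)
calls = m.call_sample(profiles, err)
report = m.evaluate_mixture(
    "demo", calls,
    [pop.contributor_panel(major), pop.contributor_panel(minor)],
    minor_id=minor,
)
print(f"overall detection rate:   {report.overall_detection_rate:.4f}")
print(f"minor allele recovery:    {report.contributor_detection[minor]:.4f}")
print(f"minor distinguishability: {report.minor_distinguishability:.4f}")
```

prints

```
overall detection rate:   0.9677
minor allele recovery:    1.0000
minor distinguishability: 1.0000
```

i.e. every allele of the 5% contributor was recovered, 96.8% of all
detected alleles belong to a known contributor (the remainder are accepted
artifacts), and every minor-unique allele was distinguishable. At one
locus the call table looks like

```
allele  count  status  template  n  p          q          round
AATG    609    major   -         -  -          -          0
AGCG    535    minor   AATG      2  ~0         ~0         1
AACG    57     minor   AATG      1  1.1e-114   1.1e-114   1
```

A command-line interface mirrors the library
(`multisnp screen | extract | errprofile | call | genotype | stats |
mixture | simulate`); run any subcommand with `--help`.

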