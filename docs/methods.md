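# Methods

This note documents the models and procedures implemented in `multisnp`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the simulation-based tests do and do not show
about real data.

## Marker screening: the D-value

For a window of S segregating sites over a phased cohort of N diploid
individuals, the D-value is `t / C(N, 2)`, where a pair of individuals
counts toward `t` when their genotypes differ at **at least two** sites in
the window. Two readings of "differ" are possible; the default compares
*unordered diploid genotypes* per site (phase ignored), because the
statistic is defined over pairings of individuals; a `compare="haplotype"`
switch scores the best phase pairing instead. The ≥ 2-SNV requirement
means a lone SNP can never distinguish a pair, which is what pushes the
screen toward genuinely multi-allelic, linked-SNP windows.

Scanning slides a 75 bp window at 1 bp steps (the step is a parameter;
the window size accommodates degraded, short-fragment DNA) and scores
every window containing ≥ 1 site. Filtering retains windows with
D ≥ 0.6 whose sequence has no homopolymer run ≥ 6 bp and no 2–6 bp motif
repeated ≥ 3 times contiguously — both detectors configurable, since such
tracts breed alignment and amplification artifacts. Overlapping survivors
(inevitable at 1 bp stepping) are resolved greedily by descending D.
Amplicons are the window plus symmetric flanks capped below 140 bp so a
single read spans the whole amplicon; primer design proper is out of
scope.

## Allele extraction

The allele of a locus is the string of base calls at its SNP positions in
genomic order — fixed length, so Hamming distances between alleles are
well defined. A mate is used only when fully mapped (any clipping
disqualifies it) and spanning every SNP of the locus. A SNP call is
masked when it lies within, or within 2 bp of, (a) a repeat tract
annotated on the amplicon with the same detectors as the screen, (b) an
indel in that read's alignment, or (c) a run of ≥ 2 consecutive
mismatched columns. A pair with any masked SNP is dropped whole rather
than emitting a partial allele. Base qualities are ignored by default (a
minimum-quality mask exists but is off).

The decisive filter is **pair concordance**: both mates must report the
identical allele. Sequencing errors strike mates independently, so a
false allele must arise twice identically — per SNP a probability of
order e²/3 against e per base raw; the simulator-backed tests confirm the
concordant-error fraction sits orders of magnitude below the per-base
rate. PCR errors, in contrast, are molecule-level: both mates inherit
them, concordance cannot remove them, and they are exactly what the
downstream caller models.

## The error profile e_l(n)

In a single-source sample at most two alleles per locus are real. Every
other allele is an artifact whose "false SNV count" n is its minimum
Hamming distance to a true allele. Per sample, `ratio(n)` is the fraction
of the locus's retained reads carried by artifacts at distance n (the
denominator is all retained concordant pairs — the natural normalisation,
since the caller's binomial uses read counts); `e_l(n)` is the mean of
`ratio(n)` over samples.

Designating "true" alleles: the top-count allele always; the second-
ranked allele only when it reaches α = 0.05 of the top count (otherwise
the sample is treated as homozygous there and the runner-up as an
artifact — counting a homozygote's artifact as true would deflate e_l),
and not when tied with the third rank (ties for second place are all
treated as erroneous; conservative, slightly inflating e_l).

Because independent errors rarely co-occur in one molecule, e_l(n) is
made non-increasing in n by pool-adjacent-violators. **Unobserved n**:
an n with no artifact reads at all carries no evidence of its own rate;
it inherits the last observed (fitted) rate at smaller n, never less than
the floor (10⁻⁶). This is deliberately conservative. The alternative —
dropping unobserved n straight to the floor — lets a *single stray read*
at distance ≥ 2 from the major reach p ≈ N·10⁻⁶ ≈ 6·10⁻⁴ < 0.005 and be
"accepted": in round 1 every candidate is measured against the major
allele, so a PCR mutant of the heterozygous *partner* allele naturally
sits at distance ≥ 2 from the major, and the floor would wave it through.
Under the conservative inheritance rule the measured false-discovery
proportion of the caller stays below its nominal 0.5% (see the acceptance
experiments); under the bare floor it reaches ~10%. The floor itself
remains only for loci with no observed artifacts at any n.

## Iterative binomial calling

Round 1: the top-count allele (ties broken lexicographically) is the
major; every other allele is a candidate presumed to be an amplification
product of the major. A candidate with count c at distance n from its
template T is tested with the exact binomial upper tail
P(X ≥ c), X ~ Binomial(count(T) + c, e_l(n)). All p-values of a round are
Benjamini–Hochberg corrected together (within the locus by default; a
per-sample pooling switch exists) and candidates with q < 0.5% become
true minor alleles. Later rounds re-template each remaining candidate on
its most similar accepted allele (minimum Hamming, ties lexicographic)
and repeat; the procedure stops when a round accepts nothing. Accepted
sets grow monotonically, so termination is guaranteed; candidates with
c = 1 are tested like any other — the tail probability handles them.

## Genotyping rules

Only loci whose major allele exceeds 50 pairs are genotyped. With
α(a) = count(a)/count(major): all α < 0.05 → homozygous; exactly one α in
[0.05, 0.2] (both ends inclusive — the homozygous rule's "< 0.05" forces
the lower boundary, the upper is a choice) and the rest < 0.05 →
heterozygous; anything else fails. These rules are implemented exactly as
stated, including their awkward corollary: a *balanced* true heterozygote
(α ≈ 1) fails genotyping. For that reason the pipeline's recovery checks
run through the caller (which accepts both alleles of a balanced
heterozygote trivially); the genotyper rules are asserted verbatim on
their own cases. Genotyping consumes raw profiles by default; a wiring
that first removes the caller's rejected artifacts is provided.

## Forensic statistics

Counting-method allele frequencies over 2n chromosomes; Ho = heterozygote
fraction; He = 1 − Σp² (plain form; an unbiased 2n/(2n−1) switch exists);
MP = Σ (observed genotype frequency)², DP = 1 − MP; PE = h²(1 − 2hH²)
with h = Ho, H = 1 − Ho (the standard single-parent exclusion form).
These are stated as conventions, not claims about any particular
commercial implementation. HWE uses the exact conditional test: full
enumeration of the heterozygote-count distribution for biallelic loci,
seeded Monte-Carlo permutation of the 2n allele copies otherwise
(10⁵ permutations by default, (m+1)/(reps+1) estimator) — enumerating
multi-allelic tables adds complexity without accuracy at that replicate
count. Panel combination runs in log space: CMP = ΠMP, TDP = 1 − CMP,
CPE = 1 − Π(1 − PE), and the Bonferroni HWE threshold is family α / L
(0.05/567 = 8.818·10⁻⁵ at full panel size).

## Mixture scoring

All rates count unique allele strings, never reads. Overall detection
rate = matched detected alleles / all detected alleles. Per-contributor
detection conditions on loci with ≥ 1 called allele. Minor
distinguishability is the fraction of the minor's *unique* alleles
(absent from every other contributor at that locus) that were called,
counted over **all** panel loci — a locus that drops out entirely scores
against the minor, since an undefined-on-dropout rate would hide exactly
the failure mode of interest.

## Simulator

The generator emulates the study conditions end to end and is the test
bed for every stage:

* **Panel**: 567 loci by default, category mix 48/157/246/91/25 for
  1/2/3/4/5 linked SNPs (largest-remainder apportionment, so the default
  panel reproduces those counts exactly). SNPs sit on a 3 bp grid inside
  the 75 bp window so linked variants never form adjacent-mismatch runs.
* **Frequencies**: per locus a symmetric Dirichlet over all 2^k ref/alt
  haplotypes. Concentrations per category (2.0, 0.6875, 0.2115, 0.0887,
  0.0410 for k = 1…5) solve E[He] = (2^k−1)α/(2^kα+1) ≈ 0.55 for
  multi-SNP loci — the realistic mean heterozygosity of such panels —
  and 0.40 for biallelic single-SNP loci (whose He is capped at 0.5).
* **Population**: two haplotypes per individual per locus by independent
  draws, so HWE holds by construction.
* **Template molecules**: a contributor with mass fraction f in a sample
  of M ng contributes Poisson(M·f/0.0033) haploid genome copies per locus
  (3.3 pg per haploid copy), split evenly between its two haplotypes.
  Zero copies at a locus is dropout; at the lowest dilution input
  (0.00976563 ng ≈ 3 copies) the dropout fraction is the Poisson zero
  class. This molecule model is the simulator's own construction — the
  link from nanograms to copies is physics, not a fitted parameter.
* **PCR layer**: each molecule's allele mutates at 10⁻⁴ per base, once,
  before reads are drawn; all reads of that molecule inherit the mutation
  (maximally clumpy, i.e. the hardest case for a read-level binomial
  model). A per-cycle branching model was considered and left out: the
  caller abstracts the compound process through e_l(n), and the
  single-hit layer already produces the clonal artifact class the method
  exists to remove.
* **Sequencing layer**: Poisson(1150) read pairs per locus (optional
  lognormal per-locus spread), assigned to molecules proportionally;
  each mate mutates independently at 10⁻³ per base. Error placement uses
  exact event-count sampling (binomial totals, uniform placement without
  replacement), which is equivalent to per-base Bernoulli draws and fast
  enough for ~10⁵ locus-samples per minute.
* **Outputs**: aggregated (allele_r1, allele_r2) pair tables by default;
  full per-pair truth records in tracked mode; optional aligned SAM plus
  reference FASTA (with repeat-free SNP neighbourhoods) so the
  alignment-facing extraction filters are integration-tested.
* **Design grids**: the 75-configuration mixture study
  (25 two-person, 25 three-person, 23 four-person, one balanced 5-person,
  one balanced 10-person, at their published ratios and inputs — the
  printed four-person ratio row that does not sum to 100 is normalised to
  96.5:2:1:0.5 following the halving pattern of the neighbouring rows)
  and the 60-sample dilution series (2 × 10 inputs × 3 replicates).

Single-source *reference-style* samples default to 50 ng input: reference
material (microlitres of blood-derived extract) is abundant, and at that
template depth (~15 000 copies/locus) PCR artifacts stay sub-clonal —
each mutant molecule receives ≪ 1 read on average. Mixtures use the
design-grid masses.

## Benchmark experiments and their honest limits

`scripts/acceptance.py` runs two experiments (shared with the test
suite; problem sizes chosen to finish in about a minute on one CPU):

* **Minor distinguishability**: 567 loci, error profile from 100
  simulated single-source samples, then 10 replicates each of 2-, 3- and
  4-person mixtures (99.5:0.5, 98.5:1:0.5, 96.5:2:1:0.5) at 1 ng total,
  depth 1150, caller at FDR 0.5%; the pooled fraction of minor-unique
  alleles called is reported together with the fraction backed by ≥ 1
  template molecule. At these conditions the 0.5% minor contributes
  Poisson(≈1.5) haploid copies per locus, so only ~56% of its unique
  alleles are physically present in the tube at all — that is the hard
  ceiling of this experiment, and no caller can exceed it under this
  molecule model. The caller recovers ~85–90% of the present alleles
  (≈46–48% pooled). Wet-lab reports of higher rates at nominally
  identical inputs imply more effective template than the nominal mass
  predicts (pipetting at 5 pg is not exact) or a differently conditioned
  denominator; the simulation keeps the physical model and reports the
  number it actually computes.
* **False-discovery proportion**: 200 single-source samples; e_l(n)
  estimated on one half, the caller run on the other; every accepted
  non-major allele outside the individual's two true alleles is a false
  discovery. Pooled FDP ≈ 0.3%, inside the nominal 0.5% despite the
  clumpy molecule-level error layer.

What the simulations do **not** show: sequence-context-dependent error
spectra, per-cycle PCR branching, chimeric amplicons, index hopping,
degradation and inhibitor effects, primer-binding bias, or real
population structure (the Dirichlet model is exchangeable and HWE holds
exactly). Passing tests demonstrate the algorithms are implemented
correctly and calibrated under the stated generative model, not that the
same numbers will be observed on any particular instrument or cohort.

## Numerical choices

Exact binomial tails via the regularised incomplete beta
(`scipy.stats.binom.sf`), verified in tests against a 60-digit decimal
summation oracle to 10⁻¹² relative error. Panel products in log space
(exact to 10⁻¹² against direct products at small L, no underflow at
L = 567). Deterministic tie-breaks throughout (lexicographic for major
alleles, templates and true-allele designation) make every result
invariant to input ordering. All randomness flows from
`numpy.random.default_rng` seeded explicitly; identical seeds give
byte-identical outputs.
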