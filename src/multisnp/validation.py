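"""End-to-end benchmark experiments on fully simulated data.

Two study-condition experiments exercise the whole pipeline (simulation
-> concordance extraction -> error-profile estimation -> iterative
binomial calling -> mixture scoring):

* :func:`minor_distinguishability_experiment` — how many of a 0.5%
  minor contributor's unique alleles the caller recovers from 1 ng
  total-input 2/3/4-person mixtures.
* :func:`single_source_fdp_experiment` — the empirical false-discovery
  proportion of accepted minor alleles on single-source samples, where
  the two true alleles are known and every other accepted allele is a
  false discovery.

Both derive all randomness from one integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .caller import call_sample
from .errors import ErrorProfile, estimate_error_profile
from .mixture import minor_unique_alleles
from .sim import SimConfig, SimPopulation, simulate_population, simulate_sample_profiles

logger = logging.getLogger(__name__)

#: total DNA input of a simulated reference-style single-source sample (ng).
#: Reference samples are abundant (microlitres of blood-derived gDNA), so the
#: per-locus template count is large and PCR artifacts stay sub-clonal.
SINGLE_SOURCE_INPUT_NG = 50.0

#: the three mixture designs with the minor contributor at 0.5% mass
MINOR_MIX_DESIGNS: tuple[tuple[float, ...], ...] = (
    (99.5, 0.5),
    (98.5, 1.0, 0.5),
    (96.5, 2.0, 1.0, 0.5),
)


def build_error_profile(
    population: SimPopulation,
    sample_ids: list[str],
    rng: np.random.Generator,
    total_input_ng: float = SINGLE_SOURCE_INPUT_NG,
) -> ErrorProfile:
    """Estimate e_l(n) from simulated single-source samples."""
    samples = []
    for sid in sample_ids:
        profiles, _ = simulate_sample_profiles(
            population, [(sid, 1.0)], rng=rng, total_input_ng=total_input_ng
        )
        samples.append(profiles)
    snp_counts = {sl.locus_id: sl.n_snps for sl in population.panel}
    return estimate_error_profile(samples, snp_counts)


@dataclass
class MinorDistinguishabilityResult:
    fraction_called: float
    n_unique_alleles: int
    n_called: int
    #: upper bound imposed by template sampling: fraction of minor-unique
    #: alleles backed by at least one template molecule
    fraction_with_template: float
    n_mixtures: int


def minor_distinguishability_experiment(
    seed: int,
    n_loci: int = 567,
    population_size: int = 409,
    n_error_samples: int = 100,
    n_replicates: int = 10,
    total_input_ng: float = 1.0,
    minor_fraction: float = 0.005,
    fdr: float = 0.005,
    mean_depth: float = 1150.0,
    seq_error: float = 1e-3,
    pcr_error: float = 1e-4,
) -> MinorDistinguishabilityResult:
    """Pooled minor-unique allele recovery over 2/3/4-person mixtures.

    One panel + population is simulated; e_l(n) is estimated from
    ``n_error_samples`` single-source individuals; each replicate then
    draws fresh contributors for each design (minor at
    ``minor_fraction`` of ``total_input_ng``), runs extraction and the
    caller, and scores the minor's unique alleles.
    """
    cfg = SimConfig(
        seed=seed,
        n_loci=n_loci,
        population_size=population_size,
        mean_depth=mean_depth,
        seq_error=seq_error,
        pcr_error=pcr_error,
    )
    population = simulate_population(cfg)
    rng = np.random.default_rng(seed + 1)
    profile_ids = population.sample_ids[:n_error_samples]
    err = build_error_profile(population, profile_ids, rng)

    pool = population.sample_ids[n_error_samples:]
    found = total = present = 0
    n_mix = 0
    for _ in range(n_replicates):
        for ratios in MINOR_MIX_DESIGNS:
            n_c = len(ratios)
            picked = rng.choice(len(pool), size=n_c, replace=False)
            ids = [pool[i] for i in picked]
            fracs = [r / 100.0 for r in ratios[:-1]] + [minor_fraction]
            fracs = [f / sum(fracs) for f in fracs]
            contributors = list(zip(ids, fracs))
            minor_id = ids[-1]
            profiles, truth = simulate_sample_profiles(
                population, contributors, rng=rng, total_input_ng=total_input_ng
            )
            calls = call_sample(profiles, err, fdr)
            panels = [population.contributor_panel(i) for i in ids]
            unique = minor_unique_alleles(panels, minor_id)
            for lid, alleles in unique.items():
                total += len(alleles)
                truth_mols = truth.per_locus[lid].molecules.get(minor_id, {})
                present += sum(1 for a in alleles if truth_mols.get(a, 0) > 0)
                if lid in calls:
                    found += len(alleles & frozenset(calls[lid].true_alleles))
            n_mix += 1
    return MinorDistinguishabilityResult(
        fraction_called=found / total,
        n_unique_alleles=total,
        n_called=found,
        fraction_with_template=present / total,
        n_mixtures=n_mix,
    )


@dataclass
class FdpResult:
    fdp: float
    n_false: int
    n_accepted_minor: int
    n_samples_called: int


def single_source_fdp_experiment(
    seed: int,
    n_loci: int = 567,
    population_size: int = 409,
    n_samples: int = 200,
    fdr: float = 0.005,
    total_input_ng: float = SINGLE_SOURCE_INPUT_NG,
    mean_depth: float = 1150.0,
    seq_error: float = 1e-3,
    pcr_error: float = 1e-4,
) -> FdpResult:
    """Empirical FDP of minor-allele calls on single-source samples.

    e_l(n) is estimated on the first half of the samples; the caller runs
    on the second half, where an accepted non-major allele outside the
    individual's two true alleles is a false discovery.  The proportion
    is pooled over loci and samples.
    """
    cfg = SimConfig(
        seed=seed,
        n_loci=n_loci,
        population_size=population_size,
        mean_depth=mean_depth,
        seq_error=seq_error,
        pcr_error=pcr_error,
    )
    population = simulate_population(cfg)
    rng = np.random.default_rng(seed + 1)
    half = n_samples // 2
    train_ids = population.sample_ids[:half]
    test_ids = population.sample_ids[half : half + (n_samples - half)]
    err = build_error_profile(population, train_ids, rng, total_input_ng)

    n_false = n_accepted = 0
    for sid in test_ids:
        profiles, _ = simulate_sample_profiles(
            population, [(sid, 1.0)], rng=rng, total_input_ng=total_input_ng
        )
        calls = call_sample(profiles, err, fdr)
        for li, sl in enumerate(population.panel):
            cs = calls.get(sl.locus_id)
            if cs is None:
                continue
            true = set(population.individual_alleles(sid, li))
            for c in cs.calls:
                if c.status == "minor":
                    n_accepted += 1
                    if c.allele not in true:
                        n_false += 1
    fdp = n_false / n_accepted if n_accepted else 0.0
    return FdpResult(fdp, n_false, n_accepted, len(test_ids))
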