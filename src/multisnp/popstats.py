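"""Forensic population statistics for a multi-SNP panel.

Per locus: counting-method allele frequencies, observed/expected
heterozygosity, match probability (sum of squared observed genotype
frequencies), discrimination power, single-parent power of exclusion and
a Hardy–Weinberg exact test (full enumeration for biallelic loci, seeded
Monte-Carlo permutation otherwise).  Panel-wide: combined match
probability, total discrimination power and combined power of exclusion,
accumulated in log space, plus the Bonferroni-corrected HWE alpha.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotype import GenotypeCall

logger = logging.getLogger(__name__)


@dataclass
class LocusStats:
    locus_id: str
    allele_freqs: dict[str, float]
    he: float
    ho: float
    mp: float
    dp: float
    pe: float
    hwe_p: float
    n_individuals: int


@dataclass
class PanelStats:
    loci: dict[str, LocusStats]
    cmp: float
    tdp: float
    cpe: float
    bonferroni_alpha: float


def acr(depth_a: int, depth_b: int) -> float:
    """Allele coverage ratio at a heterozygous genotype: min/max depth."""
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("ACR undefined for zero allele depth")
    return min(depth_a, depth_b) / max(depth_a, depth_b)


def locus_stats(
    genotypes: Iterable[GenotypeCall],
    hwe_reps: int = 100_000,
    rng: np.random.Generator | int | None = None,
    unbiased_he: bool = False,
) -> LocusStats:
    """Compute the statistics of one locus from per-individual genotypes.

    Only successfully genotyped individuals (homozygous or heterozygous
    calls) enter; at least two are required.  ``unbiased_he`` applies the
    2n/(2n-1) small-sample factor to the expected heterozygosity.
    """
    calls = [g for g in genotypes if g.genotyped]
    if len(calls) < 2:
        raise ValueError("locus_stats needs >= 2 genotyped individuals")
    locus_id = calls[0].locus_id

    allele_counts: Counter[str] = Counter()
    geno_counts: Counter[tuple[str, ...]] = Counter()
    n_het = 0
    for g in calls:
        if g.status == "homozygous":
            allele_counts[g.alleles[0]] += 2
            geno_counts[(g.alleles[0], g.alleles[0])] += 1
        else:
            a, b = sorted(g.alleles)
            allele_counts[a] += 1
            allele_counts[b] += 1
            geno_counts[(a, b)] += 1
            n_het += 1
    n = len(calls)
    two_n = 2 * n
    freqs = {a: c / two_n for a, c in allele_counts.items()}

    ho = n_het / n
    he = 1.0 - sum(p * p for p in freqs.values())
    if unbiased_he:
        he *= two_n / (two_n - 1)
    mp = sum((c / n) ** 2 for c in geno_counts.values())
    dp = 1.0 - mp
    h, hom = ho, 1.0 - ho
    pe = h * h * (1.0 - 2.0 * h * hom * hom)
    if len(freqs) < 2:
        hwe_p = 1.0
    else:
        hwe_p = hwe_exact_test(geno_counts, hwe_reps, rng)
    return LocusStats(locus_id, freqs, he, ho, mp, dp, pe, hwe_p, n)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------


def _log_table_prob_terms(geno_counts: Mapping[tuple[str, ...], int]) -> float:
    """Permutation-variable part of log P(genotype table | allele counts)."""
    n_het = sum(c for g, c in geno_counts.items() if g[0] != g[1])
    return n_het * math.log(2.0) - sum(
        math.lgamma(c + 1) for c in geno_counts.values()
    )


def hwe_exact_test(
    geno_counts: Mapping[tuple[str, ...], int],
    reps: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Exact HWE test on a genotype-count table.

    Biallelic tables are fully enumerated (conditional distribution of the
    heterozygote count given allele counts).  Multi-allelic tables use a
    Monte-Carlo permutation of the 2n allele copies, with the conditional
    table probability as the ordering statistic and the (m+1)/(reps+1)
    estimator.
    """
    alleles = sorted({a for g in geno_counts for a in g})
    if len(alleles) == 2:
        return _hwe_exact_biallelic(geno_counts, alleles)

    rng = np.random.default_rng(rng)
    pool = []
    for (a, b), c in geno_counts.items():
        pool.extend([a] * c)
        pool.extend([b] * c)
    pool = np.array(pool)
    obs = _log_table_prob_terms(geno_counts)
    hits = 0
    for _ in range(reps):
        rng.shuffle(pool)
        table: Counter[tuple[str, ...]] = Counter()
        it = iter(pool.tolist())
        for a in it:
            b = next(it)
            table[tuple(sorted((a, b)))] += 1
        if _log_table_prob_terms(table) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1)


def _hwe_exact_biallelic(geno_counts: Mapping[tuple[str, ...], int],
                         alleles: Sequence[str]) -> float:
    a, b = alleles
    n_ab = geno_counts.get((a, b), 0) + geno_counts.get((b, a), 0)
    n_aa = geno_counts.get((a, a), 0)
    n_bb = geno_counts.get((b, b), 0)
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)

    def log_prob(het: int) -> float:
        hom_r = (rare - het) // 2
        hom_c = n - hom_r - het
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_c + 1)
            + het * math.log(2.0)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs = logs[n_ab]
    total = sum(math.exp(lp) for lp in logs.values())
    p = sum(math.exp(lp) for lp in logs.values() if lp <= obs + 1e-12) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Panel combination
# ---------------------------------------------------------------------------


def combine_panel(stats: Sequence[LocusStats], family_alpha: float = 0.05) -> PanelStats:
    """Combine per-locus statistics panel-wide.

    CMP = product of MP over loci, TDP = 1 - CMP, CPE = 1 - product of
    (1 - PE); the products run in log space so a 567-locus panel does not
    underflow.  ``bonferroni_alpha`` = family_alpha / number of loci.
    """
    if not stats:
        raise ValueError("combine_panel needs >= 1 locus")
    log_cmp = 0.0
    for s in stats:
        if s.mp <= 0.0:
            log_cmp = -math.inf
            break
        log_cmp += math.log(s.mp)
    cmp_ = math.exp(log_cmp) if log_cmp > -math.inf else 0.0
    log_no_excl = 0.0
    for s in stats:
        if s.pe >= 1.0:
            log_no_excl = -math.inf
            break
        log_no_excl += math.log1p(-s.pe)
    cpe = 1.0 - (math.exp(log_no_excl) if log_no_excl > -math.inf else 0.0)
    return PanelStats(
        loci={s.locus_id: s for s in stats},
        cmp=cmp_,
        tdp=1.0 - cmp_,
        cpe=cpe,
        bonferroni_alpha=family_alpha / len(stats),
    )


def write_stats(panel_stats: PanelStats, tsv_path: str, json_path: str | None = None) -> None:
    import json

    import pandas as pd

    rows = [
        {
            "locus_id": s.locus_id,
            "n_alleles": len(s.allele_freqs),
            "He": s.he,
            "Ho": s.ho,
            "MP": s.mp,
            "DP": s.dp,
            "PE": s.pe,
            "HWE_p": s.hwe_p,
            "n_individuals": s.n_individuals,
        }
        for s in panel_stats.loci.values()
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "CMP": panel_stats.cmp,
                    "TDP": panel_stats.tdp,
                    "CPE": panel_stats.cpe,
                    "bonferroni_alpha": panel_stats.bonferroni_alpha,
                    "n_loci": len(panel_stats.loci),
                },
                fh,
                indent=2,
            )
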