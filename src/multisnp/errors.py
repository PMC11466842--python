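"""Locus-specific error-profile estimation, e_l(n).

At a multi-SNP locus of a single-source sample at most two alleles are
real; everything else in the read profile is a technical artifact.  For
each artifact allele the number of false SNVs, n, is its minimum Hamming
distance to a true allele.  e_l(n) is the mean, over single-source
samples, of the fraction of the locus's retained reads carried by
artifact alleles at distance n.  Because independent errors rarely
co-occur on one molecule, e_l(n) is forced non-increasing in n (pool
adjacent violators), and n values never observed fall back to a small
floor rate so the downstream binomial test stays defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .extraction import LocusReadProfile

logger = logging.getLogger(__name__)

DEFAULT_FLOOR_RATE = 1e-6
#: second-ranked allele must reach this fraction of the top allele to be
#: treated as the true second allele of a (heterozygous) single-source sample
DEFAULT_TRUE_ALLELE_ALPHA = 0.05


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("alleles must have equal length")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ErrorProfileEntry:
    """e_l(n) for one locus, n = 1..n_snps."""

    locus_id: str
    rates: dict[int, float]
    n_samples_used: int
    floor_rate: float = DEFAULT_FLOOR_RATE
    usable: bool = True

    def rate(self, n: int) -> float:
        if n < 1:
            raise ValueError("n must be >= 1")
        if n in self.rates:
            return self.rates[n]
        logger.warning("e_%s(%d) unobserved; using floor rate", self.locus_id, n)
        return self.floor_rate


@dataclass
class ErrorProfile:
    """Panel-wide error profile: locus_id -> :class:`ErrorProfileEntry`."""

    entries: dict[str, ErrorProfileEntry] = field(default_factory=dict)
    floor_rate: float = DEFAULT_FLOOR_RATE

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.entries

    def __getitem__(self, locus_id: str) -> ErrorProfileEntry:
        return self.entries[locus_id]


def true_alleles_of_sample(profile: LocusReadProfile,
                           alpha: float = DEFAULT_TRUE_ALLELE_ALPHA) -> list[str]:
    """Designate the true allele(s) of one single-source sample.

    The top-count allele is always true.  The second-ranked allele is true
    only if it reaches ``alpha`` times the top count (below that the sample
    is treated as homozygous and the runner-up as an artifact) and it is
    not tied with the third-ranked allele (ties for second place are all
    treated as erroneous — a conservative choice that slightly inflates
    e_l).  Count ties for the top are broken lexicographically.
    """
    ranked = sorted(profile.allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if not ranked:
        return []
    true = [ranked[0][0]]
    if len(ranked) > 1:
        second_count = ranked[1][1]
        tied = len(ranked) > 2 and ranked[2][1] == second_count
        if second_count >= alpha * ranked[0][1] and not tied:
            true.append(ranked[1][0])
    return true


def sample_error_ratios(profile: LocusReadProfile,
                        alpha: float = DEFAULT_TRUE_ALLELE_ALPHA) -> dict[int, float]:
    """Per-sample ratio(n): erroneous reads at distance n / total reads."""
    total = profile.total_pairs
    if total == 0:
        return {}
    true = true_alleles_of_sample(profile, alpha)
    ratios: dict[int, float] = {}
    for allele, count in profile.allele_counts.items():
        if allele in true:
            continue
        n = min(hamming(allele, t) for t in true)
        ratios[n] = ratios.get(n, 0.0) + count / total
    return ratios


def _isotonic_non_increasing(ns: Sequence[int], values: Sequence[float]) -> dict[int, float]:
    """Pool-adjacent-violators fit of a non-increasing sequence (equal weights)."""
    order = np.argsort(ns)
    ns_sorted = [ns[i] for i in order]
    vals = [values[i] for i in order]
    blocks: list[list[float]] = []  # [mean, weight]
    for v in vals:
        blocks.append([v, 1.0])
        # enforce non-increasing means: merge while previous mean < current
        while len(blocks) > 1 and blocks[-2][0] < blocks[-1][0]:
            m2, w2 = blocks.pop()
            m1, w1 = blocks.pop()
            blocks.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2])
    fitted = []
    for mean, weight in blocks:
        fitted.extend([mean] * int(round(weight)))
    return dict(zip(ns_sorted, fitted))


def estimate_error_profile_entry(
    profiles: Iterable[LocusReadProfile],
    n_snps: int,
    alpha: float = DEFAULT_TRUE_ALLELE_ALPHA,
    floor_rate: float = DEFAULT_FLOOR_RATE,
    isotonic: bool = True,
) -> ErrorProfileEntry:
    """Estimate e_l(n), n = 1..``n_snps``, for one locus from a collection
    of single-source sample profiles.

    Samples with zero depth at the locus are skipped; a locus with no
    usable sample is returned flagged unusable with floor rates throughout.
    """
    profiles = list(profiles)
    locus_id = profiles[0].locus_id if profiles else ""
    per_sample: list[dict[int, float]] = []
    for prof in profiles:
        if prof.total_pairs == 0:
            continue
        per_sample.append(sample_error_ratios(prof, alpha))
    if not per_sample:
        return ErrorProfileEntry(locus_id, {n: floor_rate for n in range(1, n_snps + 1)},
                                 0, floor_rate, usable=False)
    ns = list(range(1, n_snps + 1))
    means = [float(np.mean([r.get(n, 0.0) for r in per_sample])) for n in ns]
    if isotonic and len(ns) > 1:
        fitted = _isotonic_non_increasing(ns, means)
    else:
        fitted = dict(zip(ns, means))
    # An n with no observed artifact reads carries no evidence of its own;
    # the rarity argument only bounds it above by the rate at smaller n, so
    # it inherits the last observed (fitted) rate rather than dropping to
    # the bare floor — a conservative null for the binomial test that keeps
    # single stray reads at large n from reaching significance.
    rates: dict[int, float] = {}
    carry = floor_rate
    for n in ns:
        if fitted[n] > 0.0:
            carry = max(fitted[n], floor_rate)
        rates[n] = carry
    return ErrorProfileEntry(locus_id, rates, len(per_sample), floor_rate)


def estimate_error_profile(
    sample_profiles: Sequence[Mapping[str, LocusReadProfile]],
    locus_snp_counts: Mapping[str, int],
    alpha: float = DEFAULT_TRUE_ALLELE_ALPHA,
    floor_rate: float = DEFAULT_FLOOR_RATE,
    isotonic: bool = True,
) -> ErrorProfile:
    """Estimate the panel-wide profile from per-sample profile collections.

    ``locus_snp_counts`` maps every panel locus to its SNP count so that
    loci unseen in the data still receive (unusable, floor-rate) entries.
    """
    profile = ErrorProfile(floor_rate=floor_rate)
    for locus_id, k in locus_snp_counts.items():
        per_locus = [
            s[locus_id] for s in sample_profiles if locus_id in s
        ]
        entry = estimate_error_profile_entry(per_locus, k, alpha, floor_rate, isotonic)
        entry.locus_id = locus_id
        profile.entries[locus_id] = entry
    return profile


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_error_profile(profile: ErrorProfile, path: str) -> None:
    rows = [
        {"locus_id": lid, "n": n, "e": e, "n_samples": entry.n_samples_used,
         "usable": entry.usable}
        for lid, entry in sorted(profile.entries.items())
        for n, e in sorted(entry.rates.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_error_profile(path: str, floor_rate: float = DEFAULT_FLOOR_RATE) -> ErrorProfile:
    df = pd.read_csv(path, sep="\t")
    profile = ErrorProfile(floor_rate=floor_rate)
    for lid, grp in df.groupby("locus_id"):
        rates = dict(zip(grp["n"].astype(int), grp["e"].astype(float)))
        profile.entries[str(lid)] = ErrorProfileEntry(
            str(lid), rates, int(grp["n_samples"].iloc[0]), floor_rate,
            usable=bool(grp["usable"].iloc[0]),
        )
    return profile
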