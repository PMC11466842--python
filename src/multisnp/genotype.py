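"""Single-source genotyping by depth and allele-ratio (alpha) rules.

A locus is genotyped only when its major allele holds more than
``min_depth`` (default 50) read pairs.  Every non-major allele gets an
alpha value — its pair count divided by the major's.  All alphas below
0.05: homozygous for the major allele.  Exactly one alpha in
[0.05, 0.2] with all others below 0.05: heterozygous for the major and
that allele.  Any other configuration fails genotyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .extraction import LocusReadProfile

DEFAULT_MIN_DEPTH = 50
ALPHA_HOM_MAX = 0.05   # alphas strictly below this are noise
ALPHA_HET_MAX = 0.2    # upper bound (inclusive) of the heterozygous band


@dataclass
class GenotypeCall:
    locus_id: str
    status: str  # homozygous | heterozygous | failed | low_depth
    alleles: tuple[str, ...] = ()
    major_depth: int = 0
    minor_depth: int = 0
    alpha_values: dict[str, float] = field(default_factory=dict)

    @property
    def genotyped(self) -> bool:
        return self.status in ("homozygous", "heterozygous")


def genotype_locus(
    profile: LocusReadProfile,
    min_depth: int = DEFAULT_MIN_DEPTH,
    alpha_hom: float = ALPHA_HOM_MAX,
    alpha_het: float = ALPHA_HET_MAX,
) -> GenotypeCall:
    """Genotype one locus of a putatively single-source sample.

    The alpha band is closed on both ends: alpha = 0.05 counts toward
    heterozygosity (the homozygous rule requires alphas strictly below
    0.05), and alpha = 0.2 is still heterozygous.
    """
    counts = profile.allele_counts
    if not counts:
        return GenotypeCall(profile.locus_id, "low_depth")
    major = min(counts, key=lambda a: (-counts[a], a))
    major_depth = counts[major]
    if major_depth <= min_depth:
        return GenotypeCall(profile.locus_id, "low_depth", (major,), major_depth)
    alphas = {a: c / major_depth for a, c in counts.items() if a != major}
    in_band = [a for a, v in alphas.items() if alpha_hom <= v <= alpha_het]
    below = [a for a, v in alphas.items() if v < alpha_hom]
    if len(in_band) == 0 and len(below) == len(alphas):
        return GenotypeCall(profile.locus_id, "homozygous", (major,),
                            major_depth, 0, alphas)
    if len(in_band) == 1 and len(below) == len(alphas) - 1:
        minor = in_band[0]
        return GenotypeCall(profile.locus_id, "heterozygous", (major, minor),
                            major_depth, counts[minor], alphas)
    return GenotypeCall(profile.locus_id, "failed", (major,), major_depth, 0, alphas)


def genotype_sample(
    profiles: Mapping[str, LocusReadProfile],
    min_depth: int = DEFAULT_MIN_DEPTH,
    alpha_hom: float = ALPHA_HOM_MAX,
    alpha_het: float = ALPHA_HET_MAX,
) -> dict[str, GenotypeCall]:
    return {
        lid: genotype_locus(p, min_depth, alpha_hom, alpha_het)
        for lid, p in profiles.items()
    }


def genotype_from_calls(callset, profile: LocusReadProfile,
                        min_depth: int = DEFAULT_MIN_DEPTH,
                        alpha_hom: float = ALPHA_HOM_MAX,
                        alpha_het: float = ALPHA_HET_MAX) -> GenotypeCall:
    """Alternative wiring: apply the alpha rules to the caller's accepted
    alleles only (artifact alleles removed from the profile first)."""
    accepted = set(callset.true_alleles)
    filtered = LocusReadProfile(
        profile.locus_id,
        {a: c for a, c in profile.allele_counts.items() if a in accepted},
    )
    return genotype_locus(filtered, min_depth, alpha_hom, alpha_het)


def write_genotypes(genotypes: Mapping[str, GenotypeCall], path: str) -> None:
    import pandas as pd

    rows = [
        {
            "locus_id": lid,
            "status": g.status,
            "alleles": "/".join(g.alleles),
            "major_depth": g.major_depth,
            "minor_depth": g.minor_depth,
            "alphas": ",".join(f"{a}:{v:.4g}" for a, v in sorted(g.alpha_values.items())),
        }
        for lid, g in sorted(genotypes.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str) -> dict[str, GenotypeCall]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"alleles": str, "alphas": str})
    out = {}
    for r in df.itertuples():
        alleles = tuple(str(r.alleles).split("/")) if isinstance(r.alleles, str) and r.alleles else ()
        alphas = {}
        if isinstance(r.alphas, str) and r.alphas:
            for item in r.alphas.split(","):
                a, v = item.rsplit(":", 1)
                alphas[a] = float(v)
        out[str(r.locus_id)] = GenotypeCall(
            str(r.locus_id), str(r.status), alleles,
            int(r.major_depth), int(r.minor_depth), alphas,
        )
    return out
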