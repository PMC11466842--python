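"""Mixture-experiment scoring: detection rates and minor-contributor
allele distinguishability.

All rates count unique allele strings per locus, never reads.  The
overall detection rate follows the convention of comparing what was
detected against the union of the contributors' known alleles: matched
detected alleles over all detected alleles.  Per-contributor detection
conditions on loci where anything was detected.  Minor distinguishability
is the fraction of the minor contributor's *unique* alleles (absent from
every other contributor at that locus) that were called — counted over
all panel loci, so locus dropout of the minor scores against it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)


@dataclass
class ContributorPanel:
    """A contributor's true alleles: locus_id -> set of 1 or 2 alleles."""

    contributor_id: str
    alleles: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass
class MixtureReport:
    mixture_id: str
    overall_detection_rate: float
    contributor_detection: dict[str, float]
    minor_distinguishability: float | None
    per_locus: dict[str, dict] = field(default_factory=dict)


def _called_alleles(called: Mapping[str, object]) -> dict[str, frozenset[str]]:
    """Normalise caller output (AlleleCallSet mapping or plain sets)."""
    out = {}
    for lid, cs in called.items():
        alleles = cs.true_alleles if hasattr(cs, "true_alleles") else cs
        out[lid] = frozenset(alleles)
    return out


def detection_rate(
    called: Mapping[str, object],
    truth: Mapping[str, frozenset[str] | set[str]],
) -> float:
    """Matched detected alleles / all detected alleles.

    ``truth`` is the per-locus union of the contributors' alleles.  Loci
    with no calls contribute nothing; an entirely empty call set is
    undefined.
    """
    calls = _called_alleles(called)
    matched = total = 0
    for lid, alleles in calls.items():
        if not alleles:
            continue
        total += len(alleles)
        matched += len(alleles & frozenset(truth.get(lid, frozenset())))
    if total == 0:
        raise ValueError("detection rate undefined: no alleles detected")
    return matched / total


def truth_union(contributors: Sequence[ContributorPanel]) -> dict[str, frozenset[str]]:
    union: dict[str, set[str]] = {}
    for c in contributors:
        for lid, alleles in c.alleles.items():
            union.setdefault(lid, set()).update(alleles)
    return {lid: frozenset(a) for lid, a in union.items()}


def contributor_detection(
    called: Mapping[str, object],
    contributor: ContributorPanel,
) -> float:
    """Fraction of the contributor's true alleles found among the calls,
    over loci where detection was attempted (>= 1 allele called)."""
    calls = _called_alleles(called)
    found = total = 0
    for lid, truth in contributor.alleles.items():
        detected = calls.get(lid)
        if not detected:
            continue
        total += len(truth)
        found += len(truth & detected)
    return found / total if total else 0.0


def minor_unique_alleles(
    contributors: Sequence[ContributorPanel], minor_id: str
) -> dict[str, frozenset[str]]:
    """Per locus, the minor's alleles carried by no other contributor."""
    minor = next(c for c in contributors if c.contributor_id == minor_id)
    others = [c for c in contributors if c.contributor_id != minor_id]
    unique: dict[str, frozenset[str]] = {}
    for lid, alleles in minor.alleles.items():
        shared = set()
        for o in others:
            shared |= o.alleles.get(lid, frozenset())
        u = alleles - shared
        if u:
            unique[lid] = frozenset(u)
    return unique


def minor_distinguishability(
    called: Mapping[str, object],
    contributors: Sequence[ContributorPanel],
    minor_id: str,
) -> float:
    """Fraction of minor-unique alleles present among the called alleles.

    Counted over every locus where the minor has unique alleles, whether
    or not the locus yielded calls (a dropped-out locus counts as missed).
    Undefined when the minor shares every allele with the other
    contributors.
    """
    unique = minor_unique_alleles(contributors, minor_id)
    if not unique:
        raise ValueError(f"minor {minor_id!r} has no unique alleles")
    calls = _called_alleles(called)
    total = sum(len(a) for a in unique.values())
    found = sum(len(a & calls.get(lid, frozenset())) for lid, a in unique.items())
    return found / total


def evaluate_mixture(
    mixture_id: str,
    called: Mapping[str, object],
    contributors: Sequence[ContributorPanel],
    minor_id: str | None = None,
) -> MixtureReport:
    """Full scoring of one mixture experiment."""
    calls = _called_alleles(called)
    union = truth_union(contributors)
    per_locus = {
        lid: {
            "called": sorted(calls.get(lid, frozenset())),
            "truth": sorted(union.get(lid, frozenset())),
            "matched": sorted(calls.get(lid, frozenset()) & union.get(lid, frozenset())),
        }
        for lid in sorted(set(calls) | set(union))
    }
    minor = None
    if minor_id is not None:
        try:
            minor = minor_distinguishability(called, contributors, minor_id)
        except ValueError:
            logger.warning("minor %s has no unique alleles in %s", minor_id, mixture_id)
    return MixtureReport(
        mixture_id=mixture_id,
        overall_detection_rate=detection_rate(called, union),
        contributor_detection={
            c.contributor_id: contributor_detection(called, c) for c in contributors
        },
        minor_distinguishability=minor,
        per_locus=per_locus,
    )


def write_report(report: MixtureReport, json_path: str) -> None:
    with open(json_path, "w") as fh:
        json.dump(
            {
                "mixture_id": report.mixture_id,
                "overall_detection_rate": report.overall_detection_rate,
                "contributor_detection": report.contributor_detection,
                "minor_distinguishability": report.minor_distinguishability,
                "per_locus": report.per_locus,
            },
            fh,
            indent=2,
        )
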