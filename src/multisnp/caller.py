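"""Iterative binomial allele caller with FDR control.

At each locus the top-count allele is the major allele; every other
observed allele starts as a candidate artifact.  A candidate with count c
tested against template allele T (count C_T, Hamming distance n) is
modelled as Binomial(C_T + c, e_l(n)): a significantly excessive count —
upper tail P(X >= c) — rejects the artifact hypothesis.  Within a round
the candidates' p-values are Benjamini–Hochberg corrected together and
those with q below the FDR threshold (default 0.5%) are accepted as true
minor alleles.  Subsequent rounds re-test the remaining candidates
against their most similar accepted allele; the procedure stops when a
round accepts nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .errors import ErrorProfile, ErrorProfileEntry, hamming
from .extraction import LocusReadProfile

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.005


@dataclass
class AlleleCall:
    allele: str
    count: int
    status: str  # major | minor | artifact
    template: str | None = None
    n: int | None = None
    p_value: float | None = None
    q_value: float | None = None
    iteration: int | None = None


@dataclass
class AlleleCallSet:
    locus_id: str
    calls: list[AlleleCall] = field(default_factory=list)

    @property
    def true_alleles(self) -> list[str]:
        return [c.allele for c in self.calls if c.status in ("major", "minor")]

    @property
    def major(self) -> AlleleCall:
        return next(c for c in self.calls if c.status == "major")


def binomial_tail(c: int, n_total: int, e: float) -> float:
    """Exact upper-tail P(X >= c) for X ~ Binomial(n_total, e)."""
    if not 0 <= c <= n_total:
        raise ValueError(f"require 0 <= c <= n_total, got c={c}, n_total={n_total}")
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"error rate must be in [0, 1], got {e}")
    if c == 0:
        return 1.0
    return float(binom.sf(c - 1, n_total, e))


def _nearest(allele: str, accepted: Sequence[str]) -> tuple[str, int]:
    """Most similar accepted allele; ties broken lexicographically."""
    best = min(accepted, key=lambda t: (hamming(allele, t), t))
    return best, hamming(allele, best)


def call_alleles(
    profile: LocusReadProfile,
    error_entry: ErrorProfileEntry,
    fdr: float = DEFAULT_FDR,
) -> AlleleCallSet:
    """Run the iterative binomial test on one locus profile.

    Ties for the major allele are broken toward the lexicographically
    smallest allele string, making the output invariant to input order.
    """
    if not profile.allele_counts:
        raise ValueError(f"empty profile at {profile.locus_id}")
    counts = profile.allele_counts
    ranked = sorted(counts, key=lambda a: (-counts[a], a))
    major = ranked[0]
    accepted = [major]
    remaining = ranked[1:]
    calls = {major: AlleleCall(major, counts[major], "major", iteration=0)}

    iteration = 0
    while remaining:
        iteration += 1
        tested = []
        for allele in remaining:
            template, n = _nearest(allele, accepted)
            e = error_entry.rate(n)
            c = counts[allele]
            p = binomial_tail(c, counts[template] + c, e)
            tested.append((allele, template, n, p))
        pvals = [t[3] for t in tested]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        newly = []
        for (allele, template, n, p), q in zip(tested, qvals):
            calls[allele] = AlleleCall(
                allele, counts[allele], "artifact", template, n, p, float(q), iteration
            )
            if q < fdr:
                newly.append(allele)
        if not newly:
            break
        for allele in newly:
            calls[allele].status = "minor"
            accepted.append(allele)
        remaining = [a for a in remaining if a not in set(newly)]

    ordered = sorted(calls.values(), key=lambda c: (-c.count, c.allele))
    return AlleleCallSet(profile.locus_id, ordered)


def call_sample(
    profiles: Mapping[str, LocusReadProfile],
    error_profile: ErrorProfile,
    fdr: float = DEFAULT_FDR,
) -> dict[str, AlleleCallSet]:
    """Apply :func:`call_alleles` to every locus of a sample independently."""
    out: dict[str, AlleleCallSet] = {}
    for locus_id, profile in profiles.items():
        if locus_id not in error_profile:
            raise KeyError(f"locus {locus_id} absent from error profile")
        if not profile.allele_counts:
            continue
        out[locus_id] = call_alleles(profile, error_profile[locus_id], fdr)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_calls(callsets: Mapping[str, AlleleCallSet], path: str) -> None:
    import pandas as pd

    rows = [
        {
            "locus_id": lid,
            "allele": c.allele,
            "count": c.count,
            "status": c.status,
            "template": c.template or "",
            "n": c.n if c.n is not None else "",
            "p": c.p_value if c.p_value is not None else "",
            "q": c.q_value if c.q_value is not None else "",
            "iteration": c.iteration,
        }
        for lid, cs in sorted(callsets.items())
        for c in cs.calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> dict[str, AlleleCallSet]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"allele": str, "template": str})
    out: dict[str, AlleleCallSet] = {}
    for lid, grp in df.groupby("locus_id"):
        calls = [
            AlleleCall(
                str(r.allele), int(r.count), str(r.status),
                str(r.template) if isinstance(r.template, str) and r.template else None,
                int(r.n) if pd.notna(r.n) and r.n != "" else None,
                float(r.p) if pd.notna(r.p) and r.p != "" else None,
                float(r.q) if pd.notna(r.q) and r.q != "" else None,
                int(r.iteration),
            )
            for r in grp.itertuples()
        ]
        out[str(lid)] = AlleleCallSet(str(lid), calls)
    return out
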