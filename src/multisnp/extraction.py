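"""Per-locus allele extraction from aligned paired-end amplicon reads.

The allele of a multi-SNP locus is the concatenation of the base calls at
its SNP positions, in genomic order.  A mate is usable only if it is fully
mapped (no clipping) and spans every SNP position; a SNP call is masked when
it lies within, or within 2 bp of, an annotated repeat tract, an indel in
the alignment, or a run of >= 2 consecutive mismatches.  Because sequencing
errors strike the two mates of a pair independently, only pairs whose two
mates report identical alleles are counted — concordance is the first error
filter of the pipeline.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel import PanelLocus, has_homopolymer, has_tandem_repeat

logger = logging.getLogger(__name__)

#: proximity (bp) within which an alignment artifact masks a SNP call
ARTIFACT_PROXIMITY = 2


@dataclass
class ReadPairObservation:
    """Allele strings called from the two mates of one read pair."""

    locus_id: str
    allele_r1: str | None
    allele_r2: str | None
    evaluable: bool = True
    reject_reason: str | None = None

    @property
    def concordant(self) -> bool:
        return (
            self.evaluable
            and self.allele_r1 is not None
            and self.allele_r1 == self.allele_r2
        )


@dataclass
class LocusReadProfile:
    """Concordant read-pair counts per allele string at one locus."""

    locus_id: str
    allele_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_pairs(self) -> int:
        return sum(self.allele_counts.values())

    def __post_init__(self) -> None:
        lengths = {len(a) for a in self.allele_counts}
        if len(lengths) > 1:
            raise ValueError(f"unequal allele lengths at {self.locus_id}")
        if any(c <= 0 for c in self.allele_counts.values()):
            raise ValueError("allele counts must be positive")


# ---------------------------------------------------------------------------
# Single-pair extraction
# ---------------------------------------------------------------------------


def repeat_tracts(seq: str, offset: int = 0, max_homopolymer: int = 6,
                  tandem_max_motif: int = 6, tandem_min_copies: int = 3) -> list[tuple[int, int]]:
    """Annotate homopolymer/tandem tracts on an amplicon sequence.

    Returns 0-based half-open genomic intervals (``offset`` = genomic start
    of ``seq``).  Uses the same detectors as the panel screen.
    """
    import re

    tracts = []
    for m in re.finditer(r"(.)\1{%d,}" % (max_homopolymer - 1), seq.upper()):
        tracts.append((offset + m.start(), offset + m.end()))
    for motif in range(2, tandem_max_motif + 1):
        for m in re.finditer(r"(.{%d})\1{%d,}" % (motif, tandem_min_copies - 1), seq.upper()):
            tracts.append((offset + m.start(), offset + m.end()))
    return tracts


def _mate_allele(read, locus: PanelLocus, reference: str,
                 repeats: Sequence[tuple[int, int]], min_baseq: int = 0) -> tuple[str | None, str | None]:
    """Call the allele string from one mate.

    Returns ``(allele, None)`` on success or ``(None, reason)``.
    """
    if read is None or read.is_unmapped:
        return None, "unmapped"
    cigar = read.cigartuples or []
    if any(op in (4, 5) for op, _ in cigar):  # soft/hard clip => partially mapped
        return None, "partially_mapped"
    span = (read.reference_start, read.reference_end)
    if not all(span[0] <= p < span[1] for p in locus.snp_positions):
        return None, "not_spanning"

    # Map reference positions to read positions; record indel loci.
    ref2read: dict[int, int] = {}
    indel_pos: list[int] = []
    mismatch_cols: list[int] = []
    for qpos, rpos in read.get_aligned_pairs():
        if rpos is None:  # insertion in read
            # attribute the insertion to the following reference column
            continue
        if qpos is None:  # deletion from reference
            indel_pos.append(rpos)
            continue
        ref2read[rpos] = qpos
    # insertions: reference gap between consecutive aligned columns
    prev_r, prev_q = None, None
    for qpos, rpos in read.get_aligned_pairs():
        if rpos is None and prev_r is not None:
            indel_pos.append(prev_r + 1)
        if rpos is not None:
            prev_r = rpos
        if qpos is not None:
            prev_q = qpos

    seq = read.query_sequence
    quals = read.query_qualities
    for rpos, qpos in ref2read.items():
        ref_base = reference[rpos].upper()
        if seq[qpos].upper() != ref_base:
            mismatch_cols.append(rpos)
    mismatch_cols.sort()
    # runs of >= 2 consecutive mismatching aligned columns
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(mismatch_cols):
        j = i
        while j + 1 < len(mismatch_cols) and mismatch_cols[j + 1] == mismatch_cols[j] + 1:
            j += 1
        if j > i:
            runs.append((mismatch_cols[i], mismatch_cols[j] + 1))
        i = j + 1

    bases = []
    for p in locus.snp_positions:
        if any(r[0] - ARTIFACT_PROXIMITY <= p < r[1] + ARTIFACT_PROXIMITY for r in repeats):
            return None, "near_repeat"
        if any(abs(p - ip) <= ARTIFACT_PROXIMITY for ip in indel_pos):
            return None, "near_indel"
        if any(s - ARTIFACT_PROXIMITY <= p < e + ARTIFACT_PROXIMITY for s, e in runs):
            return None, "in_mismatch_run"
        q = ref2read.get(p)
        if q is None:
            return None, "near_indel"
        if quals is not None and min_baseq > 0 and quals[q] < min_baseq:
            return None, "low_baseq"
        bases.append(seq[q].upper())
    return "".join(bases), None


def extract_pair(read1, read2, locus: PanelLocus, reference: str,
                 repeats: Sequence[tuple[int, int]] | None = None,
                 min_baseq: int = 0) -> ReadPairObservation:
    """Convert one aligned read pair into a :class:`ReadPairObservation`.

    ``reference`` is the full sequence of the locus's chromosome.  A pair
    with any masked SNP position is unevaluable as a whole (partial alleles
    are never emitted).
    """
    if repeats is None:
        repeats = repeat_tracts(
            reference[locus.amplicon_start : locus.amplicon_end], locus.amplicon_start
        )
    a1, why1 = _mate_allele(read1, locus, reference, repeats, min_baseq)
    a2, why2 = _mate_allele(read2, locus, reference, repeats, min_baseq)
    if a1 is None or a2 is None:
        return ReadPairObservation(locus.locus_id, a1, a2, evaluable=False,
                                   reject_reason=why1 or why2)
    return ReadPairObservation(locus.locus_id, a1, a2)


# ---------------------------------------------------------------------------
# Profile building
# ---------------------------------------------------------------------------


def build_profile(observations: Iterable[ReadPairObservation],
                  locus_id: str | None = None,
                  discard_log: Counter | None = None) -> LocusReadProfile:
    """Count concordant evaluable pairs per allele.

    Discordant or unevaluable pairs contribute nothing; their reasons are
    tallied into ``discard_log`` when given.
    """
    counts: Counter[str] = Counter()
    for obs in observations:
        if locus_id is None:
            locus_id = obs.locus_id
        elif obs.locus_id != locus_id:
            raise ValueError("observations span multiple loci")
        if obs.concordant:
            counts[obs.allele_r1] += 1
        elif discard_log is not None:
            discard_log[obs.reject_reason or "discordant"] += 1
    return LocusReadProfile(locus_id or "", dict(counts))


def build_profile_from_pairs(locus_id: str, pair_counts: Mapping[tuple[str, str], int],
                             discard_log: Counter | None = None) -> LocusReadProfile:
    """Concordance-filter a weighted table of (allele_r1, allele_r2) pairs.

    Equivalent to :func:`build_profile` on the expanded observation list;
    used for simulator output where pairs arrive pre-aggregated.
    """
    counts: Counter[str] = Counter()
    for (a1, a2), c in pair_counts.items():
        if a1 == a2:
            counts[a1] += c
        elif discard_log is not None:
            discard_log["discordant"] += c
    return LocusReadProfile(locus_id, dict(counts))


def extract_sample(sam_path: str, panel: Sequence[PanelLocus],
                   reference: Mapping[str, str], min_baseq: int = 0
                   ) -> tuple[dict[str, LocusReadProfile], Counter]:
    """Stream a (queryname-pairable) SAM/BAM and build per-locus profiles.

    Mates are paired by query name; each pair is evaluated against every
    panel locus whose SNP positions both mates could span.
    """
    import pysam

    by_chrom: dict[str, list[PanelLocus]] = defaultdict(list)
    for loc in panel:
        by_chrom[loc.chrom].append(loc)
    repeats = {
        loc.locus_id: repeat_tracts(
            reference[loc.chrom][loc.amplicon_start : loc.amplicon_end],
            loc.amplicon_start,
        )
        for loc in panel
    }

    observations: dict[str, list[ReadPairObservation]] = defaultdict(list)
    discard: Counter = Counter()
    pending: dict[str, object] = {}
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        for read in af:
            if read.is_secondary or read.is_supplementary:
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (mate, read) if mate.is_read1 else (read, mate)
            chrom = af.get_reference_name(r1.reference_id) if not r1.is_unmapped else (
                af.get_reference_name(r2.reference_id) if not r2.is_unmapped else None)
            if chrom is None:
                discard["unmapped"] += 1
                continue
            for loc in by_chrom.get(chrom, []):
                lo = min(loc.snp_positions)
                hi = max(loc.snp_positions)
                overlaps = all(
                    (not r.is_unmapped)
                    and r.reference_start <= hi
                    and lo < (r.reference_end or 0)
                    for r in (r1, r2)
                )
                if not overlaps:
                    continue
                obs = extract_pair(r1, r2, loc, reference[chrom],
                                   repeats[loc.locus_id], min_baseq)
                observations[loc.locus_id].append(obs)
    for qname in pending:
        discard["unpaired"] += 1
    profiles = {
        lid: build_profile(obs, lid, discard) for lid, obs in observations.items()
    }
    return profiles, discard


# ---------------------------------------------------------------------------
# Profile I/O
# ---------------------------------------------------------------------------


def write_profiles(profiles: Mapping[str, LocusReadProfile], path: str) -> None:
    rows = [
        {"locus_id": lid, "allele": a, "pair_count": c}
        for lid, prof in sorted(profiles.items())
        for a, c in sorted(prof.allele_counts.items())
    ]
    pd.DataFrame(rows, columns=["locus_id", "allele", "pair_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles(path: str) -> dict[str, LocusReadProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"allele": str})
    profiles: dict[str, LocusReadProfile] = {}
    for lid, grp in df.groupby("locus_id"):
        profiles[str(lid)] = LocusReadProfile(
            str(lid), dict(zip(grp["allele"], grp["pair_count"].astype(int)))
        )
    return profiles
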