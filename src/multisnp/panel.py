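"""Genome-wide screening of multi-SNP (linked-SNP haplotype) markers.

Scans phased population genotypes in fixed-size windows and scores each
window with the D-value: the fraction of the C(N, 2) pairs of individuals
that are distinguishable by at least two single-nucleotide differences
inside the window.  Windows with high D that are free of homopolymer and
tandem-repeat tracts become panel loci, each wrapped in a short amplicon
suitable for single-read coverage.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = "ACGT"

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """A fixed genomic window holding the segregating sites it contains.

    Coordinates are 0-based half-open; ``snp_positions`` are genomic
    positions (0-based), strictly increasing, inside ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    snp_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty window {self.chrom}:{self.start}-{self.end}")
        pos = self.snp_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("snp_positions must be strictly increasing")
        if pos and not (self.start <= pos[0] and pos[-1] < self.end):
            raise ValueError("snp_positions must lie within [start, end)")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowScore:
    """D-value score of one window: ``d_value = t / C(N, 2)``."""

    window: Window
    t: int
    n_pairs: int
    d_value: float


@dataclass(frozen=True)
class PanelLocus:
    """A screened multi-SNP marker with its amplicon interval.

    The allele of the locus is the string of bases observed at
    ``snp_positions`` (in order); single-SNP markers are permitted.
    """

    locus_id: str
    window: Window
    snp_positions: tuple[int, ...]
    amplicon_start: int
    amplicon_end: int

    def __post_init__(self) -> None:
        if self.amplicon_end - self.amplicon_start >= 140:
            raise ValueError("amplicon length must be < 140 bp")
        if not (self.amplicon_start <= self.window.start and self.window.end <= self.amplicon_end):
            raise ValueError("window must be contained in the amplicon")
        if len(self.snp_positions) < 1:
            raise ValueError("a locus needs at least one SNP position")

    @property
    def chrom(self) -> str:
        return self.window.chrom

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)


class PhasedCohort:
    """Phased genotypes of N >= 2 diploid individuals at SNV sites.

    Parameters
    ----------
    samples
        Sample identifiers.
    positions
        Mapping chromosome -> sorted array of 0-based site positions.
    haplotypes
        Mapping chromosome -> byte array of shape (N, 2, S) holding the
        base (one of ``A/C/G/T``) carried by each haplotype at each site.
    """

    def __init__(
        self,
        samples: Sequence[str],
        positions: Mapping[str, np.ndarray],
        haplotypes: Mapping[str, np.ndarray],
    ) -> None:
        if len(samples) < 2:
            raise ValueError("a cohort needs at least 2 individuals")
        self.samples = list(samples)
        self.positions = {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
        self.haplotypes = {}
        for chrom, hap in haplotypes.items():
            hap = np.asarray(hap)
            if hap.shape[:2] != (len(self.samples), 2):
                raise ValueError(f"haplotype array for {chrom} must be (N, 2, S)")
            if hap.shape[2] != len(self.positions[chrom]):
                raise ValueError(f"site count mismatch on {chrom}")
            self.haplotypes[chrom] = hap
        for chrom, pos in self.positions.items():
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on {chrom} are not strictly increasing")

    @property
    def n(self) -> int:
        return len(self.samples)

    @classmethod
    def from_vcf(cls, path: str) -> "PhasedCohort":
        """Load a phased VCF (pipe-separated GT), keeping biallelic SNVs only."""
        import pysam

        vf = pysam.VariantFile(path)
        samples = list(vf.header.samples)
        pos: dict[str, list[int]] = {}
        haps: dict[str, list[np.ndarray]] = {}
        last: dict[str, int] = {}
        for rec in vf:
            if rec.chrom in last and rec.pos < last[rec.chrom]:
                raise ValueError(f"unsorted VCF at {rec.chrom}:{rec.pos}")
            last[rec.chrom] = rec.pos
            alleles = rec.alleles
            if alleles is None or len(alleles) != 2 or any(len(a) != 1 for a in alleles):
                logger.info("skipping non-biallelic-SNV record %s:%s", rec.chrom, rec.pos)
                continue
            col = np.empty((len(samples), 2), dtype="S1")
            ok = True
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or len(gt) != 2 or None in gt:
                    ok = False
                    break
                if not rec.samples[s].phased:
                    raise ValueError(f"unphased genotype at {rec.chrom}:{rec.pos} sample {s}")
                col[i, 0] = alleles[gt[0]].encode()
                col[i, 1] = alleles[gt[1]].encode()
            if not ok:
                logger.info("skipping record with missing GT at %s:%s", rec.chrom, rec.pos)
                continue
            pos.setdefault(rec.chrom, []).append(rec.pos - 1)  # 1-based -> 0-based
            haps.setdefault(rec.chrom, []).append(col)
        positions = {c: np.array(p, dtype=np.int64) for c, p in pos.items()}
        haplotypes = {
            c: np.stack(haps[c], axis=-1) if haps[c] else np.empty((len(samples), 2, 0), dtype="S1")
            for c in pos
        }
        return cls(samples, positions, haplotypes)


# ---------------------------------------------------------------------------
# D-value
# ---------------------------------------------------------------------------


def compute_d_value(
    window_genotypes: Sequence[tuple[Sequence[str], Sequence[str]]] | np.ndarray,
    window: Window | None = None,
    min_differences: int = 2,
    compare: str = "genotype",
) -> WindowScore:
    """Score a window: the fraction of individual pairs distinguishable by
    >= ``min_differences`` single-nucleotide differences.

    ``window_genotypes`` holds, per individual, the two haplotype vectors
    over the window's SNP positions.  With ``compare="genotype"`` (default)
    a position differs between two individuals when their unordered diploid
    genotypes (allele multisets) differ; ``compare="haplotype"`` counts the
    differing positions under the best phase pairing of the four haplotypes.
    """
    hap = _as_hap_array(window_genotypes)
    n = hap.shape[0]
    if n < 2:
        raise ValueError("D-value requires N >= 2 individuals")
    n_pairs = comb(n, 2)
    if window is None:
        s = hap.shape[2]
        window = Window("win", 0, max(s, 1), tuple(range(s)))
    if hap.shape[2] == 0:
        return WindowScore(window, 0, n_pairs, 0.0)

    if compare == "genotype":
        geno = np.sort(hap, axis=1)  # unordered diploid genotype per site
        diff = (geno[:, None] != geno[None, :]).any(axis=2).sum(axis=2)
    elif compare == "haplotype":
        d_same = (hap[:, None] != hap[None, :]).sum(axis=3).sum(axis=2)
        swapped = hap[:, ::-1]
        d_swap = (hap[:, None] != swapped[None, :]).sum(axis=3).sum(axis=2)
        diff = np.minimum(d_same, d_swap)
    else:
        raise ValueError(f"unknown compare mode {compare!r}")

    iu = np.triu_indices(n, k=1)
    t = int((diff[iu] >= min_differences).sum())
    return WindowScore(window, t, n_pairs, t / n_pairs)


def _as_hap_array(window_genotypes) -> np.ndarray:
    """Normalise genotypes to a (N, 2, S) byte array."""
    if isinstance(window_genotypes, np.ndarray) and window_genotypes.ndim == 3:
        return np.asarray(window_genotypes, dtype="S1")
    rows = []
    for h1, h2 in window_genotypes:
        a = [list(h1), list(h2)]
        rows.append(a)
    arr = np.array(rows, dtype="S1")
    if arr.ndim == 2:  # zero-length haplotypes collapse a dimension
        arr = arr.reshape(arr.shape[0], 2, 0)
    lengths = {arr.shape[2]}
    if len(lengths) != 1:
        raise ValueError("haplotype vectors must share one length")
    return arr


# ---------------------------------------------------------------------------
# Genome scan and filtering
# ---------------------------------------------------------------------------


def scan_genome(
    cohort: PhasedCohort,
    window_size: int = 75,
    step: int = 1,
    min_differences: int = 2,
    compare: str = "genotype",
) -> list[WindowScore]:
    """Score every ``window_size`` window containing >= 1 segregating site.

    Windows start on the ``step`` grid anchored at the first site of each
    chromosome and are reported in genomic order.
    """
    scores: list[WindowScore] = []
    for chrom in sorted(cohort.positions):
        pos = cohort.positions[chrom]
        if pos.size == 0:
            continue
        hap = cohort.haplotypes[chrom]
        first = max(0, int(pos[0]) - window_size + 1)
        last = int(pos[-1])
        for start in range(first, last + 1, step):
            end = start + window_size
            lo, hi = np.searchsorted(pos, [start, end])
            if hi <= lo:
                continue
            win = Window(chrom, start, end, tuple(int(p) for p in pos[lo:hi]))
            scores.append(
                compute_d_value(hap[:, :, lo:hi], win, min_differences, compare)
            )
    return scores


def has_homopolymer(seq: str, min_run: int = 6) -> bool:
    """True if ``seq`` contains a single-base run of length >= ``min_run``."""
    return re.search(r"(.)\1{%d,}" % (min_run - 1), seq.upper()) is not None


def has_tandem_repeat(seq: str, max_motif: int = 6, min_copies: int = 3) -> bool:
    """True if a 2..``max_motif`` bp motif repeats >= ``min_copies`` times
    contiguously."""
    seq = seq.upper()
    for m in range(2, max_motif + 1):
        if re.search(r"(.{%d})\1{%d,}" % (m, min_copies - 1), seq):
            return True
    return False


def filter_windows(
    scores: Iterable[WindowScore],
    reference: Mapping[str, str],
    d_min: float = 0.6,
    max_homopolymer: int = 6,
    tandem_max_motif: int = 6,
    tandem_min_copies: int = 3,
    amplicon_max: int = 140,
    locus_prefix: str = "CHM",
    greedy_nonoverlapping: bool = True,
) -> list[PanelLocus]:
    """Retain windows with D >= ``d_min`` whose sequence is free of
    homopolymer runs and tandem repeats, then emit panel loci.

    Overlapping survivors are resolved greedily by descending D (the scan
    steps by 1 bp, so neighbouring windows largely duplicate each other).
    Amplicons are the window plus symmetric flanks, capped below
    ``amplicon_max`` bp and clipped to the reference.
    """
    kept: list[WindowScore] = []
    for ws in scores:
        w = ws.window
        if w.chrom not in reference:
            raise KeyError(f"window chromosome {w.chrom} absent from reference")
        ref = reference[w.chrom]
        if w.end > len(ref):
            raise ValueError(f"window {w.chrom}:{w.start}-{w.end} outside reference")
        if ws.d_value < d_min:
            continue
        seq = ref[w.start : w.end]
        if has_homopolymer(seq, max_homopolymer):
            continue
        if has_tandem_repeat(seq, tandem_max_motif, tandem_min_copies):
            continue
        kept.append(ws)

    if greedy_nonoverlapping:
        kept.sort(key=lambda s: (-s.d_value, s.window.chrom, s.window.start))
        chosen: list[WindowScore] = []
        for ws in kept:
            w = ws.window
            if any(
                c.window.chrom == w.chrom
                and c.window.start < w.end
                and w.start < c.window.end
                for c in chosen
            ):
                continue
            chosen.append(ws)
        kept = chosen
    kept.sort(key=lambda s: (s.window.chrom, s.window.start))

    loci = []
    flank = (amplicon_max - 1 - kept[0].window.size) // 2 if kept else 0
    for i, ws in enumerate(kept, start=1):
        w = ws.window
        ref_len = len(reference[w.chrom])
        a_start = max(0, w.start - flank)
        a_end = min(ref_len, w.end + flank)
        loci.append(
            PanelLocus(
                locus_id=f"{locus_prefix}{i:03d}",
                window=w,
                snp_positions=w.snp_positions,
                amplicon_start=a_start,
                amplicon_end=a_end,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Panel I/O (BED + TSV sidecar)
# ---------------------------------------------------------------------------


def write_panel(loci: Sequence[PanelLocus], out_prefix: str, scores: Mapping[str, WindowScore] | None = None) -> None:
    """Write ``<prefix>.bed`` (amplicons, 0-based half-open) and
    ``<prefix>.tsv`` (window coordinates, SNP positions, D statistics)."""
    with open(out_prefix + ".bed", "w") as bed:
        for loc in loci:
            bed.write(f"{loc.chrom}\t{loc.amplicon_start}\t{loc.amplicon_end}\t{loc.locus_id}\n")
    rows = []
    for loc in loci:
        sc = scores.get(loc.locus_id) if scores else None
        rows.append(
            {
                "locus_id": loc.locus_id,
                "chrom": loc.chrom,
                "window_start": loc.window.start,
                "window_end": loc.window.end,
                "snp_positions": ",".join(map(str, loc.snp_positions)),
                "d_value": sc.d_value if sc else float("nan"),
                "t": sc.t if sc else -1,
                "n_pairs": sc.n_pairs if sc else -1,
            }
        )
    pd.DataFrame(rows).to_csv(out_prefix + ".tsv", sep="\t", index=False)


def read_panel(prefix_or_tsv: str) -> list[PanelLocus]:
    """Read a panel written by :func:`write_panel` (pass the prefix or the
    TSV path; the BED sidecar supplies amplicon intervals if present)."""
    import os

    tsv = prefix_or_tsv if prefix_or_tsv.endswith(".tsv") else prefix_or_tsv + ".tsv"
    bed = tsv[:-4] + ".bed"
    amplicons = {}
    if os.path.exists(bed):
        with open(bed) as fh:
            for line in fh:
                chrom, s, e, name = line.split()[:4]
                amplicons[name] = (int(s), int(e))
    df = pd.read_csv(tsv, sep="\t", dtype={"snp_positions": str})
    loci = []
    for row in df.itertuples():
        snps = tuple(int(x) for x in str(row.snp_positions).split(","))
        win = Window(row.chrom, int(row.window_start), int(row.window_end), snps)
        a = amplicons.get(row.locus_id, (max(0, win.start - 32), win.end + 32))
        loci.append(PanelLocus(row.locus_id, win, snps, a[0], a[1]))
    return loci
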