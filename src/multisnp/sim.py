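"""Synthetic populations, panels, single-source samples and mixtures.

The generator emulates a 567-locus multi-SNP amplicon panel end to end
with full ground truth:

* **Panel** — loci carry 1–5 linked SNPs in a 75 bp window (category mix
  follows the panel's published composition), each SNP biallelic, the
  haplotype alphabet being all ref/alt combinations.  Haplotype
  frequencies are drawn from a symmetric Dirichlet whose per-category
  concentration is set so the expected heterozygosity is realistic for a
  forensic multi-SNP panel (~0.55 for multi-SNP loci).
* **Population** — individuals receive two haplotypes per locus by
  multinomial draw, so Hardy–Weinberg equilibrium holds by construction.
* **Template molecules** — a sample of ``total_input_ng`` nanograms
  contributes Poisson-distributed haploid genome copies per locus
  (3.3 pg per haploid copy), split between a contributor's two
  haplotypes and scaled by each contributor's mass fraction.  Zero
  molecules at a locus is dropout.
* **PCR layer** — each template molecule's allele string mutates once at
  ``pcr_error`` per base.  Both mates of every read pair from that
  molecule inherit the mutation, so it survives concordance filtering —
  this is the artifact class the binomial caller exists to remove.
* **Sequencing layer** — each mate independently mutates at
  ``seq_error`` per base (≈0.1%/base, Illumina-like); discordant pairs
  are emitted and left for the concordance filter to discard.

Read pairs are emitted as aggregated (allele_r1, allele_r2) count tables
by default; an optional writer produces an aligned SAM plus reference
FASTA so the alignment-facing extraction filters can be exercised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .extraction import LocusReadProfile, build_profile_from_pairs
from .mixture import ContributorPanel
from .panel import PanelLocus, PhasedCohort, Window

logger = logging.getLogger(__name__)

BASES = "ACGT"
HAPLOID_MASS_NG = 0.0033  # 3.3 pg per haploid genome copy

#: panel category mix: number of linked SNPs -> locus count (567 total)
DEFAULT_CATEGORY_WEIGHTS: dict[int, float] = {1: 48, 2: 157, 3: 246, 4: 91, 5: 25}

#: symmetric Dirichlet concentration per category, solved so that
#: E[He] = K*alpha/(K*alpha+1) - ... ~= 0.55 for k >= 2 (K = 2**k haplotypes)
#: and 0.40 for single-SNP loci (biallelic He is capped at 0.5)
DEFAULT_CONCENTRATIONS: dict[int, float] = {
    1: 2.0,
    2: 0.6875,
    3: 0.2115,
    4: 0.0887,
    5: 0.0410,
}


@dataclass
class SimConfig:
    """Study conditions for one simulated sample or mixture."""

    seed: int
    n_loci: int = 567
    category_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    concentrations: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATIONS)
    )
    population_size: int = 409
    contributors: Sequence[tuple[str, float]] = (("C1", 1.0),)
    total_input_ng: float = 50.0
    mean_depth: float = 1150.0
    seq_error: float = 0.001
    pcr_error: float = 1e-4
    haploid_mass_ng: float = HAPLOID_MASS_NG
    depth_sigma: float = 0.0  # lognormal per-locus depth spread (0 = homogeneous)
    label: str = ""

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.contributors]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("contributor mass fractions must sum to 1")
        for p in (self.seq_error, self.pcr_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error rates must be probabilities")


@dataclass
class SimLocus:
    """A simulated panel locus with its haplotype alphabet and frequencies."""

    locus: PanelLocus
    haplotypes: tuple[str, ...]
    freqs: np.ndarray

    @property
    def locus_id(self) -> str:
        return self.locus.locus_id

    @property
    def n_snps(self) -> int:
        return self.locus.n_snps


@dataclass
class LocusTruth:
    """Ground truth of one locus in one simulated sample."""

    molecules: dict[str, dict[str, int]]  # contributor -> allele -> template count
    mutant_alleles: list[str] = field(default_factory=list)
    dropout: bool = False


@dataclass
class MixtureTruth:
    contributors: list[tuple[str, float]]
    per_locus: dict[str, LocusTruth] = field(default_factory=dict)
    #: per emitted pair (tracked mode only):
    #: (locus_id, contributor, molecule_id, post_pcr_allele, r1, r2)
    pair_records: list[tuple] | None = None


@dataclass
class SampleReads:
    """Simulator output for one sample: aggregated read-pair tables."""

    pair_counts: dict[str, dict[tuple[str, str], int]]
    truth: MixtureTruth

    def to_profiles(self, discard_log=None) -> dict[str, LocusReadProfile]:
        """Concordance-filter the pair tables into per-locus profiles."""
        profiles = {}
        for lid, pairs in self.pair_counts.items():
            prof = build_profile_from_pairs(lid, pairs, discard_log)
            if prof.allele_counts:
                profiles[lid] = prof
        return profiles


# ---------------------------------------------------------------------------
# Panel and population
# ---------------------------------------------------------------------------


def _category_counts(weights: Mapping[int, float], n_loci: int) -> dict[int, int]:
    """Deterministic largest-remainder apportionment of loci to categories."""
    total = sum(weights.values())
    raw = {k: w * n_loci / total for k, w in weights.items()}
    counts = {k: math.floor(v) for k, v in raw.items()}
    short = n_loci - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


LOCUS_SPACING = 250  # bp between simulated windows on the synthetic contig
WINDOW_SIZE = 75
AMPLICON_FLANK = 32  # 75 + 2*32 = 139 < 140


class SimPopulation:
    """A simulated panel plus a phased population over it."""

    def __init__(self, config: SimConfig, panel: list[SimLocus],
                 hap_idx: np.ndarray, depth_mult: np.ndarray) -> None:
        self.config = config
        self.panel = panel
        self.hap_idx = hap_idx  # (N, L, 2) haplotype indices
        self.depth_mult = depth_mult
        self.sample_ids = [f"IND{i + 1:04d}" for i in range(hap_idx.shape[0])]
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_individuals(self) -> int:
        return self.hap_idx.shape[0]

    def individual_alleles(self, sample_id: str, locus_index: int) -> tuple[str, str]:
        i = self._index[sample_id]
        sl = self.panel[locus_index]
        h = self.hap_idx[i, locus_index]
        return sl.haplotypes[h[0]], sl.haplotypes[h[1]]

    def contributor_panel(self, sample_id: str) -> ContributorPanel:
        alleles = {}
        for li, sl in enumerate(self.panel):
            a, b = self.individual_alleles(sample_id, li)
            alleles[sl.locus_id] = frozenset((a, b))
        return ContributorPanel(sample_id, alleles)

    def cohort(self) -> PhasedCohort:
        """Expose the population as a phased cohort for the window screen."""
        positions = []
        for sl in self.panel:
            positions.extend(sl.locus.snp_positions)
        positions = np.array(positions, dtype=np.int64)
        n = self.n_individuals
        haps = np.empty((n, 2, positions.size), dtype="S1")
        col = 0
        for li, sl in enumerate(self.panel):
            k = sl.n_snps
            for i in range(n):
                for s in range(2):
                    hap = sl.haplotypes[self.hap_idx[i, li, s]]
                    haps[i, s, col : col + k] = list(hap)
            col += k
        chrom = self.panel[0].locus.chrom
        return PhasedCohort(self.sample_ids, {chrom: positions}, {chrom: haps})


def simulate_population(config: SimConfig) -> SimPopulation:
    """Draw the panel (loci, haplotype frequencies) and the population."""
    rng = np.random.default_rng(config.seed)
    counts = _category_counts(config.category_weights, config.n_loci)
    ks: list[int] = []
    for k in sorted(counts):
        ks.extend([k] * counts[k])
    rng.shuffle(ks)

    panel: list[SimLocus] = []
    for i, k in enumerate(ks):
        start = 50 + i * LOCUS_SPACING
        end = start + WINDOW_SIZE
        # SNPs on a 3 bp grid so linked variants never sit adjacent
        offsets = np.sort(rng.choice(WINDOW_SIZE // 3, size=k, replace=False)) * 3
        snps = tuple(int(start + o) for o in offsets)
        locus = PanelLocus(
            locus_id=f"CHM{i + 1:03d}",
            window=Window("chrS", start, end, snps),
            snp_positions=snps,
            amplicon_start=start - AMPLICON_FLANK,
            amplicon_end=end + AMPLICON_FLANK,
        )
        # biallelic SNPs: ref/alt base per site, haplotypes = all combos
        site_bases = []
        for _ in range(k):
            ref, alt = rng.choice(4, size=2, replace=False)
            site_bases.append((BASES[ref], BASES[alt]))
        haplotypes = tuple(
            "".join(site_bases[j][(h >> j) & 1] for j in range(k))
            for h in range(2 ** k)
        )
        alpha = config.concentrations.get(k, 0.5)
        freqs = rng.dirichlet(np.full(2 ** k, alpha))
        panel.append(SimLocus(locus, haplotypes, freqs))

    n = config.population_size
    hap_idx = np.empty((n, len(panel), 2), dtype=np.int32)
    for li, sl in enumerate(panel):
        hap_idx[:, li, :] = rng.choice(len(sl.haplotypes), size=(n, 2), p=sl.freqs)

    if config.depth_sigma > 0:
        mu = -0.5 * config.depth_sigma ** 2  # unit-mean lognormal
        depth_mult = rng.lognormal(mu, config.depth_sigma, size=len(panel))
    else:
        depth_mult = np.ones(len(panel))
    return SimPopulation(config, panel, hap_idx, depth_mult)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _mutate(rng: np.random.Generator, base: str) -> str:
    others = [b for b in BASES if b != base]
    return others[rng.integers(3)]


def simulate_reads(
    population: SimPopulation,
    contributors: Sequence[tuple[str, float]] | None = None,
    rng: np.random.Generator | int | None = None,
    total_input_ng: float | None = None,
    mean_depth: float | None = None,
    seq_error: float | None = None,
    pcr_error: float | None = None,
    track_pairs: bool = False,
) -> SampleReads:
    """Simulate one sample's (possibly mixed) amplicon read pairs.

    ``contributors`` are (individual id, mass fraction) entries; defaults
    come from the population's :class:`SimConfig`.  With ``track_pairs``
    every emitted pair carries its source molecule in the truth record
    (slower; meant for small validation runs).
    """
    cfg = population.config
    if contributors is None:
        contributors = [(population.sample_ids[0], 1.0)] if cfg.contributors[0][0] not in population._index else list(cfg.contributors)
    total_ng = cfg.total_input_ng if total_input_ng is None else total_input_ng
    depth = cfg.mean_depth if mean_depth is None else mean_depth
    e_seq = cfg.seq_error if seq_error is None else seq_error
    e_pcr = cfg.pcr_error if pcr_error is None else pcr_error
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)

    panel = population.panel
    L = len(panel)
    C = len(contributors)
    karr = np.array([sl.n_snps for sl in panel])

    # haplotype strings per contributor/slot/locus
    ind_idx = [population._index[sid] for sid, _ in contributors]
    # Poisson template molecules: per haplotype lambda = mass*frac/(2*haploid_mass)
    mols = np.empty((C, 2, L), dtype=np.int64)
    for ci, (_, frac) in enumerate(contributors):
        lam = total_ng * frac / (2.0 * cfg.haploid_mass_ng)
        mols[ci] = rng.poisson(lam, size=(2, L))
    pcr_events = rng.binomial(mols * karr[None, None, :], e_pcr)
    n_pairs_per_locus = rng.poisson(depth * population.depth_mult).astype(np.int64)

    truth = MixtureTruth(list(contributors), pair_records=[] if track_pairs else None)
    pair_counts: dict[str, dict[tuple[str, str], int]] = {}

    for li in range(L):
        sl = panel[li]
        k = int(karr[li])
        base_groups: dict[str, int] = {}
        locus_truth = LocusTruth(molecules={})
        mutant_groups: list[str] = []
        for ci, (sid, _) in enumerate(contributors):
            per_contrib = locus_truth.molecules.setdefault(sid, {})
            for slot in (0, 1):
                m = int(mols[ci, slot, li])
                if m == 0:
                    continue
                allele = sl.haplotypes[population.hap_idx[ind_idx[ci], li, slot]]
                per_contrib[allele] = per_contrib.get(allele, 0) + m
                ev = int(pcr_events[ci, slot, li])
                if ev:
                    ev = min(ev, m * k)
                    slots = rng.choice(m * k, size=ev, replace=False)
                    by_mol: dict[int, list[int]] = {}
                    for s in slots:
                        by_mol.setdefault(int(s) // k, []).append(int(s) % k)
                    for hit_bases in by_mol.values():
                        s = list(allele)
                        for bp in hit_bases:
                            s[bp] = _mutate(rng, s[bp])
                        mutant_groups.append("".join(s))
                    m -= len(by_mol)
                if m:
                    base_groups[allele] = base_groups.get(allele, 0) + m
        locus_truth.mutant_alleles = mutant_groups
        total_mol = sum(base_groups.values()) + len(mutant_groups)
        if total_mol == 0:
            locus_truth.dropout = True
            truth.per_locus[sl.locus_id] = locus_truth
            continue

        alleles = list(base_groups) + mutant_groups
        weights = np.array(
            [base_groups[a] for a in base_groups] + [1] * len(mutant_groups),
            dtype=float,
        )
        n_pairs = int(n_pairs_per_locus[li])
        assign = rng.multinomial(n_pairs, weights / total_mol)
        counts: dict[tuple[str, str], int] = {}
        seq_ev = rng.binomial(assign * 2 * k, e_seq)
        for g, src in enumerate(alleles):
            n_g = int(assign[g])
            if n_g == 0:
                continue
            ev = int(seq_ev[g])
            clean = n_g
            if ev:
                slots = rng.choice(n_g * 2 * k, size=ev, replace=False)
                affected: dict[int, list[tuple[int, int]]] = {}
                for s in slots:
                    s = int(s)
                    pair, rem = divmod(s, 2 * k)
                    mate, bp = divmod(rem, k)
                    affected.setdefault(pair, []).append((mate, bp))
                clean = n_g - len(affected)
                for subs in affected.values():
                    mates = [list(src), list(src)]
                    for mate, bp in subs:
                        mates[mate][bp] = _mutate(rng, mates[mate][bp])
                    key = ("".join(mates[0]), "".join(mates[1]))
                    counts[key] = counts.get(key, 0) + 1
                    if track_pairs:
                        truth.pair_records.append(
                            (sl.locus_id, _group_source(g, base_groups, contributors, locus_truth),
                             g, src, key[0], key[1])
                        )
            if clean:
                counts[(src, src)] = counts.get((src, src), 0) + clean
                if track_pairs:
                    for _ in range(clean):
                        truth.pair_records.append(
                            (sl.locus_id, _group_source(g, base_groups, contributors, locus_truth),
                             g, src, src, src)
                        )
        pair_counts[sl.locus_id] = counts
        truth.per_locus[sl.locus_id] = locus_truth
    return SampleReads(pair_counts, truth)


def _group_source(g, base_groups, contributors, locus_truth) -> str:
    """Best-effort contributor attribution of a molecule group (tracked mode)."""
    alleles = list(base_groups)
    if g < len(alleles):
        allele = alleles[g]
        for sid, per in locus_truth.molecules.items():
            if allele in per:
                return sid
    return "pcr_mutant"


def simulate_sample_profiles(
    population: SimPopulation,
    contributors: Sequence[tuple[str, float]],
    rng: np.random.Generator | int | None = None,
    **overrides,
) -> tuple[dict[str, LocusReadProfile], MixtureTruth]:
    """Simulate reads and run them through concordance extraction."""
    reads = simulate_reads(population, contributors, rng=rng, **overrides)
    return reads.to_profiles(), reads.truth


# ---------------------------------------------------------------------------
# Experimental design grids
# ---------------------------------------------------------------------------

#: mixture ratios (%) and total inputs (ng) of the 75-sample mixture study
TABLE1_ROWS: list[tuple[tuple[float, ...], tuple[float, ...]]] = [
    ((90, 10), (5, 2, 1, 0.5, 0.2, 0.1, 0.05)),
    ((95, 5), (5, 2, 1, 0.5, 0.2, 0.1)),
    ((98, 2), (5, 2, 1, 0.5, 0.2)),
    ((99, 1), (5, 2, 1, 0.5)),
    ((99.5, 0.5), (5, 2, 1)),
    ((70, 20, 10), (5, 2, 1, 0.5, 0.2, 0.1, 0.05)),
    ((85, 10, 5), (5, 2, 1, 0.5, 0.2, 0.1)),
    ((94, 4, 2), (5, 2, 1, 0.5, 0.2)),
    ((97, 2, 1), (5, 2, 1, 0.5)),
    ((98.5, 1, 0.5), (5, 2, 1)),
    ((50, 20, 20, 10), (5, 2, 1, 0.5, 0.2, 0.1, 0.05)),
    ((65, 20, 10, 5), (5, 2, 1, 0.5, 0.2, 0.1)),
    ((86, 8, 4, 2), (5, 2, 1, 0.5, 0.2)),
    ((93, 4, 2, 1), (5, 2, 1)),
    ((96.5, 2, 1, 0.5), (5, 2)),
    ((20, 20, 20, 20, 20), (5,)),
    ((10,) * 10, (10,)),
]

#: DNA inputs (ng) of the sensitivity dilution series
DILUTION_INPUTS: tuple[float, ...] = (
    5, 2.5, 1.25, 0.625, 0.3125, 0.15625, 0.078125, 0.0390625,
    0.01953125, 0.00976563,
)


def design_grid(kind: str, seed: int = 0) -> list[SimConfig]:
    """Return the experimental design grid as simulator configurations.

    ``table1``: the 75-mixture study (25 two-person, 25 three-person,
    23 four-person, one balanced 5-person, one balanced 10-person).
    ``dilution``: the sensitivity series, 2 single-source samples x
    10 inputs x 3 replicates = 60 configurations.  Contributor ids are
    placeholders (``C1``..``Cn`` / ``S1``, ``S2``) to be mapped onto
    population individuals at run time.
    """
    configs: list[SimConfig] = []
    if kind == "table1":
        for ratios, inputs in TABLE1_ROWS:
            for ng in inputs:
                contribs = tuple(
                    (f"C{i + 1}", r / 100.0) for i, r in enumerate(ratios)
                )
                label = f"{len(ratios)}p_" + ":".join(f"{r:g}" for r in ratios) + f"_{ng:g}ng"
                configs.append(
                    SimConfig(seed=seed, contributors=contribs,
                              total_input_ng=float(ng), label=label)
                )
    elif kind == "dilution":
        for s in ("S1", "S2"):
            for ng in DILUTION_INPUTS:
                for rep in (1, 2, 3):
                    configs.append(
                        SimConfig(seed=seed, contributors=((s, 1.0),),
                                  total_input_ng=float(ng),
                                  label=f"{s}_{ng:g}ng_rep{rep}")
                    )
    else:
        raise ValueError(f"unknown design grid {kind!r}")
    return configs


# ---------------------------------------------------------------------------
# Optional aligned-read output (SAM + reference FASTA)
# ---------------------------------------------------------------------------


def build_reference(population: SimPopulation, rng: np.random.Generator | int | None = None) -> str:
    """Synthesize the panel's contig, keeping SNP neighbourhoods free of
    repeat tracts so alignment-artifact masking stays quiet."""
    from .extraction import repeat_tracts

    rng = np.random.default_rng(rng if rng is not None else population.config.seed + 1)
    length = 50 + len(population.panel) * LOCUS_SPACING + 200
    seq = list(rng.choice(list(BASES), size=length))
    for sl in population.panel:
        loc = sl.locus
        # impose the ref base of each SNP
        for j, p in enumerate(loc.snp_positions):
            seq[p] = sl.haplotypes[0][j]
        for _ in range(50):  # resample amplicon until no tract near a SNP
            amp = "".join(seq[loc.amplicon_start : loc.amplicon_end])
            tracts = repeat_tracts(amp, loc.amplicon_start)
            bad = any(
                t[0] - 2 <= p < t[1] + 2
                for t in tracts
                for p in loc.snp_positions
            )
            if not bad:
                break
            for i in range(loc.amplicon_start, loc.amplicon_end):
                if i not in loc.snp_positions:
                    seq[i] = BASES[rng.integers(4)]
        else:  # pragma: no cover
            logger.warning("could not clean repeats near %s", loc.locus_id)
    return "".join(seq)


def write_sam(population: SimPopulation, reads: SampleReads, reference: str,
              sam_path: str, fasta_path: str | None = None) -> None:
    """Write the sample's pairs as full-amplicon alignments (text SAM)."""
    import pysam

    chrom = population.panel[0].locus.chrom
    if fasta_path:
        with open(fasta_path, "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, len(reference), 60):
                fh.write(reference[i : i + 60] + "\n")

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": len(reference)}]}
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for sl in population.panel:
            pairs = reads.pair_counts.get(sl.locus_id)
            if not pairs:
                continue
            loc = sl.locus
            amp = reference[loc.amplicon_start : loc.amplicon_end]
            offs = [p - loc.amplicon_start for p in loc.snp_positions]
            serial = 0
            for (a1, a2), count in sorted(pairs.items()):
                for _ in range(count):
                    serial += 1
                    qname = f"{sl.locus_id}:{serial}"
                    for mate_i, allele in ((0, a1), (1, a2)):
                        s = list(amp)
                        for j, off in enumerate(offs):
                            s[off] = allele[j]
                        read = pysam.AlignedSegment(out.header)
                        read.query_name = qname
                        read.query_sequence = "".join(s)
                        read.query_qualities = pysam.qualitystring_to_array("I" * len(s))
                        read.reference_id = 0
                        read.reference_start = loc.amplicon_start
                        read.cigartuples = [(0, len(s))]
                        read.flag = 99 if mate_i == 0 else 147
                        read.next_reference_id = 0
                        read.next_reference_start = loc.amplicon_start
                        read.template_length = len(s) if mate_i == 0 else -len(s)
                        out.write(read)
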