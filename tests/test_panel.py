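"""Window scanning, D-value scoring and panel filtering."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multisnp import (
    PhasedCohort,
    Window,
    compute_d_value,
    filter_windows,
    scan_genome,
)
from multisnp.panel import has_homopolymer, has_tandem_repeat, read_panel, write_panel


def brute_force_d(genotypes, min_diff=2):
    """Exhaustive O(N^2 S) oracle: compare unordered diploid genotypes."""
    n = len(genotypes)
    t = 0
    for (h1a, h1b), (h2a, h2b) in itertools.combinations(genotypes, 2):
        diffs = sum(
            sorted((a, b)) != sorted((c, d))
            for a, b, c, d in zip(h1a, h1b, h2a, h2b)
        )
        if diffs >= min_diff:
            t += 1
    return t, n * (n - 1) // 2


class TestDValue:
    def test_identical_cohort_scores_zero(self):
        geno = [("ACT", "ACT")] * 10
        ws = compute_d_value(geno)
        assert (ws.t, ws.d_value) == (0, 0.0)

    def test_single_pair_two_differences(self):
        ws = compute_d_value([("AA", "AA"), ("TT", "TT")])
        assert (ws.t, ws.n_pairs, ws.d_value) == (1, 1, 1.0)

    def test_one_difference_is_not_distinguishable(self):
        ws = compute_d_value([("AA", "AA"), ("TA", "AA")])
        assert ws.t == 0

    def test_toy_cohort_matches_enumeration(self):
        geno = [
            ("ACT", "ACT"),
            ("GCT", "ACA"),
            ("GTT", "GTA"),
            ("ACT", "GCA"),
            ("GTA", "GTA"),
        ]
        ws = compute_d_value(geno)
        t, n_pairs = brute_force_d(geno)
        assert (ws.t, ws.n_pairs) == (t, n_pairs)
        assert ws.d_value == pytest.approx(t / n_pairs)

    def test_rejects_single_individual(self):
        with pytest.raises(ValueError):
            compute_d_value([("ACT", "ACT")])

    def test_empty_window_scores_zero(self):
        ws = compute_d_value([("", ""), ("", "")])
        assert (ws.t, ws.d_value) == (0, 0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 20),
        s=st.integers(1, 10),
        data=st.data(),
    )
    def test_matches_oracle_on_random_fixtures(self, n, s, data):
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        geno = [
            tuple("".join(row) for row in bases[rng.integers(0, 4, size=(2, s))])
            for _ in range(n)
        ]
        ws = compute_d_value(geno)
        t, n_pairs = brute_force_d(geno)
        assert (ws.t, ws.n_pairs) == (t, n_pairs)
        assert 0.0 <= ws.d_value <= 1.0

    def test_invariant_under_relabeling(self, rng):
        bases = np.array(list("ACGT"))
        geno = [
            tuple("".join(row) for row in bases[rng.integers(0, 4, size=(2, 4))])
            for _ in range(8)
        ]
        d0 = compute_d_value(geno).d_value
        perm = rng.permutation(len(geno))
        assert compute_d_value([geno[i] for i in perm]).d_value == pytest.approx(d0)

    def test_duplicating_an_individual_never_increases_d(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(10):
            geno = [
                tuple("".join(row) for row in bases[rng.integers(0, 4, size=(2, 3))])
                for _ in range(6)
            ]
            d0 = compute_d_value(geno).d_value
            d1 = compute_d_value(geno + [geno[0]]).d_value
            assert d1 <= d0 + 1e-12


class TestScan:
    def _cohort(self, positions, haps):
        return PhasedCohort(
            [f"s{i}" for i in range(haps.shape[0])],
            {"chr1": np.array(positions)},
            {"chr1": haps},
        )

    def test_empty_variant_set_yields_no_windows(self):
        cohort = self._cohort([], np.empty((3, 2, 0), dtype="S1"))
        assert scan_genome(cohort) == []

    def test_single_site_never_distinguishes(self, rng):
        haps = np.array(list("ACGT"))[rng.integers(0, 4, size=(6, 2, 1))].astype("S1")
        cohort = self._cohort([100], haps)
        scores = scan_genome(cohort, window_size=75, step=10)
        assert scores and all(s.t == 0 and s.d_value == 0.0 for s in scores)

    def test_windows_match_isolated_recomputation(self, rng):
        positions = [10, 25, 40, 90, 130, 170]
        haps = np.array(list("ACGT"))[rng.integers(0, 4, size=(5, 2, 6))].astype("S1")
        cohort = self._cohort(positions, haps)
        scores = scan_genome(cohort, window_size=75, step=1)
        pos = np.array(positions)
        starts = [s.window.start for s in scores]
        assert starts == sorted(starts)
        for s in scores:
            lo, hi = np.searchsorted(pos, [s.window.start, s.window.end])
            expected = compute_d_value(haps[:, :, lo:hi])
            assert (s.t, s.d_value) == (expected.t, expected.d_value)
        # every window holding a site is present
        covered = {st for st in range(max(0, 10 - 74), 171) if any(st <= p < st + 75 for p in positions)}
        assert covered == set(starts)


class TestFilters:
    def test_sequence_filters(self):
        assert has_homopolymer("TTAAAAAAGG")
        assert not has_homopolymer("TTAAAGG")
        assert has_tandem_repeat("ACACAC")
        assert has_tandem_repeat("GATGATGATC")
        assert not has_tandem_repeat("ACGTACGA")

    def test_threshold_and_sequence_rules(self):
        from multisnp.panel import WindowScore

        ref = {"chr1": "ACGT" * 40 + "AAAAAAAA" + "ACGT" * 40}
        good = WindowScore(Window("chr1", 0, 10, (2, 5)), 8, 10, 0.8)
        low = WindowScore(Window("chr1", 20, 30, (22,)), 5, 10, 0.59)
        poly = WindowScore(Window("chr1", 158, 170, (159,)), 8, 10, 0.8)
        loci = filter_windows([good, low, poly], ref)
        assert [l.window.start for l in loci] == [0]
        assert loci[0].locus_id == "CHM001"

    def test_manual_filter_on_ten_windows(self):
        from multisnp.panel import WindowScore

        rng = np.random.default_rng(5)
        ref_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        ref = {"chr1": ref_seq}
        scores = []
        for i in range(10):
            start = i * 150
            d = [0.9, 0.61, 0.6, 0.59, 0.3, 0.95, 0.8, 0.5, 1.0, 0.7][i]
            scores.append(
                WindowScore(Window("chr1", start, start + 75, (start + 9, start + 30)), 0, 1, d)
            )
        expected = [
            s.window.start
            for s in scores
            if s.d_value >= 0.6
            and not has_homopolymer(ref_seq[s.window.start : s.window.end])
            and not has_tandem_repeat(ref_seq[s.window.start : s.window.end])
        ]
        loci = filter_windows(scores, ref)
        assert [l.window.start for l in loci] == sorted(expected)
        # amplicons obey the cap and contain their windows
        for loc in loci:
            assert loc.amplicon_end - loc.amplicon_start < 140
            assert loc.amplicon_start <= loc.window.start <= loc.window.end <= loc.amplicon_end

    def test_window_outside_reference_errors(self):
        from multisnp.panel import WindowScore

        ws = WindowScore(Window("chr1", 0, 75, (10,)), 1, 1, 1.0)
        with pytest.raises(ValueError):
            filter_windows([ws], {"chr1": "ACGT"})


class TestPanelIO:
    def test_round_trip(self, tmp_path, small_population):
        loci = [sl.locus for sl in small_population.panel[:5]]
        prefix = str(tmp_path / "panel")
        write_panel(loci, prefix)
        back = read_panel(prefix)
        assert [l.locus_id for l in back] == [l.locus_id for l in loci]
        assert all(
            a.snp_positions == b.snp_positions
            and (a.amplicon_start, a.amplicon_end) == (b.amplicon_start, b.amplicon_end)
            for a, b in zip(back, loci)
        )


class TestVcfScreen:
    def test_vcf_to_panel_rediscovers_simulated_loci(self, tmp_path, small_population):
        """Full screening path: phased VCF -> scan -> D filter."""
        pop = small_population
        cohort = pop.cohort()
        chrom = "chrS"
        vcf = tmp_path / "cohort.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(cohort.samples)
                + "\n"
            )
            pos = cohort.positions[chrom]
            haps = cohort.haplotypes[chrom]
            for j, p in enumerate(pos):
                bases = sorted({b.decode() for b in haps[:, :, j].ravel()})
                if len(bases) == 1:
                    bases.append("N")  # monomorphic in sample: pick dummy alt
                ref, alt = bases[0], bases[1]
                if len(bases) > 2:
                    continue
                code = {ref: "0", alt: "1"}
                gts = "\t".join(
                    f"{code[haps[i, 0, j].decode()]}|{code[haps[i, 1, j].decode()]}"
                    for i in range(haps.shape[0])
                )
                fh.write(f"{chrom}\t{p + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
        loaded = PhasedCohort.from_vcf(str(vcf))
        assert loaded.samples == cohort.samples
        scores = scan_genome(loaded, window_size=75, step=25)
        # every simulated locus's SNP set is covered by some scanned window
        for sl in pop.panel[:10]:
            covering = [
                s
                for s in scores
                if set(sl.locus.snp_positions) <= set(s.window.snp_positions)
            ]
            assert covering, f"no scanned window covers {sl.locus_id}"
            # D of a window holding exactly this locus's sites matches a
            # direct recomputation on the loaded cohort
            pos = loaded.positions["chrS"]
            for s in covering[:1]:
                lo, hi = np.searchsorted(pos, [s.window.start, s.window.end])
                direct = compute_d_value(loaded.haplotypes["chrS"][:, :, lo:hi])
                assert s.t == direct.t
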