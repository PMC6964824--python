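import itertools

import numpy as np
import pytest
from scipy import special

from boundaryalt.io_formats import (GenomicInterval, IntervalCollection,
                                    MutationRecord)
from boundaryalt.motif_engine import MotifSite
from boundaryalt.mutation_analysis import (chi_square_homogeneity,
                                           classify_titv, count_per_patient,
                                           enrichment_gof_test,
                                           expected_in_fraction,
                                           genes_near_mutated_sites,
                                           positional_profile,
                                           promoters_from_tss,
                                           stratify_by_region, titv_table)


def make_site(start, in_boundary, active=True, chrom="chr1", strand="+",
              score=1.0):
    s = MotifSite(GenomicInterval(chrom, start, start + 19), strand, score, 0.9)
    s.active = active
    s.in_boundary = in_boundary
    return s


def mut(sample, pos, ref="A", alt="G", chrom="chr1"):
    return MutationRecord(sample, chrom, pos, ref, alt)


class TestChiSquare:
    def test_perfect_homogeneity(self):
        res = chi_square_homogeneity([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.dof == 1

    def test_2x2_uses_yates_by_default(self):
        res = chi_square_homogeneity([[260, 300], [212, 119]])
        assert res.method == "chi2_yates"
        res3 = chi_square_homogeneity([[10, 5], [8, 9], [3, 12]])
        assert res3.method == "chi2" and res3.dof == 2

    def test_matches_textbook_formula_on_random_tables(self):
        # independent oracle: explicit Pearson statistic + regularised
        # incomplete gamma survival function
        rng = np.random.default_rng(8)
        for _ in range(200):
            R = int(rng.integers(2, 8))
            t = rng.integers(1, 60, size=(R, 2)).astype(float)
            res = chi_square_homogeneity(t, yates=False)
            grand = t.sum()
            stat = 0.0
            for i in range(R):
                for j in range(2):
                    e = t[i].sum() * t[:, j].sum() / grand
                    stat += (t[i, j] - e) ** 2 / e
            p = special.gammaincc((R - 1) / 2.0, stat / 2.0)
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            chi_square_homogeneity([[1, 2]])                 # single row
        with pytest.raises(ValueError):
            chi_square_homogeneity([[0, 0], [1, 2]])         # zero row
        with pytest.raises(ValueError):
            chi_square_homogeneity([[1, 0], [2, 0]])         # zero column

    def test_low_expected_flagged(self):
        assert chi_square_homogeneity([[2, 3], [3, 2]]).low_expected


class TestEnrichmentGof:
    def test_matches_by_hand_single_patient(self):
        # one patient, 30 mutations split 20/10 against an even split
        res = enrichment_gof_test([[20, 10], [15, 15]], 0.5)
        stat = ((20 - 15) ** 2 / 15 + (10 - 15) ** 2 / 15) + 0.0
        assert res.statistic == pytest.approx(stat)
        assert res.dof == 2

    def test_detects_shared_multiplier_where_homogeneity_cannot(self):
        # every patient enriched 2x in-boundary: homogeneous across rows,
        # but far from the composition-expected 1:2 split
        table = np.array([[40, 40]] * 12)
        q = 1 / 3
        hom = chi_square_homogeneity(table, yates=False)
        gof = enrichment_gof_test(table, q)
        assert hom.p_value == pytest.approx(1.0)
        assert gof.p_value < 1e-10


class TestPerPatientCounting:
    def test_retention_rule_discards_low_patients(self):
        sites = [make_site(0, True), make_site(100, False)]
        muts = [mut("P1", 5)] * 4 + [mut("P1", 105)] * 9
        cont = count_per_patient(muts, sites, min_count=5)
        assert cont.discarded_patients == ["P1"]
        assert cont.retained_patients == []

    def test_exactly_five_and_five_retained(self):
        sites = [make_site(0, True), make_site(100, False)]
        muts = [mut("P1", 5)] * 5 + [mut("P1", 105)] * 5
        cont = count_per_patient(muts, sites, min_count=5)
        assert cont.retained_patients == ["P1"]
        assert cont.table.tolist() == [[5, 5]]

    def test_both_rule_keeps_patient_with_one_good_category(self):
        sites = [make_site(0, True), make_site(100, False)]
        muts = [mut("P1", 5)] * 2 + [mut("P1", 105)] * 9
        assert count_per_patient(muts, sites, min_count=5,
                                 rule="both").retained_patients == ["P1"]

    def test_inactive_sites_ignored(self):
        sites = [make_site(0, True, active=False), make_site(100, False)]
        muts = [mut("P1", 5)] * 10 + [mut("P1", 105)] * 10
        cont = count_per_patient(muts, sites, min_count=5)
        assert cont.table.tolist() == [] or cont.retained_patients == []

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(13)
        sites = [make_site(int(s), bool(rng.random() < 0.5))
                 for s in range(0, 4000, 200)]
        muts = [mut(f"P{rng.integers(0, 20):02d}", int(rng.integers(0, 4000)))
                for _ in range(2000)]
        cont = count_per_patient(muts, sites, min_count=0)
        expected = {}
        for m in muts:
            for s in sites:
                if s.active and s.interval.start <= m.pos < s.interval.end:
                    row = expected.setdefault(m.sample_id, [0, 0])
                    row[0 if s.in_boundary else 1] += 1
        got = dict(zip(cont.retained_patients, cont.table.tolist()))
        assert got == expected

    def test_expected_in_fraction(self):
        sites = [make_site(0, True), make_site(100, False),
                 make_site(200, False), make_site(300, True, active=False)]
        assert expected_in_fraction(sites) == pytest.approx(1 / 3)


class TestTiTv:
    def test_named_examples(self):
        assert classify_titv("A", "G") == "transition"
        assert classify_titv("A", "T") == "transversion"

    def test_exhaustive_enumeration(self):
        kinds = [classify_titv(r, a) for r, a in
                 itertools.permutations("ACGT", 2)]
        assert kinds.count("transition") == 4
        assert kinds.count("transversion") == 8

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            classify_titv("A", "A")
        with pytest.raises(ValueError):
            classify_titv("N", "A")

    def test_planted_mix_counted_exactly(self):
        sites = [make_site(0, True), make_site(100, False)]
        muts = ([mut("P1", 3, "A", "G")] * 4 + [mut("P1", 4, "A", "C")] * 2 +
                [mut("P1", 103, "C", "T")] * 5 + [mut("P1", 104, "C", "G")] * 7)
        table, res = titv_table(muts, sites)
        assert table.loc["in_boundary"].tolist() == [4, 2]
        assert table.loc["off_boundary"].tolist() == [5, 7]
        assert res is not None

    def test_all_mutations_off_motif(self):
        sites = [make_site(0, True)]
        table, res = titv_table([mut("P1", 500)], sites)
        assert table.to_numpy().sum() == 0
        assert res is None


class TestPositionalProfile:
    def test_zero_mutations(self):
        prof = positional_profile([], [make_site(100, True)], half_width=50)
        assert prof.total == 0
        assert all(v == 0 for v in prof.counts.values())
        assert prof.positions[0] == -49 and prof.positions[-1] == 69

    def test_motif_center_offset_is_ten(self):
        site = make_site(100, True)           # interval [100, 119)
        prof = positional_profile([mut("P1", 109)], [site], half_width=50)
        assert prof.counts[10] == 1 and prof.total == 1

    def test_minus_strand_flipped(self):
        site = make_site(100, True, strand="-")
        # genomic position at interval start maps to motif position W
        prof = positional_profile([mut("P1", 100)], [site], half_width=0)
        assert prof.counts[19] == 1

    def test_mass_conservation_and_brute_force(self):
        rng = np.random.default_rng(4)
        sites = [make_site(int(s), bool(rng.random() < 0.5),
                           strand="+-"[rng.integers(0, 2)])
                 for s in range(200, 3000, 400)]
        muts = [mut("P1", int(rng.integers(0, 3200))) for _ in range(800)]
        prof = positional_profile(muts, sites, half_width=100)
        expected = {}
        n_in_windows = 0
        for m in muts:
            for s in sites:
                if s.strand == "-":
                    off = s.interval.end - m.pos
                else:
                    off = m.pos - s.interval.start + 1
                if -99 <= off <= 119:
                    n_in_windows += 1
                    expected[off] = expected.get(off, 0) + 1
        assert prof.total == n_in_windows
        assert {k: v for k, v in prof.counts.items() if v} == expected
        assert sum(prof.counts.values()) == prof.total

    def test_by_type_stratification(self):
        site = make_site(100, True)
        prof = positional_profile([mut("P1", 109, "G", "A"),
                                   mut("P2", 109, "G", "T")],
                                  [site], half_width=0, by_type=True)
        assert prof.counts[10] == {"G>A": 1, "G>T": 1}

    def test_strand_normalization_complements_types(self):
        site = make_site(100, True, strand="-")
        prof = positional_profile([mut("P1", 109, "G", "A")], [site],
                                  half_width=0, by_type=True,
                                  strand_normalize=True)
        assert prof.counts[10] == {"C>T": 1}


class TestRegionsAndGenes:
    def test_promoter_window(self):
        tss = IntervalCollection("tss", [GenomicInterval("chr1", 10_000, 10_001,
                                                         name="GENE1")])
        prom = promoters_from_tss(tss)
        assert prom.intervals[0].start == 8000
        assert prom.intervals[0].end == 12_000

    def test_promoter_clipped_at_origin(self):
        tss = IntervalCollection("tss", [GenomicInterval("chr1", 500, 501)])
        prom = promoters_from_tss(tss)
        assert (prom.intervals[0].start, prom.intervals[0].end) == (0, 2500)

    def test_stratify_matches_brute_force(self):
        rng = np.random.default_rng(30)
        sites = [make_site(int(s), True) for s in rng.integers(0, 5000, 40)]
        regions = [GenomicInterval("chr1", int(s := rng.integers(0, 5000)),
                                   int(s + rng.integers(10, 300)))
                   for _ in range(8)]
        inside, outside = stratify_by_region(
            sites, IntervalCollection("r", regions))
        assert len(inside) + len(outside) == len(sites)
        for s in sites:
            hit = any(s.interval.overlaps(r) for r in regions)
            assert (s in inside) == hit

    def test_gene_at_exact_radius_included(self):
        site = make_site(100_000, True)          # center 100_009
        tss = IntervalCollection("tss", [
            GenomicInterval("chr1", 100_009 + 180_000, 100_009 + 180_001,
                            name="EDGE"),
            GenomicInterval("chr1", 100_009 + 180_001, 100_009 + 180_002,
                            name="OUT")])
        frame = genes_near_mutated_sites([mut("P1", 100_005)], [site], tss)
        assert frame["gene"].tolist() == ["EDGE"]
        assert frame["distance"].iloc[0] == 180_000

    def test_no_mutated_sites_empty(self):
        tss = IntervalCollection("tss", [GenomicInterval("chr1", 0, 1, name="G")])
        frame = genes_near_mutated_sites([], [make_site(100, True)], tss)
        assert frame.empty

    def test_sample_counting(self):
        sites = [make_site(1000, True), make_site(5000, True)]
        tss = IntervalCollection("tss", [GenomicInterval("chr1", 3000, 3001,
                                                         name="G")])
        muts = [mut("P1", 1005), mut("P2", 1010), mut("P2", 5003)]
        frame = genes_near_mutated_sites(muts, sites, tss, radius=10_000)
        assert frame["n_samples"].iloc[0] == 2
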