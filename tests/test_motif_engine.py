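import math

import numpy as np
import pytest

from boundaryalt.io_formats import GenomicInterval, IntervalCollection
from boundaryalt.motif_engine import (build_motif_model, classify_sites,
                                      dedup_sites, reverse_complement,
                                      scan_sequence, summarize_classes)
from boundaryalt.synthetic_data import (SYNTHETIC_CTCF_CONSENSUS,
                                        synthetic_ctcf_pfm)
from conftest import brute_force_overlaps


def brute_force_scan(chrom, seq, model, min_fraction):
    """Score every window on both strands with plain python loops."""
    W = model.width
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for strand in "+-":
        for i in range(len(seq) - W + 1):
            window = seq[i:i + W]
            if "N" in window:
                continue
            if strand == "-":
                window = reverse_complement(window)
            score = sum(model.score_matrix[idx[b], j]
                        for j, b in enumerate(window))
            frac = (score - model.min_score) / (model.max_score - model.min_score)
            if frac >= min_fraction:
                hits.append((i, strand, round(score, 9)))
    return sorted(hits)


class TestBuildModel:
    def test_flat_matrix_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_motif_model(np.full((4, 5), 10.0))

    def test_all_zero_column_without_pseudocount(self):
        counts = np.zeros((4, 3))
        counts[0, 0] = counts[1, 1] = 1
        with pytest.raises(ValueError):
            build_motif_model(counts, pseudocount=0.0)

    def test_consensus_scores_max(self, model):
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        score = sum(model.score_matrix[idx[b], j]
                    for j, b in enumerate(model.consensus))
        assert score == pytest.approx(model.max_score)
        assert model.consensus == SYNTHETIC_CTCF_CONSENSUS

    def test_first_column_against_hand_computation(self):
        # independent closed-form check: column 0 has 85 on T, 5 elsewhere,
        # pseudocount 0.8 split over uniform background
        counts = synthetic_ctcf_pfm()
        model = build_motif_model(counts, pseudocount=0.8)
        p_T = (85 + 0.8 * 0.25) / (100 + 0.8)
        p_other = (5 + 0.8 * 0.25) / (100 + 0.8)
        assert model.score_matrix[3, 0] == pytest.approx(math.log2(p_T / 0.25))
        for b in range(3):
            assert model.score_matrix[b, 0] == pytest.approx(
                math.log2(p_other / 0.25))

    def test_probability_columns_sum_to_one(self, model):
        probs = ((model.counts + model.pseudocount * model.background[:, None])
                 / (model.counts.sum(axis=0) + model.pseudocount))
        assert np.allclose(probs.sum(axis=0), 1.0)


class TestScan:
    def test_sequence_shorter_than_motif(self, model):
        assert scan_sequence("chr1", "ACGTACGTAC", model) == []

    def test_invalid_min_fraction(self, model):
        with pytest.raises(ValueError):
            scan_sequence("chr1", "A" * 40, model, min_fraction=0.0)

    def test_planted_consensus_found_exactly(self, model):
        rng = np.random.default_rng(5)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        seq = bg[:100] + SYNTHETIC_CTCF_CONSENSUS + bg[100:250] + \
            SYNTHETIC_CTCF_CONSENSUS + bg[250:]
        sites = scan_sequence("chr1", seq, model, 0.99)
        assert [(s.interval.start, s.strand) for s in sites] == \
            [(100, "+"), (269, "+")]
        assert all(s.score_fraction == pytest.approx(1.0) for s in sites)

    def test_agrees_with_brute_force(self, model):
        rng = np.random.default_rng(99)
        for _ in range(30):
            seq = "".join("ACGTN"[i] for i in
                          rng.choice(5, size=60, p=[.24, .24, .24, .24, .04]))
            got = sorted((s.interval.start, s.strand, round(s.score, 9))
                         for s in scan_sequence("chr1", seq, model, 0.5))
            assert got == brute_force_scan("chr1", seq, model, 0.5)

    def test_strand_symmetry(self, model):
        rng = np.random.default_rng(21)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        seq = seq[:50] + SYNTHETIC_CTCF_CONSENSUS + seq[50:]
        fwd = scan_sequence("chr1", seq, model, 0.6)
        rev = scan_sequence("chr1", reverse_complement(seq), model, 0.6)
        L = len(seq)
        mirrored = sorted((L - s.interval.end,
                           "+" if s.strand == "-" else "-",
                           round(s.score, 9)) for s in rev)
        assert mirrored == sorted((s.interval.start, s.strand,
                                   round(s.score, 9)) for s in fwd)

    def test_threshold_monotonicity_nested_sites(self, model):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        prev = None
        for frac in (0.5, 0.6, 0.7, 0.8, 0.9):
            keys = {(s.interval.start, s.strand)
                    for s in scan_sequence("chr1", seq, model, frac)}
            if prev is not None:
                assert keys <= prev
            prev = keys

    def test_windows_with_N_skipped(self, model):
        seq = SYNTHETIC_CTCF_CONSENSUS[:9] + "N" + SYNTHETIC_CTCF_CONSENSUS[10:]
        assert scan_sequence("chr1", seq, model, 0.5) == []

    def test_dedup_keeps_higher_score(self, model):
        sites = scan_sequence("chr1", SYNTHETIC_CTCF_CONSENSUS, model, 0.01)
        assert len(sites) == 2  # both strands of one locus
        deduped = dedup_sites(sites)
        assert len(deduped) == 1
        assert deduped[0].score == max(s.score for s in sites)


class TestClassify:
    def _site(self, start=100, end=119):
        from boundaryalt.motif_engine import MotifSite
        return MotifSite(GenomicInterval("chr1", start, end), "+", 1.0, 0.9)

    def test_peak_only_is_active_off_boundary(self):
        s = self._site()
        classify_sites([s], IntervalCollection("p", [GenomicInterval("chr1", 90, 130)]),
                       IntervalCollection("b"))
        assert s.active and not s.in_boundary
        assert s.site_class == "active_off_boundary"

    def test_boundary_only_is_inactive_in_boundary(self):
        s = self._site()
        classify_sites([s], IntervalCollection("p"),
                       IntervalCollection("b", [GenomicInterval("chr1", 0, 500)]))
        assert not s.active and s.in_boundary

    def test_flags_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            sites = [self._site(int(s), int(s) + 19)
                     for s in rng.integers(0, 2000, size=10)]
            peaks = [GenomicInterval("chr1", int(s := rng.integers(0, 2000)),
                                     int(s + rng.integers(1, 100)))
                     for _ in range(rng.integers(1, 10))]
            bnds = [GenomicInterval("chr1", int(s := rng.integers(0, 2000)),
                                    int(s + rng.integers(1, 400)))
                    for _ in range(rng.integers(1, 6))]
            classify_sites(sites, IntervalCollection("p", peaks),
                           IntervalCollection("b", bnds))
            for site in sites:
                assert site.active == bool(
                    brute_force_overlaps(site.interval, peaks))
                assert site.in_boundary == bool(
                    brute_force_overlaps(site.interval, bnds))

    def test_summary_partitions_sites(self):
        sites = [self._site(i * 100, i * 100 + 19) for i in range(4)]
        sites[0].active = sites[0].in_boundary = True
        sites[1].active = True
        sites[2].in_boundary = True
        counts = summarize_classes(sites)
        assert counts == {"active_in_boundary": 1, "active_off_boundary": 1,
                          "inactive_in_boundary": 1, "inactive_off_boundary": 1}
        assert sum(counts.values()) == len(sites)

    def test_empty_input_all_zero(self):
        assert sum(summarize_classes([]).values()) == 0
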