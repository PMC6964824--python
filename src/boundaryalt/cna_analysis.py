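"""Copy-number alteration analysis at classified CTCF motifs.

Segments with |segment mean| > 0.2 (strict) are considered CNA-mutated,
stratified by size into cumulative percentile groups (25/50/75/100%,
nearest-rank cutoffs), and tested for preferential overlap with active
in-boundary motifs via a per-patient P x 2 table: for each patient, the
number of active in-boundary vs off-boundary motifs covered by at least one
of that patient's retained segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Literal, Sequence

import numpy as np

from .io_formats import CnaSegment, IntervalCollection
from .motif_engine import MotifSite
from .mutation_analysis import (PatientContingency, TestResult,
                                chi_square_homogeneity, enrichment_gof_test,
                                expected_in_fraction)


def filter_mutated_segments(segments: Iterable[CnaSegment],
                            threshold: float = 0.2) -> list[CnaSegment]:
    """Keep segments with |seg_mean| strictly greater than ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return [s for s in segments if abs(s.seg_mean) > threshold]


@dataclass
class CnaSizeStrata:
    """Cumulative size strata of CNA-mutated segments.

    ``groups[q]`` holds segments with length <= the nearest-rank q-th
    percentile cutoff; the 100% group contains every segment.
    """

    cutoffs: dict[int, int]
    groups: dict[int, list[CnaSegment]]


def nearest_rank_percentile(sorted_values: Sequence[int], q: float) -> int:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty value list")
    rank = max(1, ceil(q / 100.0 * n))
    return sorted_values[rank - 1]


def stratify_segments(segments: Sequence[CnaSegment],
                      percentiles: Sequence[int] = (25, 50, 75, 100)
                      ) -> CnaSizeStrata:
    """Split segments into cumulative groups at size-percentile cutoffs."""
    if not segments:
        raise ValueError("cannot stratify an empty segment list")
    lengths = sorted(s.length for s in segments)
    cutoffs = {int(q): int(nearest_rank_percentile(lengths, q))
               for q in percentiles}
    groups = {q: [s for s in segments if s.length <= cut]
              for q, cut in cutoffs.items()}
    if 100 in groups:
        groups[100] = list(segments)
    return CnaSizeStrata(cutoffs=cutoffs, groups=groups)


def count_motifs_overlapped(segments: Iterable[CnaSegment],
                            sites: Sequence[MotifSite]
                            ) -> dict[str, np.ndarray]:
    """Per patient: number of active in/off-boundary motifs covered by segments.

    A motif counts once per patient regardless of how many of the patient's
    segments cover it.
    """
    by_patient: dict[str, list[CnaSegment]] = {}
    for seg in segments:
        by_patient.setdefault(seg.sample_id, []).append(seg)

    active = [(i, s) for i, s in enumerate(sites) if s.active]
    counts: dict[str, np.ndarray] = {}
    for sid, segs in by_patient.items():
        coll = IntervalCollection("segments")
        for seg in segs:
            coll.add(seg.interval)
        row = np.zeros(2, dtype=int)
        for _, site in active:
            if coll.overlaps_interval(site.interval):
                row[0 if site.in_boundary else 1] += 1
        if row.sum() > 0:
            counts[sid] = row
    return counts


def cna_contingency_test(segments: Sequence[CnaSegment],
                         sites: Sequence[MotifSite],
                         min_count: int = 1,
                         method: Literal["gof", "homogeneity"] = "gof"
                         ) -> tuple[PatientContingency, TestResult]:
    """Per-patient P x 2 test of CNA overlap with in- vs off-boundary motifs.

    Patients with fewer than ``min_count`` overlapped motifs in either
    column are discarded. ``method="gof"`` (default) tests against the
    active motif-class composition; ``method="homogeneity"`` is the
    chi-square of independence across patients (no Yates for P > 2).
    """
    counts = count_motifs_overlapped(segments, sites)
    retained, discarded = [], []
    for sid in sorted(counts):
        row = counts[sid]
        (discarded if (row < min_count).any() else retained).append(sid)
    if len(retained) < 2:
        raise ValueError(
            f"need >= 2 retained patients with motif-overlapping segments, "
            f"got {len(retained)}")
    table = np.vstack([counts[s] for s in retained])
    contingency = PatientContingency(table=table, retained_patients=retained,
                                     discarded_patients=discarded)
    if method == "gof":
        n_in = sum(1 for s in sites if s.active and s.in_boundary)
        n_off = sum(1 for s in sites if s.active and not s.in_boundary)
        if n_in == 0 or n_off == 0:
            raise ValueError("need both in- and off-boundary active motifs")
        result = enrichment_gof_test(table, n_in / (n_in + n_off))
    else:
        result = chi_square_homogeneity(table, yates=False)
    return contingency, result
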