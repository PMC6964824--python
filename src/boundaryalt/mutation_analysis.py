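"""Somatic point-mutation analyses at classified CTCF motif sites.

Covers: per-patient enrichment contingency tables and tests, transition /
transversion (Ti/Tv) contrasts between in-boundary and off-boundary active
motifs, motif-anchored positional mutation profiles, promoter/exon
stratification of sites, and gene-proximity reporting around mutated
boundaries.

Two flavours of chi-square test are provided:

* :func:`chi_square_homogeneity` — Pearson chi-square of independence on an
  R x 2 table (Yates-corrected iff exactly 2 x 2). This is the test applied
  to the Ti/Tv contrast tables.
* :func:`enrichment_gof_test` — a per-patient goodness-of-fit chi-square
  against the in/off split expected from the active motif-class composition
  (dof = number of patients). Unlike the homogeneity test, this detects a
  rate multiplier shared by all patients, and is therefore the default for
  the mutation- and CNA-enrichment questions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval, IntervalCollection, MutationRecord
from .motif_engine import MotifSite

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Test results and contingency containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    dof: int
    p_value: float
    method: str
    n_units: int
    low_expected: bool = False   # any expected cell < 5


@dataclass
class PatientContingency:
    """Per-patient counts on in-boundary vs off-boundary active motifs."""

    table: np.ndarray                  # P x 2 (columns: in, off)
    retained_patients: list[str]
    discarded_patients: list[str]

    @property
    def n_patients(self) -> int:
        return self.table.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table, index=self.retained_patients,
                            columns=["in_boundary", "off_boundary"])


# ---------------------------------------------------------------------------
# Chi-square machinery
# ---------------------------------------------------------------------------

def chi_square_homogeneity(table, yates: bool | None = None) -> TestResult:
    """Pearson chi-square test of identical column distributions on R x 2.

    Yates continuity correction is applied iff the table is exactly 2 x 2
    (``yates=None``); pass an explicit boolean to override. Requires R >= 2,
    no all-zero row and strictly positive expected counts.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError(f"need an R x 2 table with R >= 2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any():
        raise ValueError("all-zero row in contingency table")
    if (t.sum(axis=0) == 0).any():
        raise ValueError("all-zero column in contingency table")
    correction = (t.shape == (2, 2)) if yates is None else yates
    res = stats.chi2_contingency(t, correction=correction)
    expected = res.expected_freq
    if (expected == 0).any():
        raise ValueError("zero expected count")
    return TestResult(
        statistic=float(res.statistic),
        dof=int(res.dof),
        p_value=float(res.pvalue),
        method="chi2_yates" if correction else "chi2",
        n_units=t.shape[0],
        low_expected=bool((expected < 5).any()),
    )


def enrichment_gof_test(table, expected_in_fraction: float) -> TestResult:
    """Summed per-patient goodness-of-fit chi-square against a fixed split.

    For each patient with total n_i, the expected counts are
    ``(n_i * q, n_i * (1 - q))`` where ``q`` is the in-boundary fraction
    expected with no enrichment (the in-boundary share of active motif
    bases). The statistic sums the per-patient Pearson terms; dof equals the
    number of patients.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 1:
        raise ValueError(f"need a P x 2 table, got shape {t.shape}")
    if not 0.0 < expected_in_fraction < 1.0:
        raise ValueError("expected_in_fraction must be in (0, 1)")
    totals = t.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero row in contingency table")
    expected = np.column_stack([totals * expected_in_fraction,
                                totals * (1 - expected_in_fraction)])
    stat = float(((t - expected) ** 2 / expected).sum())
    dof = t.shape[0]
    p = float(stats.chi2.sf(stat, dof))
    return TestResult(statistic=stat, dof=dof, p_value=p, method="chi2_gof",
                      n_units=t.shape[0],
                      low_expected=bool((expected < 5).any()))


# ---------------------------------------------------------------------------
# Per-patient mutation counting
# ---------------------------------------------------------------------------

def _active_site_index(sites: Iterable[MotifSite]
                       ) -> tuple[IntervalCollection, dict[tuple, MotifSite]]:
    coll = IntervalCollection("active_motifs")
    lookup: dict[tuple, MotifSite] = {}
    for s in sites:
        if not s.active:
            continue
        key = (s.interval.chrom, s.interval.start, s.interval.end, s.strand)
        coll.add(s.interval)
        prev = lookup.get(key[:3])
        if prev is None or s.score > prev.score:
            lookup[key[:3]] = s
    return coll, lookup


def sites_hit_by(mutation: MutationRecord, sites_index: IntervalCollection
                 ) -> list[GenomicInterval]:
    return sites_index.overlapping(mutation.chrom, mutation.pos, mutation.pos + 1)


def count_per_patient(mutations: Iterable[MutationRecord],
                      sites: Sequence[MotifSite],
                      min_count: int = 5,
                      rule: Literal["either", "both"] = "either"
                      ) -> PatientContingency:
    """Count, per patient, mutations on in-boundary vs off-boundary active motifs.

    A mutation is counted for a class when its position falls inside the
    motif interval of an active site of that class. Patients with fewer than
    ``min_count`` mutations in either category (``rule="either"``, the
    default retention reading) — or in both (``rule="both"``) — are
    discarded and listed.
    """
    coll, lookup = _active_site_index(sites)
    counts: dict[str, np.ndarray] = {}
    for m in mutations:
        hits = sites_hit_by(m, coll)
        if not hits:
            continue
        row = counts.setdefault(m.sample_id, np.zeros(2, dtype=int))
        # a position inside overlapping in- and off-boundary motifs counts
        # once per distinct motif interval
        seen = set()
        for iv in hits:
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                continue
            seen.add(key)
            site = lookup[key]
            row[0 if site.in_boundary else 1] += 1
    retained, discarded = [], []
    for sid in sorted(counts):
        row = counts[sid]
        below = row < min_count
        drop = below.any() if rule == "either" else below.all()
        (discarded if drop else retained).append(sid)
    table = (np.vstack([counts[s] for s in retained]) if retained
             else np.zeros((0, 2), dtype=int))
    return PatientContingency(table=table, retained_patients=retained,
                              discarded_patients=discarded)


def expected_in_fraction(sites: Sequence[MotifSite]) -> float:
    """In-boundary share of active motif bases (the no-enrichment split)."""
    n_in = sum(len(s.interval) for s in sites if s.active and s.in_boundary)
    n_off = sum(len(s.interval) for s in sites if s.active and not s.in_boundary)
    if n_in == 0 or n_off == 0:
        raise ValueError("need both in-boundary and off-boundary active motifs")
    return n_in / (n_in + n_off)


def mutation_enrichment_test(contingency: PatientContingency,
                             expected_fraction: float | None = None,
                             method: Literal["gof", "homogeneity"] = "gof"
                             ) -> TestResult:
    """Test mutation enrichment on in-boundary vs off-boundary active motifs.

    ``method="gof"`` (default) tests each patient's split against
    ``expected_fraction`` and sums; ``method="homogeneity"`` runs the
    chi-square of independence across patients on the P x 2 table.
    """
    if contingency.n_patients == 0:
        raise ValueError("no retained patients — contingency table is empty")
    if method == "gof":
        if expected_fraction is None:
            raise ValueError("gof method requires expected_fraction")
        return enrichment_gof_test(contingency.table, expected_fraction)
    return chi_square_homogeneity(contingency.table, yates=False)


# ---------------------------------------------------------------------------
# Transitions / transversions
# ---------------------------------------------------------------------------

def classify_titv(ref: str, alt: str) -> str:
    """Classify a substitution as "transition" or "transversion"."""
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"bases must be single A/C/G/T, got {ref!r}->{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    same_family = ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)
    return "transition" if same_family else "transversion"


def titv_table(mutations: Iterable[MutationRecord],
               sites: Sequence[MotifSite]
               ) -> tuple[pd.DataFrame, TestResult | None]:
    """2 x 2 Ti/Tv counts (rows in/off-boundary, columns Ti/Tv) plus the test.

    Counts partition the motif-overlapping SNVs among active sites. The test
    is the Yates-corrected chi-square; if any margin is zero the counts are
    still returned with ``None`` for the test.
    """
    coll, lookup = _active_site_index(sites)
    table = np.zeros((2, 2), dtype=int)
    for m in mutations:
        hits = sites_hit_by(m, coll)
        if not hits:
            continue
        kind = classify_titv(m.ref, m.alt)
        col = 0 if kind == "transition" else 1
        seen = set()
        for iv in hits:
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                continue
            seen.add(key)
            site = lookup[key]
            table[0 if site.in_boundary else 1, col] += 1
    frame = pd.DataFrame(table, index=["in_boundary", "off_boundary"],
                         columns=["transitions", "transversions"])
    try:
        result = chi_square_homogeneity(table)
    except ValueError:
        result = None
    return frame, result


# ---------------------------------------------------------------------------
# Positional profiles
# ---------------------------------------------------------------------------

@dataclass
class MutationProfile:
    """Motif-anchored per-offset mutation counts.

    Offsets run from ``1 - half_width`` to ``motif_width + half_width``;
    positions 1..W are inside the motif (the motif centre of a 19 bp model is
    offset 10). ``counts`` maps offset -> count, or offset -> {"R>A": count}
    when stratified by substitution type.
    """

    half_width: int
    motif_width: int
    positions: np.ndarray
    counts: dict
    n_sites: int
    total: int


def positional_profile(mutations: Iterable[MutationRecord],
                       sites: Sequence[MotifSite],
                       half_width: int = 1000,
                       by_type: bool = False,
                       strand_normalize: bool = False) -> MutationProfile:
    """Aggregate mutations into motif-anchored offsets across sites.

    Minus-strand sites are flipped so offsets follow motif orientation. With
    ``strand_normalize`` the ref/alt of mutations over minus-strand sites are
    also reverse-complemented (off by default: published positional profiles
    of this kind are typically shown in genome orientation, giving symmetric
    G>A / C>T peaks).
    """
    widths = {len(s.interval) for s in sites}
    if len(widths) > 1:
        raise ValueError(f"sites must share one motif width, got {sorted(widths)}")
    W = widths.pop() if widths else 0
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    positions = np.arange(1 - half_width, W + half_width + 1)
    counts: dict = {int(p): ({} if by_type else 0) for p in positions}

    coll = IntervalCollection("profile_windows")
    window_sites: dict[tuple, list[MotifSite]] = {}
    for s in sites:
        win = GenomicInterval(s.interval.chrom,
                              max(0, s.interval.start - half_width),
                              s.interval.end + half_width)
        coll.add(win)
        window_sites.setdefault((win.chrom, win.start, win.end), []).append(s)

    total = 0
    for m in mutations:
        for win in coll.overlapping(m.chrom, m.pos, m.pos + 1):
            for s in window_sites[(win.chrom, win.start, win.end)]:
                if s.strand == "-":
                    offset = s.interval.end - m.pos
                else:
                    offset = m.pos - s.interval.start + 1
                if not (1 - half_width) <= offset <= (W + half_width):
                    continue
                total += 1
                if by_type:
                    ref, alt = m.ref, m.alt
                    if strand_normalize and s.strand == "-":
                        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
                    key = f"{ref}>{alt}"
                    counts[offset][key] = counts[offset].get(key, 0) + 1
                else:
                    counts[offset] += 1
    return MutationProfile(half_width=half_width, motif_width=W,
                           positions=positions, counts=counts,
                           n_sites=len(sites), total=total)


# ---------------------------------------------------------------------------
# Region stratification and gene proximity
# ---------------------------------------------------------------------------

def promoters_from_tss(tss: IntervalCollection, flank: int = 2000
                       ) -> IntervalCollection:
    """Build strand-independent promoter windows [TSS - flank, TSS + flank).

    Each TSS record contributes one window anchored at its start coordinate,
    clipped at the chromosome origin.
    """
    out = IntervalCollection("promoter")
    for iv in tss:
        point = iv.start
        out.add(GenomicInterval(iv.chrom, max(0, point - flank), point + flank,
                                name=iv.name, strand=iv.strand))
    return out


def stratify_by_region(sites: Sequence[MotifSite],
                       regions: IntervalCollection
                       ) -> tuple[list[MotifSite], list[MotifSite]]:
    """Partition sites by >= 1 bp overlap with ``regions``: (inside, outside)."""
    inside, outside = [], []
    for s in sites:
        (inside if regions.overlaps_interval(s.interval) else outside).append(s)
    return inside, outside


def genes_near_mutated_sites(mutations: Iterable[MutationRecord],
                             sites: Sequence[MotifSite],
                             tss: IntervalCollection,
                             radius: int = 180_000) -> pd.DataFrame:
    """Genes whose TSS lies within ``radius`` of a mutated active in-boundary motif.

    Distance is measured from the motif centre to the TSS point and the
    threshold is closed (a TSS at exactly ``radius`` qualifies). For each gene
    the table reports the number of distinct samples with a qualifying
    mutated motif in range and the minimum such distance.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    coll, lookup = _active_site_index(s for s in sites if s.in_boundary)
    mutated: dict[tuple, set[str]] = {}
    for m in mutations:
        for iv in sites_hit_by(m, coll):
            mutated.setdefault((iv.chrom, iv.start, iv.end), set()).add(m.sample_id)
    rows = []
    for gene_iv in tss:
        gene = gene_iv.name or f"{gene_iv.chrom}:{gene_iv.start}"
        samples: set[str] = set()
        best: int | None = None
        for (chrom, start, end), sample_ids in mutated.items():
            if chrom != gene_iv.chrom:
                continue
            center = (start + end) // 2
            dist = abs(gene_iv.start - center)
            if dist <= radius:
                samples |= sample_ids
                best = dist if best is None else min(best, dist)
        if samples:
            rows.append({"gene": gene, "n_samples": len(samples),
                         "distance": best})
    frame = pd.DataFrame(rows, columns=["gene", "n_samples", "distance"])
    return frame.sort_values(["n_samples", "distance"],
                             ascending=[False, True]).reset_index(drop=True)
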