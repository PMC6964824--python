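"""PWM scanning of a genome for CTCF motif matches and their classification.

A position frequency matrix (e.g. JASPAR MA0139.1, 19 bp) is turned into a
log-odds score matrix; both strands of the genome are scanned and every window
whose min-max-normalised score fraction reaches a threshold (0.80 by default)
is emitted as a motif site. Sites are then classified on two orthogonal axes:

* **active** — the site overlaps a CTCF ChIP-seq peak (>= 1 bp);
* **in-boundary** — the site overlaps an insulated-neighbourhood boundary.

The score fraction is ``(score - min_score) / (max_score - min_score)`` where
``min_score``/``max_score`` are the per-column minima/maxima summed over the
motif — the min-max convention of Biostrings-style PWM matching. Note this is
not the same as "80% of the maximum score"; with log-odds matrices whose
minima are negative the two readings differ substantially.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GenomicInterval, IntervalCollection

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A PWM with its log-odds score matrix and score range.

    ``score_matrix[b, j] = log2(p[b, j] / background[b])`` with
    ``p[b, j] = (counts[b, j] + pseudocount * background[b]) /
    (column_total + pseudocount)``.
    """

    counts: np.ndarray          # 4 x W, A/C/G/T rows
    pseudocount: float
    background: np.ndarray      # length-4 base probabilities
    score_matrix: np.ndarray    # 4 x W log-odds
    min_score: float
    max_score: float

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.counts, axis=0))

    def score_fraction(self, score: float) -> float:
        return (score - self.min_score) / (self.max_score - self.min_score)


def build_motif_model(pfm_counts, pseudocount: float = 0.8,
                      background: Sequence[float] | None = None) -> MotifModel:
    """Build a log-odds :class:`MotifModel` from raw PFM counts.

    The pseudocount is split across bases proportionally to the background
    (default uniform 0.25), the common PWM regularisation.
    """
    counts = np.asarray(pfm_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError(f"PFM must be 4 x W, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("PFM counts must be non-negative")
    bg = (np.full(4, 0.25) if background is None
          else np.asarray(background, dtype=float))
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")
    col_totals = counts.sum(axis=0)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (col_totals == 0).any():
        raise ValueError("all-zero PFM column with zero pseudocount")
    probs = (counts + pseudocount * bg[:, None]) / (col_totals + pseudocount)
    if (probs <= 0).any():
        raise ValueError("zero probability cell; increase pseudocount")
    score = np.log2(probs / bg[:, None])
    min_score = float(score.min(axis=0).sum())
    max_score = float(score.max(axis=0).sum())
    if not max_score > min_score:
        raise ValueError("degenerate motif: max_score == min_score "
                         "(flat matrix carries no information)")
    return MotifModel(counts=counts, pseudocount=pseudocount, background=bg,
                      score_matrix=score, min_score=min_score,
                      max_score=max_score)


@dataclass
class MotifSite:
    """A genomic PWM match with its classification flags."""

    interval: GenomicInterval
    strand: str
    score: float
    score_fraction: float
    active: bool = False
    in_boundary: bool = False

    @property
    def site_class(self) -> str:
        a = "active" if self.active else "inactive"
        b = "in_boundary" if self.in_boundary else "off_boundary"
        return f"{a}_{b}"


def _encode(sequence: str) -> np.ndarray:
    codes = np.full(len(sequence), 4, dtype=np.int8)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window plus a validity mask (windows without N)."""
    W = matrix.shape[1]
    n_win = len(codes) - W + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    padded = np.vstack([matrix, np.zeros(matrix.shape[1])])  # row 4 = N
    for j in range(W):
        col_codes = codes[j:j + n_win]
        scores += padded[col_codes, j]
        valid &= col_codes != 4
    return scores, valid


def scan_sequence(chrom: str, sequence: str, model: MotifModel,
                  min_fraction: float = 0.80) -> list[MotifSite]:
    """Scan one chromosome on both strands for PWM matches.

    Reverse-strand hits are reported on forward coordinates with strand "-".
    Windows containing N are skipped. A sequence shorter than the motif yields
    an empty result.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    W = model.width
    if len(sequence) < W:
        return []
    codes = _encode(sequence.upper())
    # reverse-complement score matrix applied to the forward window gives the
    # reverse-strand score at the same coordinates
    rc_matrix = model.score_matrix[::-1, ::-1]
    sites: list[MotifSite] = []
    span = model.max_score - model.min_score
    for strand, matrix in (("+", model.score_matrix), ("-", rc_matrix)):
        scores, valid = _window_scores(codes, matrix)
        fractions = (scores - model.min_score) / span
        hits = np.flatnonzero(valid & (fractions >= min_fraction))
        for i in hits:
            sites.append(MotifSite(
                interval=GenomicInterval(chrom, int(i), int(i) + W),
                strand=strand,
                score=float(scores[i]),
                score_fraction=float(fractions[i]),
            ))
    sites.sort(key=lambda s: (s.interval.start, s.strand))
    return sites


def scan_genome(genome: Mapping[str, str], model: MotifModel,
                min_fraction: float = 0.80,
                dedup: bool = False) -> list[MotifSite]:
    """Scan every chromosome; optional dedup of +/- pairs at one locus."""
    sites: list[MotifSite] = []
    for chrom in sorted(genome):
        sites.extend(scan_sequence(chrom, genome[chrom], model, min_fraction))
    return dedup_sites(sites) if dedup else sites


def dedup_sites(sites: Iterable[MotifSite]) -> list[MotifSite]:
    """Collapse +/- hits sharing an interval, keeping the higher score."""
    best: dict[tuple[str, int, int], MotifSite] = {}
    for s in sites:
        key = (s.interval.chrom, s.interval.start, s.interval.end)
        if key not in best or s.score > best[key].score:
            best[key] = s
    return sorted(best.values(),
                  key=lambda s: (s.interval.chrom, s.interval.start, s.strand))


def classify_sites(sites: Iterable[MotifSite], peaks: IntervalCollection,
                   boundaries: IntervalCollection) -> list[MotifSite]:
    """Set the active (ChIP-seq peak overlap) and in-boundary flags.

    Both use >= 1 bp half-open overlap. Returns the same site objects for
    convenience.
    """
    out = []
    for s in sites:
        s.active = peaks.overlaps_interval(s.interval)
        s.in_boundary = boundaries.overlaps_interval(s.interval)
        out.append(s)
    return out


def summarize_classes(sites: Iterable[MotifSite]) -> dict[str, int]:
    """Count sites per (active x in-boundary) class; values sum to the total."""
    counts = {"active_in_boundary": 0, "active_off_boundary": 0,
              "inactive_in_boundary": 0, "inactive_off_boundary": 0}
    for s in sites:
        counts[s.site_class] += 1
    return counts


# ---------------------------------------------------------------------------
# Site table I/O (BED6 + sidecar-free TSV with full precision and flags)
# ---------------------------------------------------------------------------

def write_sites(sites: Iterable[MotifSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tscore\tscore_fraction"
                 "\tactive\tin_boundary\n")
        for s in sites:
            fh.write(f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                     f"\t{s.strand}\t{s.score:.6f}\t{s.score_fraction:.6f}"
                     f"\t{int(s.active)}\t{int(s.in_boundary)}\n")


def read_sites(path) -> list[MotifSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            sites.append(MotifSite(
                interval=GenomicInterval(f[idx["chrom"]], int(f[idx["start"]]),
                                         int(f[idx["end"]])),
                strand=f[idx["strand"]],
                score=float(f[idx["score"]]),
                score_fraction=float(f[idx["score_fraction"]]),
                active=bool(int(f[idx["active"]])),
                in_boundary=bool(int(f[idx["in_boundary"]])),
            ))
    return sites
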