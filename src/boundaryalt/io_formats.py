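"""Readers/writers for the external formats the pipeline touches, plus the
interval-overlap engine shared by every analysis stage.

All internal coordinates are 0-based half-open. BED input is consumed natively;
mutation, probe and SEG tables are commonly 1-based and are converted at parse
time (``one_based=True`` by default for those readers). Chromosome names are
normalised to the ``chr``-prefixed form so that ICGC-style (``1``) and
ENCODE-style (``chr1``) inputs join correctly.

Record rejection is count-and-continue: consortium dumps are messy, and a bad
row should not abort a whole cohort. Structural problems (missing columns,
malformed FASTA) are fatal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree


class ParseError(ValueError):
    """Fatal, structural problem with an input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def normalize_chrom(name: str) -> str:
    """Normalise a chromosome name to the ``chr``-prefixed convention."""
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalCollection:
    """A labelled set of intervals indexed per chromosome for overlap queries.

    Query results are independent of insertion order.
    """

    def __init__(self, label: str, intervals: Iterable[GenomicInterval] = ()):
        self.label = label
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._intervals.append(iv)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return sorted(self._intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All intervals sharing >= 1 bp with ``[start, end)`` on ``chrom``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        return sorted(hits, key=lambda iv: (iv.start, iv.end))

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return bool(self._trees.get(iv.chrom) and
                    self._trees[iv.chrom].overlaps(iv.start, iv.end))


def overlaps(query: GenomicInterval, collection: IntervalCollection
             ) -> tuple[bool, list[GenomicInterval]]:
    """Half-open overlap query: ``(any_hit, hits)``.

    An unknown chromosome is simply no overlap, not an error.
    """
    hits = collection.overlapping(query.chrom, query.start, query.end)
    return bool(hits), hits


@dataclass(frozen=True)
class MutationRecord:
    """A single-nucleotide somatic substitution (0-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    cancer_type: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or len(self.ref) != 1:
            raise ValueError(f"ref must be a single base, got {self.ref!r}")
        if self.alt not in "ACGT" or len(self.alt) != 1:
            raise ValueError(f"alt must be a single base, got {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


@dataclass(frozen=True)
class CnaSegment:
    """A copy-number segment with its log-ratio segment mean."""

    sample_id: str
    chrom: str
    start: int
    end: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=self.sample_id)


@dataclass(frozen=True)
class MethylProbeRecord:
    """A 450k-style methylation probe with matched tumour/normal beta values."""

    probe_id: str
    chrom: str
    pos: int
    beta_tumor: float
    beta_normal: float

    def __post_init__(self) -> None:
        for label, b in (("beta_tumor", self.beta_tumor),
                         ("beta_normal", self.beta_normal)):
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {b}")

    @property
    def delta_beta(self) -> float:
        """Tumour-minus-normal methylation difference, in [-1, 1]."""
        return self.beta_tumor - self.beta_normal


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{chrom: uppercase sequence}``.

    Ambiguity codes are preserved; sequence is upper-cased. Raises
    :class:`ParseError` naming the offending line for malformed input.
    """
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            if line.startswith(">"):
                if current is not None:
                    seqs[current] = "".join(chunks)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                current = header
                chunks = []
            else:
                if current is None:
                    raise ParseError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                chunks.append(line.strip().upper())
    if current is not None:
        seqs[current] = "".join(chunks)
    if not seqs or n_lines == 0:
        raise ParseError(f"{path}: empty FASTA file (line 1)")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str) -> IntervalCollection:
    """Read a BED3+ file (0-based half-open) into an :class:`IntervalCollection`.

    Track/browser/comment lines are skipped. Rows with ``end <= start`` raise
    a :class:`ParseError` carrying the line number.
    """
    coll = IntervalCollection(label)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if (not line.strip() or line.startswith("#")
                    or line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: expected >= 3 BED columns at line {lineno}")
            chrom = normalize_chrom(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer coordinate at line {lineno}") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            try:
                coll.add(GenomicInterval(chrom, start, end, name=name, strand=strand))
            except ValueError as exc:
                raise ParseError(f"{path}: invalid interval at line {lineno}: {exc}") from exc
    return coll


def write_bed(collection: IntervalCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in collection.intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Tabular records (mutations, probes, SEG)
# ---------------------------------------------------------------------------

def _header_index(header_line: str, required: Sequence[str], path) -> dict[str, int]:
    cols = [c.strip() for c in header_line.rstrip("\n").split("\t")]
    index = {c: i for i, c in enumerate(cols)}
    missing = [c for c in required if c not in index]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    return index


def read_mutations(path: str | Path, one_based: bool = True,
                   drop_chrY: bool = False
                   ) -> tuple[list[MutationRecord], int]:
    """Read an ICGC-style simple-somatic-mutation TSV.

    Only single-base substitutions are retained; indels, MNVs and otherwise
    invalid rows are counted and skipped. Returns ``(records, n_rejected)``.
    """
    required = ["sample_id", "chrom", "pos", "ref", "alt"]
    records: list[MutationRecord] = []
    rejected = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty mutation file")
        idx = _header_index(header, required, path)
        has_cancer = "cancer_type" in idx
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            try:
                chrom = normalize_chrom(f[idx["chrom"]])
                pos = int(f[idx["pos"]]) - (1 if one_based else 0)
                rec = MutationRecord(
                    sample_id=f[idx["sample_id"]],
                    chrom=chrom,
                    pos=pos,
                    ref=f[idx["ref"]].upper(),
                    alt=f[idx["alt"]].upper(),
                    cancer_type=f[idx["cancer_type"]] if has_cancer else None,
                )
            except (ValueError, IndexError):
                rejected += 1
                continue
            if drop_chrY and rec.chrom == "chrY":
                continue
            records.append(rec)
    return records, rejected


def write_mutations(records: Iterable[MutationRecord], path: str | Path,
                    one_based: bool = True) -> None:
    off = 1 if one_based else 0
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tcancer_type\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.pos + off}\t{r.ref}\t{r.alt}"
                     f"\t{r.cancer_type or '.'}\n")


def read_probes(path: str | Path, one_based: bool = True
                ) -> tuple[list[MethylProbeRecord], int]:
    """Read a TCGA 450k-style probe table with matched tumour/normal betas."""
    required = ["probe_id", "chrom", "pos", "beta_tumor", "beta_normal"]
    records: list[MethylProbeRecord] = []
    rejected = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty probe file")
        idx = _header_index(header, required, path)
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            try:
                records.append(MethylProbeRecord(
                    probe_id=f[idx["probe_id"]],
                    chrom=normalize_chrom(f[idx["chrom"]]),
                    pos=int(f[idx["pos"]]) - (1 if one_based else 0),
                    beta_tumor=float(f[idx["beta_tumor"]]),
                    beta_normal=float(f[idx["beta_normal"]]),
                ))
            except (ValueError, IndexError):
                rejected += 1
    return records, rejected


def write_probes(records: Iterable[MethylProbeRecord], path: str | Path,
                 one_based: bool = True) -> None:
    off = 1 if one_based else 0
    with open(path, "w") as fh:
        fh.write("probe_id\tchrom\tpos\tbeta_tumor\tbeta_normal\n")
        for r in records:
            fh.write(f"{r.probe_id}\t{r.chrom}\t{r.pos + off}"
                     f"\t{r.beta_tumor:.6f}\t{r.beta_normal:.6f}\n")


def read_segments(path: str | Path, one_based: bool = True
                  ) -> tuple[list[CnaSegment], int]:
    """Read a SEG-style copy-number table (sample, chrom, start, end, seg_mean)."""
    required = ["sample_id", "chrom", "start", "end", "seg_mean"]
    records: list[CnaSegment] = []
    rejected = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty segment file")
        idx = _header_index(header, required, path)
        for raw in fh:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            try:
                records.append(CnaSegment(
                    sample_id=f[idx["sample_id"]],
                    chrom=normalize_chrom(f[idx["chrom"]]),
                    start=int(f[idx["start"]]) - (1 if one_based else 0),
                    end=int(f[idx["end"]]),
                    seg_mean=float(f[idx["seg_mean"]]),
                ))
            except (ValueError, IndexError):
                rejected += 1
    return records, rejected


def write_segments(records: Iterable[CnaSegment], path: str | Path,
                   one_based: bool = True) -> None:
    off = 1 if one_based else 0
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tseg_mean\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.start + off}\t{r.end}"
                     f"\t{r.seg_mean:.4f}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def read_jaspar_pfm(path: str | Path):
    """Read a JASPAR-style position frequency matrix.

    Accepts both the raw 4-row count format and the bracketed
    ``A [ 1 2 3 ]`` JASPAR format. Returns a 4 x W numpy array of counts in
    A, C, G, T row order.
    """
    import numpy as np

    rows: list[list[float]] = []
    order: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(">"):
                continue
            base = None
            if line[0] in "ACGT" and (len(line) == 1 or not line[1].isdigit()):
                base = line[0]
                line = line[1:]
            line = line.replace("[", " ").replace("]", " ")
            values = [float(tok) for tok in line.split()]
            if not values:
                continue
            rows.append(values)
            order.append(base or "ACGT"[len(rows) - 1])
    if len(rows) != 4:
        raise ParseError(f"{path}: expected 4 PFM rows (A, C, G, T), got {len(rows)}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged PFM rows, widths {sorted(widths)}")
    mat = np.array([rows[order.index(b)] for b in "ACGT"], dtype=float)
    if (mat < 0).any():
        raise ParseError(f"{path}: negative PFM counts")
    return mat


def write_jaspar_pfm(counts, path: str | Path, name: str = "motif") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", counts):
            fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")
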