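"""Synthetic cohort generator with known, controllable effect sizes.

Generates a toy genome with planted CTCF-like motifs, boundary and ChIP-seq
peak intervals arranged so all four motif classes (active/inactive x
in/off-boundary) are populated, and per-patient mutation, methylation and
copy-number cohorts whose planted effects (in-boundary mutation-rate
multiplier, delta-beta shift, CNA placement bias, signature exposures) are
recorded in a ground-truth manifest. Everything is driven by one seed and is
byte-reproducible.

The genome background is i.i.d. uniform ACGT and motif insertions are exact
consensus, so scanner recovery is deterministic and statistical power
questions are cleanly separated from scanner correctness. The bundled motif
is a synthetic CTCF-like 19 bp matrix (not the JASPAR matrix, which is read
from user-supplied PFM files when available).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (CnaSegment, GenomicInterval, IntervalCollection,
                         MethylProbeRecord, MutationRecord, write_bed,
                         write_fasta, write_mutations, write_probes,
                         write_segments)
from .motif_engine import MotifModel, MotifSite, build_motif_model
from .signature_refit import CHANNELS_96, SignatureCatalog

#: Synthetic CTCF-like 19 bp consensus (non-palindromic, one CpG at
#: positions 15-16). This is a stand-in matrix for testing, not MA0139.1.
SYNTHETIC_CTCF_CONSENSUS = "TGGCCACCAGGGGGCGCTA"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def synthetic_ctcf_pfm() -> np.ndarray:
    """4 x 19 count matrix: 85 counts on the consensus base, 5 elsewhere."""
    counts = np.full((4, len(SYNTHETIC_CTCF_CONSENSUS)), 5.0)
    for j, base in enumerate(SYNTHETIC_CTCF_CONSENSUS):
        counts[_BASE_INDEX[base], j] = 85.0
    return counts


def synthetic_ctcf_model(pseudocount: float = 0.8) -> MotifModel:
    return build_motif_model(synthetic_ctcf_pfm(), pseudocount=pseudocount)


def make_synthetic_catalog(k: int = 5, seed: int = 1234) -> SignatureCatalog:
    """Deterministic, well-separated synthetic signature catalogue.

    Signature i concentrates 85% of its mass on its own block of channels,
    with mild Dirichlet noise spread over all 96.
    """
    rng = np.random.default_rng(seed)
    block = 96 // k
    matrix = np.zeros((96, k))
    for i in range(k):
        main = np.zeros(96)
        lo = i * block
        hi = 96 if i == k - 1 else lo + block
        main[lo:hi] = rng.dirichlet(np.full(hi - lo, 2.0))
        noise = rng.dirichlet(np.full(96, 0.5))
        matrix[:, i] = 0.85 * main + 0.15 * noise
    matrix /= matrix.sum(axis=0)
    return SignatureCatalog(names=[f"SYN{i + 1}" for i in range(k)],
                            matrix=matrix)


@dataclass
class SimulationConfig:
    """Planted study conditions for one synthetic cohort.

    Defaults are toy-scale: a 2 Mb genome with 300 planted motifs and a
    40-patient cohort runs the full pipeline in seconds.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    n_planted_motifs: int = 300
    n_boundaries: int = 120
    boundary_width: int = 2_000
    peak_overlap_fraction: float = 0.85
    n_patients: int = 40
    mut_rate_off: float = 0.008       # per motif base per patient
    enrichment_factor: float = 2.0    # in-boundary rate multiplier
    mut_rate_background: float = 1e-5  # off-motif per-base rate
    titv_ratio: float = 2.0
    meth_shift: float = 0.2           # delta-beta shift on in-boundary probes
    meth_noise_sd: float = 0.15
    cna_segments_per_patient: int = 10
    cna_mean_size: int = 12_000
    cna_boundary_bias: float = 2.0    # 1.0 = unbiased placement
    signature_weights: tuple = (0.6, 0.3, 0.1, 0.0, 0.0)

    def validate(self) -> None:
        W = len(SYNTHETIC_CTCF_CONSENSUS)
        if self.n_planted_motifs * 2 * W > self.genome_length:
            raise ValueError("infeasible config: motifs do not fit the genome")
        if self.n_boundaries > self.n_planted_motifs:
            raise ValueError("more boundaries than planted motifs")
        for name in ("mut_rate_off", "mut_rate_background",
                     "peak_overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be > 0")
        if abs(sum(self.signature_weights) - 1.0) > 1e-6:
            raise ValueError("signature_weights must sum to 1")


@dataclass
class SyntheticCohort:
    """In-memory cohort plus the planted-truth manifest."""

    genome: dict[str, str]
    boundaries: IntervalCollection
    peaks: IntervalCollection
    mutations: list[MutationRecord]
    probes: list[MethylProbeRecord]
    segments: list[CnaSegment]
    sites: list[MotifSite]          # planted motifs with realised classes
    manifest: dict


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _draw_alt(ref: str, titv_ratio: float, rng: np.random.Generator) -> str:
    if rng.random() < titv_ratio / (titv_ratio + 1.0):
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][rng.integers(0, 2)]


def _draw_layout(config: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[list[int], IntervalCollection, IntervalCollection,
                            list[MotifSite]]:
    """Motif starts, boundary/peak intervals and realised site classes."""
    W = len(SYNTHETIC_CTCF_CONSENSUS)
    chrom = "chrS"
    L = config.genome_length
    slot = L // config.n_planted_motifs
    starts = []
    for i in range(config.n_planted_motifs):
        lo = i * slot
        hi = min((i + 1) * slot, L) - W
        starts.append(int(rng.integers(lo, hi)))

    order = rng.permutation(config.n_planted_motifs)
    boundary_motifs = set(order[:config.n_boundaries].tolist())
    boundaries = IntervalCollection("boundary")
    for i in sorted(boundary_motifs):
        center = starts[i] + W // 2
        half = config.boundary_width // 2
        boundaries.add(GenomicInterval(chrom, max(0, center - half),
                                       min(L, center + half)))
    peaks = IntervalCollection("peak")
    peak_flags = rng.random(config.n_planted_motifs) < config.peak_overlap_fraction
    for i, flag in enumerate(peak_flags):
        if flag:
            pad = int(rng.integers(20, 120))
            peaks.add(GenomicInterval(chrom, max(0, starts[i] - pad),
                                      min(L, starts[i] + W + pad)))

    sites: list[MotifSite] = []
    for s in starts:
        iv = GenomicInterval(chrom, s, s + W)
        sites.append(MotifSite(
            interval=iv, strand="+", score=0.0, score_fraction=1.0,
            active=peaks.overlaps_interval(iv),
            in_boundary=boundaries.overlaps_interval(iv)))
    return starts, boundaries, peaks, sites


def _draw_segments(config: SimulationConfig, sites: Sequence[MotifSite],
                   rng: np.random.Generator) -> list[CnaSegment]:
    """CNA segments with the configured in-boundary placement bias.

    With probability ``1 - 1/cna_boundary_bias`` a segment is centred on a
    random active in-boundary motif, otherwise uniformly — bias 1.0 is fully
    uniform placement. A quarter of segments get |seg_mean| < 0.2 so the
    mutated-segment filter has work to do.
    """
    W = len(SYNTHETIC_CTCF_CONSENSUS)
    L = config.genome_length
    chrom = "chrS"
    in_boundary_starts = [s.interval.start for s in sites
                          if s.active and s.in_boundary]
    p_target = 0.0 if config.cna_boundary_bias <= 1.0 else \
        1.0 - 1.0 / config.cna_boundary_bias
    segments: list[CnaSegment] = []
    for p in range(config.n_patients):
        sid = f"P{p:03d}"
        for _ in range(config.cna_segments_per_patient):
            size = int(rng.exponential(config.cna_mean_size)) + 1_000
            if in_boundary_starts and rng.random() < p_target:
                center = int(rng.choice(in_boundary_starts)) + W // 2
            else:
                center = int(rng.integers(0, L))
            start = max(0, center - size // 2)
            end = min(L, start + size)
            if rng.random() < 0.25:
                seg_mean = float(rng.uniform(-0.2, 0.2))   # not CNA-mutated
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                seg_mean = float(sign * (0.25 + abs(rng.normal(0.3, 0.15))))
            segments.append(CnaSegment(sample_id=sid, chrom=chrom,
                                       start=start, end=end,
                                       seg_mean=round(seg_mean, 4)))
    return segments


def simulate_cna_cohort(config: SimulationConfig, seed: int | None = None
                        ) -> tuple[list[CnaSegment], list[MotifSite]]:
    """Segments plus classified sites only, for repeated CNA calibration.

    Skips genome materialisation, mutations and probes, so hundreds of
    cohorts can be drawn; the layout and segment models are exactly those of
    :func:`generate_cohort`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    _, _, _, sites = _draw_layout(config, rng)
    return _draw_segments(config, sites, rng), sites


def generate_cohort(config: SimulationConfig,
                    outdir: str | Path | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; optionally write it to ``outdir``.

    Motifs are planted as exact consensus on the forward strand in evenly
    spaced slots. The first ``n_boundaries`` motifs (in shuffled order) get a
    boundary interval centred on them; each motif is independently covered
    by a ChIP-seq peak with probability ``peak_overlap_fraction``. Mutations
    are drawn per patient at ``mut_rate_off`` per off-boundary motif base and
    ``enrichment_factor`` times that in-boundary; background mutations fall
    outside motifs. Probe delta-betas are Normal(shift * 1{in-boundary},
    noise_sd) truncated to keep betas in [0, 1]. CNA segments are centred on
    a random in-boundary motif with probability ``1 - 1/cna_boundary_bias``
    and uniformly otherwise, so bias 1.0 is fully uniform placement.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    W = len(SYNTHETIC_CTCF_CONSENSUS)
    chrom = "chrS"
    L = config.genome_length

    # genome background + planted motifs, one per evenly spaced slot
    genome_arr = rng.integers(0, 4, size=L)
    starts, boundaries, peaks, sites = _draw_layout(config, rng)
    consensus_codes = [_BASE_INDEX[b] for b in SYNTHETIC_CTCF_CONSENSUS]
    for s in starts:
        genome_arr[s:s + W] = consensus_codes
    genome = {chrom: "".join("ACGT"[c] for c in genome_arr)}

    in_bases, off_bases = [], []
    for site in sites:
        if not site.active:
            continue
        target = in_bases if site.in_boundary else off_bases
        target.extend(range(site.interval.start, site.interval.end))
    in_bases = np.asarray(in_bases)
    off_bases = np.asarray(off_bases)
    motif_positions = set()
    for site in sites:
        motif_positions.update(range(site.interval.start, site.interval.end))

    # per-patient mutations
    rate_in = min(1.0, config.mut_rate_off * config.enrichment_factor)
    mutations: list[MutationRecord] = []
    for p in range(config.n_patients):
        sid = f"P{p:03d}"
        for bases, rate in ((in_bases, rate_in),
                            (off_bases, config.mut_rate_off)):
            if bases.size == 0 or rate == 0:
                continue
            n_mut = rng.binomial(bases.size, rate)
            if n_mut == 0:
                continue
            chosen = rng.choice(bases.size, size=n_mut, replace=False)
            for pos in bases[chosen]:
                ref = genome[chrom][pos]
                mutations.append(MutationRecord(
                    sample_id=sid, chrom=chrom, pos=int(pos), ref=ref,
                    alt=_draw_alt(ref, config.titv_ratio, rng),
                    cancer_type="SYN"))
        if config.mut_rate_background > 0:
            n_bg = rng.binomial(L, config.mut_rate_background)
            for pos in rng.integers(0, L, size=n_bg):
                pos = int(pos)
                if pos in motif_positions:
                    continue
                ref = genome[chrom][pos]
                mutations.append(MutationRecord(
                    sample_id=sid, chrom=chrom, pos=pos, ref=ref,
                    alt=_draw_alt(ref, config.titv_ratio, rng),
                    cancer_type="SYN"))

    # methylation probes: one per active motif, on the CpG at offset 15
    probes: list[MethylProbeRecord] = []
    probe_idx = 0
    for site in sites:
        if not site.active:
            continue
        pos = site.interval.start + 14
        beta_normal = float(rng.uniform(0.3, 0.7))
        shift = config.meth_shift if site.in_boundary else 0.0
        delta = shift + float(rng.normal(0.0, config.meth_noise_sd))
        beta_tumor = float(np.clip(beta_normal + delta, 0.0, 1.0))
        probes.append(MethylProbeRecord(
            probe_id=f"cg{probe_idx:06d}", chrom=chrom, pos=pos,
            beta_tumor=round(beta_tumor, 6),
            beta_normal=round(beta_normal, 6)))
        probe_idx += 1

    # CNA segments
    segments = _draw_segments(config, sites, rng)

    n_active_in = sum(1 for s in sites if s.active and s.in_boundary)
    n_active_off = sum(1 for s in sites if s.active and not s.in_boundary)
    manifest = {
        "config": asdict(config),
        "motif_consensus": SYNTHETIC_CTCF_CONSENSUS,
        "motif_starts": starts,
        "site_classes": [s.site_class for s in sites],
        "n_active_in_boundary": n_active_in,
        "n_active_off_boundary": n_active_off,
        "expected_in_fraction": (n_active_in / (n_active_in + n_active_off)
                                 if n_active_in + n_active_off else None),
        "n_mutations": len(mutations),
        "n_probes": len(probes),
        "n_segments": len(segments),
        "planted": {
            "enrichment_factor": config.enrichment_factor,
            "meth_shift": config.meth_shift,
            "cna_boundary_bias": config.cna_boundary_bias,
            "titv_ratio": config.titv_ratio,
            "signature_weights": list(config.signature_weights),
        },
    }
    cohort = SyntheticCohort(genome=genome, boundaries=boundaries,
                             peaks=peaks, mutations=mutations, probes=probes,
                             segments=segments, sites=sites,
                             manifest=manifest)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.genome, outdir / "genome.fa")
    write_bed(cohort.boundaries, outdir / "boundaries.bed")
    write_bed(cohort.peaks, outdir / "peaks.bed")
    write_mutations(cohort.mutations, outdir / "mutations.tsv")
    write_probes(cohort.probes, outdir / "probes.tsv")
    write_segments(cohort.segments, outdir / "segments.seg")
    from .io_formats import write_jaspar_pfm
    write_jaspar_pfm(synthetic_ctcf_pfm(), outdir / "motif.pfm",
                     name="SYN_CTCF")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Counts-level cohort simulation (for repeated statistical calibration)
# ---------------------------------------------------------------------------

def simulate_patient_counts(n_patients: int, n_bases_in: int,
                            n_bases_off: int, mut_rate_off: float,
                            enrichment_factor: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw a P x 2 per-patient (in, off) mutation-count table directly.

    Binomial sampling over motif bases — the same count model the full
    generator induces, without materialising sequences, so thousands of
    cohorts can be simulated for type-I/power calibration.
    """
    rate_in = min(1.0, mut_rate_off * enrichment_factor)
    col_in = rng.binomial(n_bases_in, rate_in, size=n_patients)
    col_off = rng.binomial(n_bases_off, mut_rate_off, size=n_patients)
    return np.column_stack([col_in, col_off])


# ---------------------------------------------------------------------------
# Signature-driven mutation generation (for exposure-recovery checks)
# ---------------------------------------------------------------------------

def generate_signature_mutations(genome: Mapping[str, str], n_mutations: int,
                                 weights: Sequence[float],
                                 catalog: SignatureCatalog,
                                 rng: np.random.Generator,
                                 sample_id: str = "SIG"
                                 ) -> list[MutationRecord]:
    """Draw mutations whose 96-channel spectrum follows ``catalog @ weights``.

    Mutations are placed at pyrimidine-centred genome positions with the
    channel's 3-mer context (purine-centred equivalents map to the same
    channels, so generating only at pyrimidines leaves the spectrum
    unchanged).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (catalog.k,) or abs(w.sum() - 1.0) > 1e-6 or (w < 0).any():
        raise ValueError("weights must be a probability vector over the catalogue")
    probs = catalog.matrix @ w
    probs = probs / probs.sum()

    context_positions: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for i in range(1, len(seq) - 1):
            if seq[i] in "CT":
                context_positions.setdefault(seq[i - 1:i + 2], []).append((chrom, i))

    mutations: list[MutationRecord] = []
    channel_ids = rng.choice(96, size=n_mutations, p=probs)
    for cid in channel_ids:
        channel = CHANNELS_96[cid]
        context = channel[0] + channel[2] + channel[6]
        alt = channel[4]
        pool = context_positions.get(context)
        if not pool:
            continue
        chrom, pos = pool[rng.integers(0, len(pool))]
        mutations.append(MutationRecord(sample_id=sample_id, chrom=chrom,
                                        pos=pos, ref=channel[2], alt=alt,
                                        cancer_type="SYN"))
    return mutations


# ---------------------------------------------------------------------------
# Recovery reporting
# ---------------------------------------------------------------------------

def manifest_compare(results: Mapping[str, object], manifest: Mapping,
                     alpha: float = 0.05) -> dict:
    """Compare pipeline results with the planted truth of a cohort.

    ``results`` maps stage names ("mutation", "methylation", "cna",
    "signatures") to their result objects; stages absent from ``results``
    are listed as not run.
    """
    planted = manifest["planted"]
    report: dict = {"stages": {}}
    for stage in ("mutation", "methylation", "cna", "signatures"):
        if stage not in results or results[stage] is None:
            report["stages"][stage] = {"run": False}
            continue
        entry: dict = {"run": True}
        res = results[stage]
        if stage == "mutation":
            entry["p_value"] = res.p_value
            entry["significant"] = res.p_value < alpha
            entry["planted_enrichment_factor"] = planted["enrichment_factor"]
        elif stage == "cna":
            entry["p_value"] = res.p_value
            entry["significant"] = res.p_value < alpha
            entry["planted_cna_boundary_bias"] = planted["cna_boundary_bias"]
        elif stage == "methylation":
            entry["empirical_p"] = res.empirical_p
            entry["direction"] = ("hyper" if res.observed_mean_in
                                  > res.observed_mean_off else "hypo")
            entry["planted_meth_shift"] = planted["meth_shift"]
        elif stage == "signatures":
            est = np.asarray(res.weights)
            true = np.asarray(planted["signature_weights"])
            if est.shape == true.shape:
                entry["mean_abs_exposure_error"] = float(
                    np.abs(est - true).mean())
            entry["weights"] = est.tolist()
        report["stages"][stage] = entry
    return report
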