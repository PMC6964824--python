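# Methods

This note documents the models, parameter choices and numerical conventions
behind `boundaryalt`, and what the synthetic validation does and does not
establish about real cohorts.

## Coordinates and formats

All internal coordinates are 0-based half-open; overlap means sharing at
least one base under that convention (touching intervals do not overlap).
BED input is consumed natively; mutation, methylation-probe and SEG tables
default to 1-based input and are shifted at parse time. Chromosome names are
normalised to the `chr`-prefixed form so ICGC-style (`1`) and ENCODE-style
(`chr1`) inputs join. Malformed data rows are counted and skipped
(consortium dumps are messy); structural problems — a missing mandatory
column, a malformed FASTA — are fatal. Records on chrY are kept by default
(`drop_chrY` is available on the mutation reader).

## Motif model and scanning

A position frequency matrix (4 x W counts; W = 19 for the CTCF motif) is
regularised with a pseudocount split across bases by the background
distribution and converted to log2 odds:

    score[b, j] = log2( (counts[b, j] + c * bg[b]) / (total_j + c) / bg[b] )

Defaults: pseudocount `c = 0.8`, uniform background. Both are configurable;
neither materially affects which windows pass a high threshold for an
informative matrix.

The score fraction of a window is min-max normalised,
`(S - S_min) / (S_max - S_min)`, where `S_min`/`S_max` sum per-column
minima/maxima. This is the convention of Biostrings-style PWM matching and
is deliberately documented because "80% of the maximum score" is a plausible
but different reading: log-odds minima are negative, so the two
normalisations select very different site sets. The default threshold is a
score fraction of 0.80.

Both strands are scanned; reverse-strand hits are reported on forward
coordinates with strand `-`, computed by applying the reverse-complemented
score matrix to forward windows. Windows containing N are skipped rather
than penalised. Opposite-strand hits at the same locus are both reported by
default; `dedup_sites` collapses them keeping the higher score (the pipeline
runner dedups). Scanning is strand-symmetric and monotone in the threshold;
both properties are tested.

A site is **active** if it overlaps a ChIP-seq peak and **in-boundary** if
it overlaps a boundary interval (>= 1 bp each); the four resulting classes
partition the site set.

## Per-patient mutation enrichment

For each patient, SNVs falling inside the 19 bp body of active motifs are
counted by class (in-boundary vs off-boundary); flanking regions contribute
to positional profiles but never to the tests. Patients with fewer than 5
mutations in *either* class are discarded (a `rule="both"` variant relaxes
this to "in both").

Two tests are offered on the resulting `P x 2` table:

* `chi_square_homogeneity` — the Pearson chi-square of independence with
  dof `(P-1)`, Yates-corrected iff the table is exactly 2x2. This is the
  classical test and the one applied to the Ti/Tv contrast.
* `enrichment_gof_test` (default for enrichment questions) — a summed
  per-patient goodness-of-fit chi-square against the in-boundary fraction
  `q` expected with no enrichment, taken from the active motif-class base
  composition; dof = P.

The design choice matters: the homogeneity test asks whether *patients
differ from each other* and is blind, by construction, to an enrichment
multiplier shared by the whole cohort — under a uniform 2x in-boundary rate
increase the table remains perfectly homogeneous. The goodness-of-fit test
asks whether patients deviate from the *compositional* expectation and is
the variant under which both calibration properties hold on synthetic
cohorts: type-I error 5% +- 2% at the nominal 0.05 level with no planted
effect, and power >= 90% at a 2x multiplier with >= 30 patients averaging
>= 20 mutations. Both are verified in the test suite at those sizes (1000
and 400 simulated cohorts respectively, simulated at the count level — the
binomial count model the full generator induces — so calibration runs in
seconds). The homogeneity variant remains available via
`method="homogeneity"` and detects patient-heterogeneous enrichment, which
is plausibly the dominant signal in real cohorts.

Yates correction is applied only to 2x2 tables. This choice reproduces, to
their printed precision, twelve published per-cancer transition/transversion
chi-square p-values recomputed from their printed count tables (two further
published rows are internally inconsistent with their own counts under both
the corrected and uncorrected statistic and are excluded from that check).

Transitions are purine-to-purine or pyrimidine-to-pyrimidine substitutions
(A<->G, C<->T); the eight remaining ordered pairs are transversions.

## Positional profiles, promoters, gene proximity

Profiles anchor mutations to motif-oriented offsets: positions 1..W inside
the motif (centre at 10 for W = 19), negative/super-W offsets in the flanks
(half-width 1000 for broad profiles, 50 for typed close-ups). Minus-strand
sites flip coordinates; ref/alt strand normalisation is opt-in and off by
default, since published profiles of this kind are displayed in genome
orientation (symmetric G>A / C>T peaks). Promoters are strand-independent
windows [TSS - 2 kb, TSS + 2 kb) clipped at the origin. Gene proximity uses
motif-centre-to-TSS distance with a closed 180 kb threshold (the average
size of an insulated neighbourhood); per gene, the number of distinct
samples with a qualifying mutated motif and the minimum distance are
reported.

## Signature refitting

Spectra use the 96 pyrimidine-centric trinucleotide channels in the
conventional catalogue order (C>A block first, flanks lexicographic);
purine-centred mutations map to the reverse-complement channel. Mutations
whose ref disagrees with the genome, or that sit at a contig edge, are
counted and skipped.

Refitting minimises the Euclidean distance between the normalised spectrum
and the catalogue-weighted mixture on the probability simplex (the
"frequency model"). The convex program is solved with SLSQP from a uniform
start with analytic gradient (`ftol` 1e-14, 500 iterations), then clipped
and renormalised; the solution is deterministic, scale-invariant in the
spectrum counts, and agrees with a 1e-3-resolution simplex grid search to
2e-3 on 2-signature problems. A multinomial-likelihood objective is out of
scope. No reference catalogue is bundled: any column-stochastic 96 x K TSV
is accepted, and a deterministic 5-signature synthetic catalogue
(`make_synthetic_catalog`) supports the tests.

## Methylation

Probes join to active motifs positionally (ties to the higher-scoring
site), with 1-based strand-oriented motif offsets. Classification at
threshold 0.2 uses strict inequalities: delta-beta of exactly +-0.2 is
"normal". The group test draws `m = min(n_in, n_off)` probes per group with
replacement per iteration (10,000 iterations by default) and reports
`empirical_p = #(mean_in <= mean_off) / n_iter`; ties count as "not
greater", conservative for hyper-methylation claims, and no +1 smoothing is
applied so exact 0 and 1 are reportable. A without-replacement subsample
variant (`method="permutation"`) is provided; the published description
("sampled an equal number of probes") is ambiguous between the two, and the
bootstrap is the default. Antisymmetry (swapping groups maps p to ~1-p),
seed determinism, null calibration (mean p in [0.4, 0.6] over 50 seeds) and
complete-separation exactness are tested.

## CNA

Segments are CNA-mutated iff `|segment mean| > 0.2` (strict). Size strata
are *cumulative*: the q% group holds segments no longer than the
nearest-rank q-th percentile cutoff (`ceil(q/100 * n)`-th smallest), so
25% ⊆ 50% ⊆ 75% ⊆ 100%; disjoint bins were the alternative reading, and the
cumulative form matches the small-CNA rationale (a large CNA dysregulates by
many mechanisms at once; preferential boundary overlap is only informative
for small ones). Per patient, the columns count active in-/off-boundary
motifs covered by at least one retained segment (a motif counts once per
patient; a per-segment binary variant is the natural alternative and
deliberately not the default since the question is about motifs hit).
Patients need at least one covered motif in both columns. The test defaults
to the goodness-of-fit form against the motif composition, for the same
power reason as above.

## Conservation

Cross-cohort overlap of altered-boundary identifier sets uses the
upper-tail hypergeometric probability P(X >= k) via scipy's survival
function (log-space stable); the upper tail is the only direction
consistent with a conservation claim. The universe is the caller's choice —
the pipeline's natural default is the active in-boundary motif set shared by
the compared cohorts. The pairwise matrix is symmetric, reported raw with no
multiple-testing correction (a Benjamini-Hochberg pass is trivial to add
downstream but not applied, matching the descriptive presentation).

## Synthetic cohorts

The generator emulates the statistical structure each analysis assumes, at
toy scale (defaults: 2 Mb genome, 300 motifs, 40 patients; the full
pipeline runs in seconds):

* i.i.d. uniform ACGT background with exact-consensus motif insertions, one
  per evenly spaced slot — scanner recovery is deterministic (a 0.99 score
  fraction admits only exact consensus), separating scanner correctness
  from power questions. The bundled matrix is a synthetic CTCF-like 19-mer
  (85/5/5/5 counts per column, one CpG) — a stand-in, not the JASPAR
  matrix, which users supply as a PFM file for real scans.
* boundaries centred on a random motif subset (width 2 kb), peaks covering
  each motif independently with probability 0.85 — all four classes
  populated.
* mutations: per patient, binomial over motif bases at 0.008 per base
  off-boundary (about 24 motif mutations per patient, comfortably above the
  retention rule) times `enrichment_factor` in-boundary, plus a 1e-5
  per-base background; alt alleles follow a 2:1 Ti:Tv ratio.
* methylation: one probe per active motif at the CpG offset;
  delta-beta ~ Normal(shift * 1{in-boundary}, 0.15) with betas clipped to
  [0, 1]; default shift +0.2.
* CNA: 10 segments per patient, exponential sizes (mean 12 kb — about twice
  the motif spacing, mirroring the genome-scale ratio of reported median
  CNA sizes to motif spacing), a quarter with |mean| < 0.2 to exercise the
  filter. `cna_boundary_bias` b centres a segment on a random active
  in-boundary motif with probability 1 - 1/b (b = 1 is fully uniform).
* signature-driven mutations are drawn channel-first from `catalog @ w` and
  placed at matching pyrimidine-centred genome contexts.

Everything is a pure function of the config seed; emitted files are
checksum-stable and re-parse with zero rejected rows.

**What passing synthetic tests does not show.** The generator has no
mutation-rate covariates (replication timing, chromatin state, expression),
no probe-density gradients, no CNA breakpoint clustering, no LD between
alterations, and plants spatially uniform effects. Calibration and power on
these cohorts validate the machinery and its implementation, not the
biological effect sizes; on real cohorts the homogeneity/goodness-of-fit
distinction above, and the choice of universe for conservation tests,
deserve explicit thought.

## Numerical and edge-case policy

* Degenerate flat PWMs (max score = min score) are rejected.
* Chi-square tests reject tables with an all-zero row or column and flag
  expected counts below 5; the Ti/Tv wrapper returns counts with a `None`
  test when a margin is zero.
* Empty mutation sets give empty contingency tables; the downstream test
  raises rather than fabricating a p-value.
* Percentile cutoffs use nearest-rank (no interpolation), so reported
  medians are realised segment sizes.
* Bootstrap p-values are exact fractions of the iteration count.
* The pipeline runner records per-stage errors and continues with
  independent stages; the summary matrix marks failed or input-less stages
  with `-`, uses strict `p < alpha` (0.05) for Y cells, and signs
  methylation calls by the observed mean delta-beta difference.

## Problem sizes used in validation

Oracle-equivalence checks run >= 100 randomised instances per engine
(scanning, interval overlap, positional profiles, hypergeometric tails).
Enrichment calibration uses 1000 null and 400 alternative simulated
cohorts at the generator's default composition; methylation null
calibration uses 50 seeds x 2000 iterations; CNA calibration uses the
segments-only simulator (150 cohorts per bias level in exploratory runs,
reported by `scripts/acceptance.py` at the same scale). These sizes were
chosen so the whole suite completes in well under a minute on one core
while keeping Monte-Carlo error far from the asserted bounds.

## Known limitations

* ChIA-PET loop records must be pre-reduced to boundary BED intervals by
  the user; anchor widths and merging policy are consortium-specific and
  deliberately not guessed here.
* Only single-nucleotide substitutions are analysed; indels and MNVs are
  rejected at parse time.
* Signature refitting offers the frequency objective only; no de novo
  extraction, no exposure confidence intervals.
* The hypergeometric conservation test models exchangeable identifiers and
  ignores genomic clustering; a permutation test respecting spatial
  structure would be stricter.
* The enhancer-class analysis (H3K4me1 ∩ H3K27ac) is not implemented as a
  stage; the interval machinery supports it, but in practice such
  intersections are too sparse at motif scale for a stable test.
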