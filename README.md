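# boundaryalt

Pan-cancer analysis of genome alterations at CTCF binding motifs overlapping
insulated-neighbourhood boundaries.

Chromatin loops ("insulated neighbourhoods", the sub-TAD units of genome
folding) are anchored by CTCF. Somatic mutations, aberrant DNA methylation
and copy-number alterations (CNAs) at the anchoring CTCF motifs can disrupt a
loop and dysregulate the genes it insulates. `boundaryalt` implements, as a
tested and reusable pipeline, the statistics needed to ask whether a tumour
cohort preferentially alters such motifs:

1. **Motif scanning and classification.** A JASPAR-style position frequency
   matrix is turned into a log-odds PWM and the genome is scanned on both
   strands; windows with min-max-normalised score fraction
   `(S - S_min) / (S_max - S_min) >= 0.80` are motif sites. Each site is
   classified *active* (>= 1 bp overlap with a CTCF ChIP-seq peak) and
   *in-boundary* (overlap with a loop-boundary interval).
2. **Mutation enrichment.** Per patient, SNVs on active in-boundary vs
   off-boundary motifs form a `P x 2` table. Two tests are provided: the
   chi-square of homogeneity across patients, and (default) a per-patient
   goodness-of-fit chi-square against the split expected from the active
   motif composition, `sum_i [(O_i1 - n_i q)^2/(n_i q) + (O_i2 - n_i(1-q))^2
   /(n_i(1-q))] ~ chi^2_P`, which has power against a cohort-wide
   enrichment. Patients with fewer than 5 mutations in either class are
   discarded.
3. **Transitions vs transversions.** A 2x2 in/off-boundary by Ti/Tv table
   with the Yates-corrected chi-square.
4. **Mutational signatures.** 96-channel trinucleotide spectra and signature
   refitting by simplex-constrained least squares,
   `min_w ||f - M w||^2, w >= 0, sum w = 1`.
5. **Methylation.** Per-probe `delta-beta = beta_tumor - beta_normal` on
   motif classes, +-0.2 hypo/hyper classification, and a 10,000-iteration
   resampling null for in-boundary over-methylation (empirical p is the
   fraction of resamples where mean in-boundary delta-beta fails to exceed
   the off-boundary mean; exact 0 and 1 are possible).
6. **CNA.** Segments with `|segment mean| > 0.2` are CNA-mutated, stratified
   by nearest-rank size percentiles, and tested per patient for preferential
   coverage of in-boundary motifs.
7. **Conservation.** Upper-tail hypergeometric tests of cross-cohort overlap
   of altered boundary sets.

A synthetic-cohort generator plants every effect (enrichment multiplier,
delta-beta shift, CNA placement bias, signature exposures) at known sizes so
each stage is testable end to end without external downloads.

## Worked example

Generate a 2 Mb toy cohort (300 planted motifs, 40 patients, 2x in-boundary
mutation enrichment, +0.2 delta-beta shift, 2x CNA placement bias) and run
every stage:

```sh
boundaryalt simulate --seed 7 --outdir demo/cohort
# wrote cohort to demo/cohort: 3002 mutations, 256 probes, 400 segments

cat > demo/config.yaml <<EOF
fasta: demo/cohort/genome.fa
boundaries: demo/cohort/boundaries.bed
peaks: demo/cohort/peaks.bed
mutations: demo/cohort/mutations.tsv
probes: demo/cohort/probes.tsv
segments: demo/cohort/segments.seg
pfm: demo/cohort/motif.pfm
min_fraction: 0.99
cancer_type: SYN
EOF

boundaryalt run-all --config demo/config.yaml --out demo/results.json
#     mutation methylation cna
# SYN        Y        Y(+)   N
```

The JSON bundle holds the underlying numbers:

```json
"class_summary": {"active_in_boundary": 107, "active_off_boundary": 149,
                  "inactive_in_boundary": 14, "inactive_off_boundary": 30},
"mutation":    {"statistic": 287.21, "dof": 40, "p_value": 3.93e-39},
"methylation": {"empirical_p": 0.0, "mean_in": 0.177, "mean_off": 0.0079},
"cna":         {"statistic": 28.85, "dof": 21, "p_value": 0.118}
```

Reading this: all four motif classes are populated; the planted 2x mutation
enrichment is detected overwhelmingly (p ~ 1e-39 over 40 patients); the
planted methylation shift gives empirical p = 0 with mean in-boundary
delta-beta 0.18 vs 0.008 off-boundary, summarised `Y(+)` for significant
hyper-methylation. The CNA cell is `N` because the default analysis uses the
median segment-size cutoff (the small-CNA focus), which halves the segment
set and retains only 21 patients; on the full mutated-segment set
(`--percentile 100`) the planted bias is detected at p = 9.1e-5 over all
40 patients.

Every stage is also exposed as a library function
(`scan_genome`, `classify_sites`, `count_per_patient`,
`chi_square_homogeneity`, `refit_exposures`, `bootstrap_group_test`,
`cna_contingency_test`, `hypergeometric_overlap`, ...) and as an individual
subcommand (`scan`, `classify`, `mut-enrich`, `titv`, `profile`,
`near-genes`, `signatures`, `meth`, `cna`, `overlap`).

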