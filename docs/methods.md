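# Methods

## Epiallele model

A bisulfite-converted molecule reports the methylation state of every
cytosine it covers: unmethylated C deaminates to U and is sequenced as T,
methylated C is protected and stays C. On the original bottom strand the
same chemistry appears, in plus-strand orientation, as G (methylated) or A
(unmethylated) at the reference G paired with the minus-strand C. Over the
*n* CpX sites of a genomic window, each read that spans the window end to
end therefore yields one binary string — its **epiallele** — out of the 2^n
possible species, and a sample's reads at that window form a population
whose composition reflects the mixture of epigenetic states among its cells.

The extraction step assumes:

- reads are aligned by a bisulfite-aware aligner and coordinate-sorted and
  indexed; the bisulfite strand of origin is taken from the Bismark `XG`
  tag (`CT` = original top, `GA` = original bottom) and falls back to the
  reverse-strand FLAG bit when the tag is absent. The tag is preferred
  because for paired-end data the mapping strand of a mate is not in
  general the bisulfite strand of origin;
- methylation calls are recomputed against the reference, not taken from an
  aligner's XM string, so the behavior is aligner-version independent;
- only reads spanning a window end to end are informative (an epiallele is
  a property of a single molecule), which bounds usable window length by
  the read length;
- a base that is neither the methylated nor the converted base (a SNV,
  sequencing error, or a deletion over the site) makes the call
  **ambiguous** (code 2); reads with any ambiguous call stay in the binary
  matrix but are excluded from the compressed epiallele table and from all
  summary statistics, so counts, entropy and methylation averages are
  mutually consistent over the same read set.

CpG sites are palindromic, so the two strands of one CpG unit can be pooled
(**merged** mode, keyed by the plus-strand C position) or profiled as two
independent populations (**stranded** mode). Non-CG contexts (CA, CC, CT)
are not palindromic and are always stranded.

## Coverage and window design

Coverage is computed genome-wide at single-base resolution from the aligned
gapless blocks of each kept alignment: bases under a deletion contribute
nothing, and secondary (0x100), duplicate (0x400) and supplementary (0x800)
records are skipped by default (configurable) to avoid double counting.
Maximal runs of bases at or above `min_coverage` become covered regions.

Two window schemes tile the covered regions:

- **site-count** windows hold exactly `k` sites, stepping one site at a
  time (adjacent windows share k−1 sites); windows longer than `max_len`
  bp (the read length) are dropped, and all k sites must come from one
  covered region so the coverage guarantee holds;
- **fixed-length** windows of `win_len` bp slide at `step` bp and are kept
  when they contain between `min_sites` and `max_sites` sites.

Window intervals include the second base of the terminal dinucleotide
(site-count mode), and the read-spanning requirement always extends over
every site's full dinucleotide, so the last site of a window is never
called from a truncated context.

## Conversion quality check

Bisulfite conversion is imperfect; an unconverted read inflates apparent
methylation. Treating non-CpX methylation as negligible, the per-read
conversion efficiency is the fraction of reference cytosines on the read's
strand inside the window — outside the CG context and, for non-CG analyses,
also outside the analyzed context (configurable, since a non-CG analysis
presumes that context can be genuinely methylated) — that the read shows as
converted. Reads below `min_conversion` (default 0.90) are removed when the
filter is enabled (off by default). A read with no assessable cytosines
passes vacuously: absence of evidence is not grounds for discarding data.
After filtering, a window whose unambiguous read count falls below
`min_coverage` is excluded and logged with the reason
(`no_spanning_reads`, `all_reads_ambiguous`, or
`insufficient_coverage_after_qc`).

## Summary statistics

Per window, over unambiguous QC-passing reads only: site count *n*; read
count *c*; mean inter-site distance *d* = mean |p_{i+1} − p_i| in bp
(reported as a positive length; undefined below 2 sites); observed species;
singleton species; the dominant epiallele (ties break to the
lexicographically smallest string, documented and deterministic); Shannon
entropy H = −Σₖ pₖ log₂ pₖ in bits, with 0·log 0 = 0, ranging from 0
(monoclonal) to *n* (all 2^n species equally frequent); and average
methylation a = m/(n·c). The registry is extensible with user functions of
the binary matrix; a failing user statistic yields a missing value and a
logged warning rather than aborting the run.

## Group statistics

**Composition (PERMANOVA).** Per window, samples' epiallele counts become
relative-frequency vectors (union of species across samples, absent species
0), making the test invariant to sequencing depth; whether to test raw
counts or frequencies is recorded in the output metadata. Bray–Curtis
distances feed the one-factor pseudo-F
F = (SS_among/(a−1)) / (SS_within/(N−a)) computed from sums of squared
distances, and significance comes from random label permutations with
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) — never exactly zero. Defaults:
999 permutations, ≥3 samples per group per window, BH adjustment across
tested windows (under-covered windows are reported untested). Small designs
can be enumerated exhaustively (`method="exact"`); the Monte-Carlo
estimator is validated against that enumeration, and the pseudo-F against
scikit-bio's implementation, in the test suite. Note the permutation floor:
with n₁ = n₂ = 4 only 70 label partitions exist, so no p below 2/70 ≈ 0.029
is attainable at that design size. Pairwise post-hoc PERMANOVA (≥3 groups)
adjusts across pairs within the window. Species contributions to
between-group dissimilarity use the SIMPER identity — Bray–Curtis
decomposes additively as d(x,y) = Σ_s |x_s − y_s| / Σ_s (x_s + y_s) —
averaged over between-group sample pairs; contributions sum to the mean
between-group dissimilarity.

**Summary statistics.** Two groups: two-sided Wilcoxon–Mann–Whitney. The
null is enumerated exhaustively over all label rearrangements whenever
C(n₁+n₂, n₁) ≤ 5·10⁵ (roughly combined n ≤ 20), using midranks, so the test
is exact even with heavy ties — e.g. four 0s vs four 2s gives exactly
p = 2/70; larger designs use the normal approximation with tie and
continuity corrections. More than two groups: Kruskal–Wallis. Windows with
constant values across all samples are flagged degenerate with p = 1.
Per-group medians are reported; BH adjustment across windows.

**ANCOVA.** `statistic ~ group + covariate + group:covariate` by ordinary
least squares; type-II F-tests for the three terms; per-group slopes
(reference slope plus interaction offsets) with standard errors from the
coefficient covariance. Rank-deficient windows (missing group, constant
covariate within a group, too few residual degrees of freedom) are flagged
and skipped.

**Ordination.** PCA is the SVD of the column-centered frequency matrix
(scores and variance fractions). CCA is correspondence analysis of the
count matrix constrained on group indicators: chi-square standardization
Q = (P − rcᵀ)/√(rcᵀ), weighted regression of Q on centered, √r-weighted
dummies, then SVD of the fitted part; at most (groups − 1) constrained
axes, inertia fractions relative to total inertia.

**Significance filter.** A convenience filter combines rank-test p ≤ 0.05,
absolute between-group median difference of the tested statistic ≥ 0.10,
and PERMANOVA p ≤ 0.05; all three thresholds are parameters.

## Annotation

Windows are assigned to the gene whose TSS is closest to the window
midpoint; the signed distance is negative upstream relative to gene
orientation. Categories follow the precedence Promoter > 5′ UTR > 3′ UTR >
Exonic > Intronic > Distal intergenic, with Promoter meaning the midpoint
lies within `promoter_flank` bp of some TSS. The default flank is 1000 bp
and both value and unit are explicit parameters, logged at run time. Gene
models come from GTF/GFF3 (via gffutils) or BED12 (exon blocks; UTRs
derived from the thick/CDS interval).

## The simulator

The simulator is the package's ground-truth instrument. It builds a
reference whose background alternates A/T, so the only cytosines are
planted: analyzed CpX dinucleotides and QC cytosines placed outside both
the CG and the analyzed context. Reads are single-end, full-length-match
CIGAR, stacked exactly over each region so every read spans every window;
each molecule draws its epiallele from the sample's per-strand mixture,
converts its QC cytosines except with the given conversion-failure
probability, and corrupts site bases to a non-bisulfite base at the given
SNV rate. An optional mode adds one read with a 1-bp deletion at a site to
exercise the indel-to-ambiguous path. Truth files record both per-read
outcomes (epiallele, SNV, conversion failures) and realized per-sample
counts, so zero-noise round trips are exact, not approximate. Defaults — 30
reads per strand per region, 100 bp regions, zero noise — mirror the
coverage conventions of typical RRBS reanalysis (regions covered end to end
by ≥30 reads, ~70–100 bp reads).

What the simulator does **not** emulate: position-dependent quality scores
and sequencing error profiles, PCR duplicates, paired-end mates and mate
overlap, soft-clipping, CpG-density-realistic genomic background,
incidental off-context cytosines, or mappability artifacts. Passing tests
therefore establish the correctness of the algorithms (coordinate handling,
strand logic, filters, statistics), not the error characteristics of any
particular sequencing platform.

## Numerical choices and scale

- All public coordinates are 1-based inclusive (SAM/FASTA convention);
  conversion to 0-based half-open happens only at pysam/BED boundaries.
- Permutation p-values use the (1+b)/(1+n_perm) estimator; F comparisons
  use a 1e-12 slack so ties at the observed value count as exceedances;
  zero within-group sums of squares yield F = ∞, which orders correctly
  under the same comparison.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single user seed; derived seeds stay below 2³¹. Seeded runs are
  bit-reproducible, and output rows are sorted (window id, then epiallele)
  so reruns are byte-identical.
- Test and validation problem sizes — 20 regions × 6 samples for round
  trips, 500 null windows × 999 permutations for calibration, 200 windows
  for power — were chosen as the smallest sizes at which the binomial
  uncertainty of the measured rates is well inside the asserted bands.

## Known limitations

- Each alignment record counts independently; overlapping mates of a pair
  would be double-counted (flagged for future mate-aware deduplication).
- Base-quality floors default to off; Phred-aware calling is available but
  conversion-efficiency assessment ignores quality.
- PERMANOVA supports a single grouping factor (plus pairwise post-hoc);
  multi-factor designs and repeated-measures structure are out of scope.
- The annotation step uses gene models only; it does not consult external
  peak sets or run pathway enrichment.
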