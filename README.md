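# epialleles

Qualitative analysis of DNA methylation from bisulfite sequencing: extract
read-level methylation patterns (**epialleles**) over user-designed CpX
windows, summarize their heterogeneity, and statistically compare epiallele
compositions between sample groups.

Classical methylation analysis averages the methylation level of each
cytosine over all molecules in a bulk sample. That average discards the
*pattern* each single sequenced molecule carries: a locus with *n* CpX sites
admits 2^n distinct binary methylation haplotypes, and their distribution is
a proxy for cell-to-cell epigenetic heterogeneity, clonality and
allele-specific methylation. This package profiles those distributions
genome-wide from any bisulfite experiment (RRBS, WGBS, targeted), in the CG
context or the strand-asymmetric non-CG contexts (CA, CC, CT), with optional
strand-separated or strand-merged (CG only) extraction — and then asks where
they differ between biological groups. It is written for epigenomics
researchers working from Bismark-style coordinate-sorted BAM files plus the
reference FASTA.

## What it computes

For every analysis window (designed by sliding windows with either a fixed
number of *k* CpX sites or a fixed bp length) and every sample:

- a binary **reads × sites matrix** with entries 0 (unmethylated: T on the
  originating strand at a reference C), 1 (methylated: the C is retained) or
  2 (ambiguous: any other base or a deletion, e.g. a SNV) — reads must span
  the window end to end;
- a per-read **bisulfite conversion efficiency** (fraction of converted
  cytosines outside the CG / analyzed context inside the window), with an
  optional filter for poorly converted reads;
- the **compressed epiallele table** counting each observed pattern (rows
  containing a 2 are excluded), and per-window summary statistics: number of
  sites *n*, spanning reads *c*, mean inter-site distance *d*, number of
  observed species, singletons, the dominant epiallele, the Shannon entropy
  H = −Σₖ pₖ log₂ pₖ ∈ [0, n], and the average methylation a = m/(n·c).

Between groups it then runs:

- **PERMANOVA** on Bray–Curtis distances between per-sample epiallele
  frequency vectors (pseudo-F, R², label-permutation p, Benjamini–Hochberg
  FDR across windows), with pairwise post-hoc tests for >2 groups and a
  SIMPER-style decomposition of which species drive the dissimilarity;
- **Wilcoxon–Mann–Whitney** (2 groups, exact for small designs) or
  **Kruskal–Wallis** (>2) on any summary statistic;
- **ANCOVA** (OLS, `statistic ~ group * covariate`) with per-group slopes;
- **PCA / CCA** ordination of samples at a locus.

A bundled simulator plants known epiallele mixtures, strands,
conversion-failure and SNV rates into a synthetic reference + sorted,
indexed BAMs with an exact per-read truth table, so the entire pipeline is
testable offline.

## Worked example

Simulate two groups of four samples whose regions carry different epiallele
mixtures (group A: 80% `00` / 20% `11`; group B: 30% `00` / 20% `01` /
50% `11`), then run the workflow:

```python
import pandas as pd
from epialleles import *
from epialleles.summaries import SummaryRegistry, summary_table

spec = default_spec(n_regions=2, samples_per_group=4, seed=42,
                    mixtures_by_group={"A": {"00": 0.8, "11": 0.2},
                                       "B": {"00": 0.3, "01": 0.2, "11": 0.5}})
ds = simulate_dataset(spec, "demo")
ref = load_reference(ds.fasta)
regions = covered_regions(open_alignments(ds.bams["A1"]), min_coverage=30)
wins = design_windows(ref, regions, "CG", scheme="site_count", k=2,
                      max_len=100, strand_mode="merged")

tables, summaries = [], []
for sid, path in ds.bams.items():
    res = extract_sample(open_alignments(path), ref, wins, sample_id=sid)
    tables += res.tables
    summaries.append(summary_table(res.matrices, sample_id=sid))
summary = pd.concat(summaries, ignore_index=True)

comp = epistat(tables_to_frame(tables), ds.metadata, n_perm=999, seed=1)
stat = diffstat(summary, ds.metadata, "shannon")
hits = significant_regions(stat, comp, groups=("A", "B"))
```

The per-sample summaries show what the test sees — one representative
sample per group:

```
       window_id sample_id  n_cpx  n_reads  n_species top_epiallele  shannon  mean_meth
chrSim_120_133_*        A1      2       60          2            00   0.8366     0.2667
chrSim_320_333_*        A1      2       60          2            00   0.6500     0.1667
chrSim_120_133_*        B1      2       60          3            11   1.5410     0.6000
chrSim_320_333_*        B1      2       60          3            11   1.5155     0.6083
```

Each window has 2 CpG units and 60 spanning reads (30 per strand, pooled by
the merged-strand mode). Group B's three-species mixture is visibly more
heterogeneous: its Shannon entropy (≈1.5 bits) approaches the 2-bit maximum
for 2 sites, while group A (≈0.7–0.8 bits) is dominated by `00`. The
composition and entropy tests agree:

```
       window_id  pseudo_f     r2     p  p_adj        # PERMANOVA (epistat)
chrSim_120_133_*  126.5394 0.9547 0.029  0.036
chrSim_320_333_*  142.0656 0.9595 0.036  0.036

       window_id     test      p  median_A  median_B  p_adj   # diffstat
chrSim_120_133_* wilcoxon 0.0286    0.7219    1.5391 0.0286
chrSim_320_333_* wilcoxon 0.0286    0.6687    1.4147 0.0286
```

With 4+4 samples the exact two-sided rank-sum p for fully separated groups
is 2/70 ≈ 0.0286, and the permutation p of the composition test bottoms out
near 2/70 as well — both windows pass the combined filter (rank-test
p ≤ 0.05, |ΔH median| ≥ 0.10, PERMANOVA p ≤ 0.05):

```
significant: ['chrSim_120_133_*', 'chrSim_320_333_*']
```

The same pipeline is available as subcommands (`epialleles simulate |
regions | windows | extract | test-composition | test-stat | test-ancova |
annotate`); run `epialleles --help`.

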