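# Methods

## The measurement model

Whole-genome bisulfite sequencing converts unmethylated cytosines to uracil
(read as T) while methylated cytosines survive, so the methylated /
unmethylated read counts (mC, umC) at each strand-specific cytosine measure
its methylation level,

    ML = mC / (mC + umC).

Conversion is imperfect: a truly unmethylated cytosine still reads
methylated at the *non-conversion rate* r, estimated here as the pooled
methylated fraction of an unmethylated spike-in control (lambda DNA in the
laboratory protocol this package models). Under that error model a read
scores methylated with probability `ml + (1 − ml)·r`, so the unbiased linear
correction is

    ML_corrected = (ML − r) / (1 − r),   clipped to [0, 1].

The clipped linear form is an interpretation: the protocol this package
follows states the correction only in prose, and the form above is the
unique linear map whose expectation removes the additive non-conversion
noise.

### Site calling

Each cytosine with depth ≥ 5 is tested against the null that all its
methylated reads are conversion failures:
`p = P(X ≥ mC), X ~ Binomial(depth, r)`, computed exactly via the binomial
survival function. Benjamini–Hochberg q-values are computed **per context
class** (CG, CHG, CHH) because their base rates differ by orders of
magnitude and pooling would let the CG signal swamp the rare non-CpG calls;
a site is called methylated at q ≤ 0.05. Sites with depth ≥ 5 but q > 0.05
are retained as covered-but-unmethylated: *composition* statistics use the
calls, *level* statistics average `ml_corrected` over all covered sites.

### DMR scan

Windows of 1000 bp slide in 100-bp steps (a chromosome shorter than one
window yields a single window covering it). Within each window the pooled
(mC, umC) counts of the two groups form a 2×2 table tested with two-sided
Fisher's exact — with one pooled library per group there is no within-group
replication, so the pooled-count exact test is the natural choice and is
verifiable against hypergeometric enumeration. Only the CG context is
scanned by default (configurable); non-CpG sites would dilute the signal.

A window is significant when all four filters hold: p < 0.05; mean depth per
covered cytosine > 5 in **both** groups (the symmetric reading of "read
coverage greater than 5"); fold change of the window's mean corrected level
> 2 (pseudocount 1e-6, taken ≥ 1 so it is direction-free); BH FDR < 0.05
across all tested windows (p < 0.05 is implied by the FDR filter but kept
explicit). Significant windows on one chromosome merge when their spans
overlap or abut within one step — at a 100-bp step any contiguous signal
appears as an overlapping run. A DMR's level is the unweighted mean of its
windows' levels (windows overlap, so site-weighting would double-count),
its fold change the max, its p and FDR the min, and its direction hyper/hypo
for group 2 versus group 1.

### Integration

A gene whose promoter (2 kb upstream of the TSS, strand-aware, clipped at
the chromosome edge), 5'UTR, exon, intron or 3'UTR overlaps a DMR is a
differentially methylated gene (DMG). When one gene carries DMRs of both
directions the majority wins and an exact tie is reported verbatim as
"Hypo/hyper". DMGs are intersected with externally supplied differentially
expressed genes (DEGs); the candidate filter keeps promoter-overlapping
rows and optionally a (methylation, regulation) signature such as
Hyper + Down — promoter hypermethylation silencing a gene. Expression
classes split genes at the median FPKM among genes with FPKM > 0 (ties and
zeros go low; rank-based, hence scale-free). Pearson correlations between
per-sample expression and traits report n per cell so users can judge
power; 2^−ΔΔCt converts qPCR Ct tables to relative abundance.

## Coordinate and labelling conventions

All internal coordinates are 0-based half-open; the per-cytosine report
(Bismark CX dialect, assumed because no dialect is standard) is 1-based and
converted exactly once at I/O. Strands are kept separate — no CpG
destranding — since the calling model is per-cytosine. When a single label
per position is needed, overlaps resolve by precedence
promoter > 5'UTR > 3'UTR > exon > intron > CGI > repeat > intergenic; DMR
annotation is multi-label (a DMR spanning a promoter and an exon counts in
both), and CGI/repeat levels are additionally reported from their full site
sets because they are plotted as their own classes.

## The synthetic data generator

The generator emulates a pooled two-group design (three individuals pooled
per group, one library per group) with vertebrate methylation biology:

| parameter | default | meaning |
|---|---|---|
| `baseline_ml` | CG 0.65, CHG 0.006, CHH 0.006 | context base rates |
| `hypomethylated_ml` (± sd) | 0.15 ± 0.06, clipped [0.02, 0.30] | per-promoter/CGI CpG level |
| `depth_mean` | 30 | Poisson read depth per site (negative-binomial switch available) |
| `r_true` | 0.005 | non-conversion rate (a simulation choice; the protocol's observed rate is unreported) |
| `cpg_depletion` | 0.75 | probability a background CpG's G is mutated away |
| `cgi_gc` | 0.65 | GC inside CpG islands (≈70% of promoters carry one) |
| `dmr_delta_ml` | 0.3 | planted shift of group-2 CpG methylation |
| `expression_coupling` | 4.0 | log2-FPKM units lost per unit promoter methylation |
| `de_log2fc` | 2.0 | extra group-2 knockdown for promoter-hyper genes |

Counts follow the site model exactly:
`n_meth ~ Binomial(depth, ml + (1 − ml)·r_true)`. Planted DMRs default to
promoter spans. This is deliberate: promoters sit on the hypomethylated
baseline (0.15), so a +0.3 shift gives fold change ≈ 3 and is detectable
under the > 2 fold-change filter, whereas the same shift on the 0.65
genome-wide baseline (fold change 1.46) is not — hypermethylation events
that pass the published filter are, by arithmetic, events on hypomethylated
ground. Promoter levels vary between genes (sd 0.06) so the
methylation–expression coupling has variance to act on, and intergenic gaps
(2.5–4.5 kb) keep neighbouring promoters disjoint so each planted DMR
belongs to exactly one gene. Expression is
`log2 FPKM = 5 − 4·promoter_ml + N(0, 0.5)` per gene, with an extra ±2 log2
knockdown/boost for genes whose promoter hosts a planted hyper/hypo DMR and
for a few unrelated genes (so DMG×DEG intersections are non-trivial);
per-sample tables add N(0, 0.25) noise, and traits are drawn per sample
around group means chosen to mimic an ageing hen comparison (higher
intramuscular fat and shear force, lower drip loss in the older group).

**What the generator does not model:** read-level artifacts (FASTQ errors,
mapping bias, PCR duplicates), SNP-induced conversion artifacts, spatial
autocorrelation of methylation outside the planted regions, replicate-level
biological variance (the design is pooled), and realistic gene structure
(exon counts and lengths are drawn from simple distributions). Passing
tests therefore demonstrate correctness of the *inference machinery* under
the stated binomial model, not robustness to alignment artifacts or
between-replicate dispersion in real libraries.

## Numerical choices

- Exact binomial tails via the survival function (verified to 1e-12 against
  term-by-term summation up to depth 50).
- BH via `statsmodels` (verified against a sort/scale/cummin oracle).
- Fisher's exact via `scipy` (verified against hypergeometric enumeration).
- Fold change pseudocount 1e-6 avoids division by zero at fully
  unmethylated windows.
- Metagene bins 20/60/20 over a 2-kb flank (unstated upstream; chosen for
  smoothness at these problem sizes and exposed as parameters);
  minus-strand genes are mirrored; genes shorter than the body bin count
  are skipped.
- Element labelling paints one int8 per base, so lookups are O(1) and the
  precedence rule is enforced by paint order.
- Windows with zero covered cytosines in either group are skipped (their
  level, and hence fold change, is undefined).
- Equal group levels in a DMR would be "ambiguous"; unreachable in practice
  because the fold-change filter precedes direction assignment.

## Problem sizes

The test-suite simulations use 150 kb – 2 Mb single-chromosome genomes with
8–80 genes at depth 30 — the scale at which the binomial site model, the
window scan and the candidate filter can be exercised end-to-end in seconds
to a few minutes. The acceptance script runs the full pipeline on a 2 Mb /
80-gene / 10-planted-DMR configuration (~790k strand-specific cytosines per
group). Headline numbers from the real pooled-hen study (e.g. its total DMR
count) depend on its deposited sequencing data and on unpublished internals
of the swDMR tool it used, and are not reproduced at these scales.

## Known limitations

- The per-window Fisher test treats reads as independent; overdispersion
  between biological replicates is out of scope for a pooled design.
- FDR is controlled per scan, but overlapping windows are positively
  correlated; BH remains valid under positive dependence, yet the effective
  number of independent tests is smaller than the window count.
- DMG direction ties are reported, not resolved.
- Differential-expression calling itself is out of scope: DE labels are an
  input.
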