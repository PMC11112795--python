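# Methods

## Scope and model

`methscreen` analyzes a small paired tumor/normal design: per-cytosine
methylation call tables (one per sample) and a gene-level RNA count matrix,
3 samples per group by default. The package's claim is not a new DMR model
but a faithful, testable implementation of a threshold-style screen:
region-level fold + significance gates on pooled counts, threshold DEG
labelling, and direction-matched set intersection.

## Per-cytosine summarization

The per-site statistic is `Rm = Nm / (Nm + Nnm)`. Sites with zero coverage
are undefined and must be filtered before levels are taken; the parser
accepts a 6-column cytosine TSV and a 7-column Bismark-CX-like variant
(auto-detected by column count). Two report families are produced and
deliberately kept distinct, because both are conventionally called "mCG
percent":

* **context shares** — among methylated cytosines (default call: a site is
  methylated iff `Nm ≥ 1`), the percent falling in CG/CHG/CHH context;
* **mean levels** — the coverage-weighted mean `Rm` over covered cytosines
  of a context (human CG levels sit around 40–75%).

Group summary rows report the mean and the sample (n−1) standard
deviation. Report rounding is half-away-from-zero to 3 decimals, matching
how printed tables round; all internal arithmetic is unrounded (the
mean/SD path is exact rational up to the final float square root).

Read QC implements the two-rule filter for bisulfite libraries: a read
fails when strictly more than 10% of bases are unknown (N) or strictly
more than 10% are below Q20; the N rule takes precedence. Exactly 10% is a
pass — the rule is "more than".

CpG dyads: stranded input records are kept separate by default;
`methylome.destrand` merges minus-strand CG calls onto the plus-strand
coordinate when a destranded view is wanted. The simulator emits
destranded (plus-strand) records directly.

## DMR calling

A usable site is CG-context and covered ≥ `min_coverage` (default 4) in
every sample of both groups. Candidates are all windows of
`window_cpgs = 5` consecutive usable sites with consecutive gaps ≤
`max_gap = 300` bp, step 1 site. Nothing in a threshold criterion defines
segmentation, so deterministic sliding windows plus union/merge were chosen
over smoothing or HMM approaches: the result is exactly reproducible and
admits an exhaustive-enumeration oracle in the tests.

Per region, counts are pooled (summed over the region's sites and the
group's samples) and tested:

* level per group: pooled ratio — recomputing from raw counts reproduces
  it exactly, which the tests assert;
* significance: two-sided Fisher exact on the pooled 2×2 table. At three
  replicates per group a per-sample test has almost no power and no clean
  null; pooling is well-defined and exact. The cost, stated plainly: pooled
  Fisher is anti-conservative when replicates are overdispersed. The
  calibration tests therefore run at `rho = 0`, where the pooled null is
  exact, and measure a per-window rejection rate at-or-below the nominal
  5% (Fisher's discreteness makes it conservative);
* fold: `(max + ε)/(min + ε)` with `ε = 0.01`, preventing division by zero
  on fully unmethylated regions. Both gates are strict: fold > 2, P < 0.05.

Overlapping significant windows of the same direction are unioned; the
union's statistics are recomputed over **all** usable sites it contains and
re-checked (a union that fails is dropped). Adjacent same-direction regions
with no opposite-direction region between them are then merged whenever the
full span — again over all usable CpGs inside — still passes; this iterates
to a fixpoint, so merging is idempotent. Every emitted DMR re-verifies the
full criterion from raw counts.

Coordinates are 1-based in cytosine tables, 0-based half-open (BED) for
all region intervals. No multiple-testing correction is applied across
windows; the screen is a candidate generator, not an inference procedure.

## DEG screen

Counts are normalized to counts per million (CPM) per sample;
`log2FC = log2((mean CPM_t + 1)/(mean CPM_n + 1))` and the p-value is a
two-sided Welch t-test on `log2(CPM + 1)`. Labels use inclusive thresholds
(`≤ −1`, `≥ 1`) with `P < 0.05`. All-zero genes are neutral with `p = 1`
and flagged. A caveat that matters at this scale: CPM renormalization makes
log2FC composition-sensitive — scaling one group's counts uniformly cancels
out, and strong planted effects shift every other gene's log2FC slightly.
The tests check the composition-aware form of monotonicity (one scaled gene
moves by ≈ k relative to the uniform renormalization shift).

## Integration

DMRs annotate to genes by interval overlap against the promoter
(strand-aware TSS window, default 2000 bp up / 500 bp down) union the gene
body; a promoter-only mode supports the stricter silencing interpretation.
Duplicates are removed per direction; genes hit by both directions join
both sets and are flagged. Crossover sets are exact intersections with
Venn counts; gene ordering is lexicographic throughout, so outputs are
byte-stable.

The Spearman screen uses average ranks for ties and retains `|ρ| ≥ 0.3`
by default; the chi-square test is Pearson's without continuity correction
(the only variant that reproduces the reference clinical statistics
1.278 / 4.141 / 3.333 from their printed 2×2 tables), p from χ²(1 df).

## Demethylation response

Panel rows are CpG units with methylation fractions before and after
treatment (plus an optional normal-cell reference). The response is the
**relative** decrease `(before − after)/before × 100` — the only reading
consistent with a 0.51 → 0.27 change printing as 47.1% — sign-preserved
for units that gain methylation, undefined (and excluded, logged) at
`before = 0`. The argmax is deterministic with a lexicographic tie-break,
and a subset flag restricts the readout to named units, since a panel's
strongest responder overall need not be among the loci of interest.

## Synthetic-data generator

The generator emulates the study shape end-to-end:

* **annotation** — non-overlapping gene bodies (uniform lengths 3–8 kb,
  ≥ 2.5 kb apart) on one chromosome, both strands, strand-correct TSS;
* **methylome** — background CpGs scattered uniformly (default 10,000 on
  1 Mb, ≈ 1 per 100 bp), ~5% CHG/CHH sites at level 0.01 (human non-CG
  methylation is near zero), baseline CG level 0.64 (mid-range of human
  tissue CG levels). Coverage is Poisson(30) truncated at ≥ 1 so every
  emitted site is covered; methylated counts are beta-binomial with mean μ
  and intra-class correlation ρ (`a = μ(1−ρ)/ρ`, `b = (1−μ)(1−ρ)/ρ`),
  degenerating to an exact binomial at ρ = 0 so calibration tests have a
  closed-form oracle. Planted DMRs are dense (≤ 50 bp spacing) CpG runs
  inside the promoters of distinct randomly chosen genes; every CG site
  falling inside a planted interval takes the planted levels, because a
  DMR is a property of a region, not of individual seeded sites;
* **expression** — negative binomial per gene (var = μ + αμ², α = 0.1, a
  tissue-level dispersion; log-normal baseline means), with planted
  promoter-hyper-DMR genes becoming down-DEGs at `2^±log2FC` (default 4-fold)
  with probability `coupling_prob`, hypo → up symmetrically; extra
  uncoupled DEGs are available for screen-power tests;
* **demethylation panel** — per-unit levels exactly as configured (default:
  a 4-unit panel with responses from 0% to 87.7%);
* **FASTQ fixtures** — reads where Bernoulli-chosen subsets carry > 10% N
  bases or > 10% sub-Q20 bases, for the QC rule.

Determinism: every stage draws from its own seed-derived stream
(`default_rng([seed, stage])`); identical configs give byte-identical
outputs, which the tests assert.

What the generator does **not** emulate: read-level bisulfite sequences,
alignment and conversion error, CpG-island/shore spatial structure beyond
planted runs, correlated methylation between neighboring background sites,
gene-length or GC expression biases, and batch effects. Passing
parameter-recovery tests therefore demonstrates that the implementation
computes its stated criteria correctly at realistic signal/noise — not that
the criteria themselves are well-calibrated on real overdispersed tissue
data (see the pooled-Fisher caveat above).

## Problem sizes and numerical choices

The test suite and acceptance script run in seconds on one CPU at the
sizes that make their statistics stable: 2,000-site null genomes
(≈ 1,700 windows) for calibration; 50 planted DMRs on a 2 Mb chromosome
for sensitivity/specificity; 200 planted DEGs among 1,000 genes for label
recovery (at 60 planted genes the recovery estimate's Monte-Carlo error
straddles the 80% margin; at 200 it does not).

Degenerate inputs are errors, not silent zeros: zero-coverage levels,
single-value SDs, zero-margin chi-square tables, constant Spearman
anchors, and zero-baseline relative decreases all raise typed exceptions.
Features with no covered sites are reported missing rather than zero.
Ties: argmax by (response, unit id); gene lists lexicographic; merge scan
left-to-right to a fixpoint.

## Known limitations

* Pooled Fisher inflates significance under replicate overdispersion; at
  ρ > 0 the emitted P-values should be read as ranking scores.
* The Welch t-test at n = 3 per group is underpowered; planted 4-fold
  changes are recovered at roughly 83–89%, not near-completely, and real
  studies at this scale should prefer shrinkage-based DE methods.
* No multiple-testing control in either screen, by design.
* Genome-wide DMR/DEG counts from real tumor cohorts are not reproducible
  from synthetic data; the package's quantitative guarantees are the
  property and recovery checks above plus exact reproduction of the
  closed-form report statistics.
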