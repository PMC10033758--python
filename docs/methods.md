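# Methods and design notes

This note documents the models, parameter choices and numerical decisions
behind `hyposcape`. Nothing here states an empirical result the test suite
or `scripts/acceptance.py` does not itself compute.

## Study design emulated by the generator

The synthetic generator (`synthetic.py`) reproduces the statistical
structure of a chronic-hypoxia cell-line study:

* **Signature fold changes.** Twelve cell lines, eight signature genes,
  six replicate fold-change values per (line, gene) — three experiments in
  duplicate. Fold changes are log-normal: per-gene baseline log2 induction
  ~ N(0.5, 0.3) shared across lines (it cancels in between-line
  comparisons), replicate noise sd 0.5 in log2. Half the lines are planted
  "sensitive" with the per-gene log2 location raised by
  `log2(group_effect)`; `group_effect` defaults to 4, a separation at which
  score-based ranking cleanly splits the two labels.
* **Expression arrays.** 2000 transcripts × (4 normoxia + 4 hypoxia)
  samples per cell line; log2 baselines uniform on [4, 12], per-sample
  noise sd 0.25 (a typical array-replicate scale). 5% of transcripts carry
  a planted ±4-fold shift in hypoxia (the smallest effect comfortably
  above the study's |FC| ≥ 2 significance cut).
* **Splicing signals.** Each transcript has a gene-level signal and two
  probe-region (exon/junction) signals at a transcript-specific fraction of
  the gene signal with independent log2 noise sd 0.2. Planted cassette-exon
  transcripts (5%) shift probe 1 four-fold relative to the gene in hypoxia,
  gene signal unchanged; their candidate-event lists score "cassette exon"
  highest (0.75–0.95) over 1–2 decoy events (< 0.6). Unaffected transcripts
  carry no candidate events and are therefore excluded from splicing
  reports.
* **Paired variant calls.** Per cell line, 2 biological × 2 technical
  replicates, each a (normoxia, hypoxia) MAF pair sharing exactly 50
  background records; the hypoxia sample additionally carries
  K ~ Poisson(rate × 57.7 Mb) private records. Rates default to 3.0 (HH)
  and 1.6 (HL) mut/Mb — the magnitude and design of the group comparison
  the pipeline is meant to resolve. Variant classes follow a mixture
  dominated by frameshift insertions (0.35) over missense (0.30); SNVs are
  transitions with probability 0.7, split 60/40 between C>T and T>C folded
  classes, with a uniformly random reference strand. Positions are uniform
  on a single synthetic contig `chrS` (duplicates redrawn, so MAF identity
  keys are unique within a sample); insertions use reference allele `-`,
  deletions alternate allele `-`. Gene labels come from a 300-gene pool
  with weights ∝ 1/(rank+5), so a stable head of genes recurs across
  samples as in real top-mutated-gene tables.
* **Coverage tracks.** 2000 windows of 50 kb on `chrS`; control depth
  ~ Poisson(100), case depth ~ Poisson(100 · CN/ploidy). The default truth
  is a triploid baseline with segments of CN 2 (windows 200–400), CN 4
  (900–1100) and CN 2 (1500–1600). Depth noise is plain Poisson;
  overdispersion is deliberately not modeled (see limitations).
* **Cohort.** 50 patients with a latent hypoxia factor z ~ N(0, 1);
  signature-gene log2 expression = baseline + z + N(0, 0.5). Binary
  alteration events over 30 genes (the head of the mutation gene pool)
  have baseline probability 0.15, with odds multiplied by
  `alteration_enrichment` (default 5) for patients in the top half of z.

Every generator is a pure function of the configuration including the
seed; independent replicates (one expression matrix per cell line, one
coverage pair per sample pair) are drawn from per-scenario,
per-instance RNG streams.

What the generator does **not** emulate: cell-line-specific biology
(transcripts are exchangeable within a matrix), LD-like correlation among
variants, GC/mappability bias (mappability defaults to 1 and the matched
control cancels shared biases anyway), overdispersed depth, batch effects,
and array probe-level artifacts. Passing tests therefore demonstrate that
the statistical machinery recovers effects of the planted kind and size
under clean noise — not performance on raw instrument data.

## Hypoxia scores

The cell-line score is the geometric mean of per-gene replicate-averaged
fold changes; it is homogeneous of degree 1 (scaling all FCs by c scales
every score by c). The relative score is `score − geomean(all scores)`;
the sign convention puts responsive lines positive, so relative score > 0
defines HH. (The alternative subtraction direction would invert the rule
that positive values mark hypoxia-high lines, so it is not used.) The
cohort score dichotomizes each gene at its cohort median — midpoint median
for even cohorts — assigning −1 to values exactly at the median, which
keeps the boundary patient in the HL-inclusive group (score ≤ 0 → HL);
the construction is invariant under any strictly increasing per-gene
transformation.

## Differential expression and splicing

Testing is on log2 intensities. The per-transcript pooled variance s²
(df d = n₁+n₂−2) is shrunk toward the across-transcript mean variance s₀²:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),   t = Δmean / (s̃·√(1/n₁+1/n₂))

with reference df d + d₀ and prior df d₀ = 4 by default — a standard
moderated-t construction for small array designs that reduces exactly to
the classical two-sample t at d₀ = 0. Fold changes are reported as signed
linear ratios of the group means on the linear scale (r if r ≥ 1, else
−1/r). Significance rules preserve the boundary conventions of the two
analyses as printed in the array software: DE uses |FC| ≥ 2 with
BH FDR ≤ 0.05, splicing uses |SI| > 2 with exon FDR < 0.05.

The splicing index divides each probe-region signal by its gene signal per
sample (making it invariant to any per-sample common scaling), applies the
same moderated test on log2-normalized signals with BH adjustment across
probes, and represents each transcript by its probe of maximal |SI|. The
splicing mode is the candidate event with the highest event score in
[0, 1]; ties break by a fixed label order (cassette exon, intron
retention, alt 5′ donor, alt 3′ acceptor, mutually exclusive exons, alt
first exon, alt last exon, complex); transcripts with no scored candidate
are excluded from reports.

"Group-specific" DEG sets subtract only the all-lines intersection from a
group's own intersection; genes significant in some (but not all) lines of
the other group are not additionally excluded. This is the weakest
defensible reading and keeps the three reported sets pairwise disjoint.

## Paired mutational landscape

Variant identity for subtraction is (chromosome, start, end, ref, alt,
variant type) — annotations (gene symbol, classification) are excluded so
annotation drift between the two calls cannot break the subtraction.
Duplicate keys within a sample are collapsed with a warning; multi-allelic
sites arrive as separate rows and are treated independently; chromosome
labels are compared verbatim. TMB divides the retained variant count by a
configurable exome footprint, default 57.7 Mb (the published design size
of the exome panel emulated); all retained variants count, silent
included. SNV classes use the pyrimidine-reference six-class convention
(purine-reference pairs complemented); transitions are C>T and T>C.
Top-gene ranking is by number of pairs carrying ≥ 1 retained variant in
the gene, ties by total variant count then gene label.

## Windowed CNV

Ratios: windows with mappability < 0.85 (either track) or control depth
< 10 reads are dropped from all counts (the retained count is reported);
each track is normalized by its median over retained windows before the
case/control division, so the ratio is invariant to uniform depth scaling
of either track. Ratios are floored at 10⁻³ before taking logs.

Segmentation is deterministic recursive change-point splitting on log2
ratios, per contig. At each step the candidate is either a single
breakpoint or an interior segment tested against the pooled remainder —
the circular-binary-segmentation-style statistic. The interior candidate
is essential: with single cuts only, the side means of an event far from
segment edges are diluted by flanking neutral windows and planted
100–200-window segments inside a 2000-window contig are missed. Among
candidates the one minimizing within-segment squared error wins, and it is
accepted iff |Δmean| exceeds `breakpoint_threshold` (default 0.8) times
the pooled within-segment SD. Minimum segment length is 3 windows;
interior candidates must span ≥ 20 windows (1 Mb at the default window
size) — below that, a fixed threshold cannot distinguish a real interior
event from the most extreme noise run among thousands of candidates, so
shorter interior events are outside the method's resolution. Segments
report the geometric mean of their window ratios.

Ploidy is selected among {2, 3, 4} as the value maximizing the fraction of
windows whose segmented ratio × ploidy is within ε = 0.1 of an integer
(ties to the smallest candidate). Selection deliberately uses
segment-mean ratios rather than raw window ratios: raw Poisson noise at
depth 100 spreads window ratios so widely that every candidate explains a
similar ~2ε share, whereas segment means are tight enough for planted copy
numbers to resolve to integers only under the true baseline. Copy numbers
are `round(mean_ratio × ploidy)` (half away from zero); gain/loss/neutral
status is relative to the selected ploidy, and CNV/CNG/CNL are window
counts with cnv = cng + cnl and cng + cnl + neutral = retained, always.

## Group statistics

The default two-group test is the Student pooled-variance unpaired
two-sided t-test (Welch available); each sample pair is the unit of
analysis for group aggregates. Degenerate zero-variance inputs follow the
p = 1 convention when means are equal. ANOVA-based multiple comparisons
use the one-way residual mean square and df for pairwise t statistics and
Sidak adjustment p′ = 1 − (1 − p)^m clamped to [0, 1]. Alteration
concordance counts genes whose alteration frequency is strictly higher in
HH than in HL.

## Problem sizes and calibration checks

The shipped test suite exercises: oracle equivalence (paired subtraction
vs set difference on 100 random pairs; BH vs the textbook step-up on 1000
random vectors at 10⁻¹²; top-gene ranking vs a brute-force tally),
closed-form score identities, planted-effect recovery at generator
defaults (DE sensitivity and false-discovery proportion over 20 seeds;
cassette-exon sensitivity over 20 seeds; CNV window-status accuracy and
ploidy recovery over 20 seeds; group-TMB direction and test power over
100 seeds), null calibration (global-null pipeline over 20 seeds; t-test
type-I error over 5000 replicates; CI coverage over 1000 draws), and
byte-identical end-to-end determinism. These sizes were chosen to make the
Monte-Carlo estimates stable at the asserted tolerances while keeping the
suite fast on a single CPU.

## Known limitations

* The moderated test is a generic moderated-t; equivalence with any
  specific array software's proprietary eBayes variant is not claimed.
* The CNV module is a simplified windowed-ratio re-implementation, not a
  clone of any particular tool: no GC correction (the matched control
  cancels shared bias), no contamination model, no allele-frequency
  refinement, no inter-contig segments, and the breakpoint threshold's
  scale (multiples of pooled log2-ratio SD) is this package's definition.
* Interior copy-number events shorter than ~20 windows are below the
  segmentation's resolution unless they touch a segment boundary.
* The splicing stage thresholds and selects externally supplied event
  scores; it does not detect event types from probe geometry itself.
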