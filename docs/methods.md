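# Methods

This note documents the statistical procedures, the defaults and why they
hold, the synthetic-data model behind the test suite, and the package's own
design choices where the design was genuinely open.

## Coordinates and distance

All coordinates are 1-based inclusive (GTF convention); any BED export would
convert to 0-based half-open at the boundary. A gene locus is the union span
(min start, max end) of its transcripts. Transcript *length* always means
spliced length — the sum of exon widths, i.e. the mature transcript — since
lncRNA length definitions in transcript catalogs refer to the mature
molecule, not the genomic footprint.

Genomic distance between two loci is the nearest-edge separation:
0 if the intervals overlap, otherwise `start(downstream) − end(upstream)`,
with no ±1 adjustment; it is symmetric and strand-agnostic. For display the
distance is converted to kb and **truncated toward zero** — two decimals
below 1 kb, one decimal otherwise. Truncation, not rounding, is the only
display rule consistent with the reference pair set this package reproduces
(e.g. 86,376 bp prints "86.3" and 181 bp prints "0.18").

## Transcript classification and the lncRNA filter

Assembler class codes are replaced by a documented same-strand
exonic-overlap rule, testable against a brute-force per-base oracle:

- `known_coding`: shares ≥ 1 same-strand exonic base with a reference coding
  transcript (strand "." is compatible with either strand);
- `known_noncoding`: same rule against the reference noncoding set;
- `undefined`: overlaps reference exons only antisense, or only reference
  introns (transcript spans), — the "undefinable" bucket;
- `novel`: no overlap with any reference exon or transcript span.

Novel transcripts pass the lncRNA filter iff spliced length ≥ 200 nt **and**
exon count ≥ 2 (both inclusive) **and** coding-potential score strictly < 0.
Scores come from an external CNCI-like classifier and are an input; the
classifier itself is out of scope. A transcript without a score fails with
its own verdict (`fail_no_score`). Fail reasons are reported in the fixed
order length → exons → score so verdicts are deterministic. The filter is
applied to novel candidates only; known noncoding transcripts enter the
catalog as-is.

## Differential expression

FPKM is modeled as log-normal; each gene is tested with a two-sided
two-sample t-test on `log2(FPKM + 1)`. The pseudocount (1.0 FPKM,
configurable) guards against log(0) and stabilizes the fold change
`(mean_case + 1) / (mean_control + 1)`.

The test pools variances by default. With triplicate groups the
Welch–Satterthwaite approximation is markedly conservative — its empirical
size is ≈ 0.035 at nominal 0.05 — while the pooled test is exact under the
common-variance log-normal model used throughout (measured size 0.051 on
null simulations). Welch's form remains available via `equal_var=False` for
data with genuine variance heterogeneity. Degenerate genes with zero
variance in both groups get p = 1 when means agree and p = 0 when they do
not (perfect separation).

No multiple-testing correction is applied: the DEG list at raw p < 0.05 is
consumed downstream only as a candidate set for pairing, and the stated
thresholds are raw. Call thresholds are strict (fold > 2.0 or < 0.5); the
stratified count table uses inclusive thresholds (≥ 2 / ≥ 4 / ≥ 8 and the
reciprocals), so a gene at exactly fold 2 is tabulated but not called. Both
conventions are deliberate and documented where they apply.

## Coexpression and *cis* pairing

Correlations are computed across **all samples pooled** (both groups), the
convention matching how such pair screens report coexpression. The default
coefficient is Spearman's ρ with average ranks. For n ≤ 8 samples the
two-sided p-value is exact by full enumeration of all n! rank permutations
(at n = 6 the t-approximation materially misstates p, and 720 permutations
are cheap); beyond n = 8 the t-approximation is used. Under ties the
enumeration permutes the actual tied rank vector, so exactness is retained.
Pearson's r (p from the t-distribution) is available as an alternative
because screens of this kind are described sometimes with Pearson > 0.9 and
sometimes with Spearman 0.8/0.9 thresholds; this package defaults to the
Spearman description and surfaces the choice as a parameter.

A pair is kept iff ρ ≥ 0.8, p < 0.05, both loci share a chromosome, and
their nearest-edge distance is ≤ 100 kb; ρ ≥ 0.9 marks the pair "strong".
Strand is ignored (the screen is sense-agnostic), pairs are not
deduplicated (one lncRNA may pair with several coding genes and vice
versa), and genes with constant expression are skipped with a warning
rather than failing the run. Output ordering is (chrom, lncRNA start,
coding start) for byte-stable reruns.

## Synthetic-data model

For gene g and sample s:

    log2 FPKM(g, s) = mu_g + shift_g·[s in case] + w_g·z_{c(g),s} + eps

with `mu_g ~ U(2, 6)` (FPKM ≈ 4–64), planted DEG shifts on the log2 scale,
`z` a standard-normal latent factor shared by the members of a planted pair,
and `eps ~ N(0, noise_sd²)` iid. Expression is log-normal rather than
negative-binomial because the pipeline consumes FPKM, not counts, and the
inference it feeds (ranks, fold changes, t on logs) is distribution-light; a
count layer is a non-goal.

One latent factor is drawn per **connected component** of the planted-pair
graph, not per pair: when two pairs share a member (one lncRNA flanked by
two coding partners, or two lncRNAs sharing one coding gene — both occur in
the reference pair set), a per-pair factor would load the shared gene twice
and cap its correlation with each partner at 1/√2 < 0.8 even at zero noise,
defeating noise-free recovery by construction. For disjoint pairs the
component rule reduces exactly to one factor per pair, so planted pairs stay
mutually independent and recovery statistics decompose.

Geometry: genes are laid left-to-right per chromosome with uniform
intergenic gaps (5–50 kb default) and lengths (2–30 kb). Planted pairs are
placed first, on round-robin chromosomes, with the requested nearest-edge
gap reproduced **exactly**; the first transcript of every gene spans its
full locus so the gene span equals the placement. Pair components must be
stars (one shared gene); longer sharing chains raise a configuration error —
a known limitation, sufficient for the reference multiplicity. Which genes
are lncRNAs, and which lncRNAs are pre-annotated vs novel candidates, is a
deterministic function of the gene index so that preset builders can refer
to gene ids before any random draw; all randomness flows from the single
config seed through named generators, and identical configs are
bit-reproducible.

Presets:

- `null` — 200 genes, no planted signal, noise 0.5 (calibration checks);
- `paper_like` — the study shape at reduced scale: 8 chromosomes × 250 genes
  (~2,000 genes standing in for a genome-wide assembly), 3 vs 3 samples,
  30 planted lncRNA DEGs and 250 planted coding DEGs (magnitudes cycling
  1.5/2/3 log2, one third down-regulated), and 6 planted *cis* pairs over
  5 lncRNAs and 5 coding genes with gaps 181 bp – 86.4 kb echoing the
  reference geometry, latent weight 0.9, noise 0.25, fixed seed 2018. The
  pair genes carry a log2 shift of 5 (strong induction, as for the validated
  liver pairs): the shared latent factor contributes within-group variance,
  and a smaller shift would leave the DE gate of pair members at the mercy
  of single latent draws even at zero measurement noise;
- `stress` — pairs planted at 99,999 and 100,001 bp to exercise the 100 kb
  boundary.

What passing tests on this generator do **not** show: robustness to count
noise at low expression, library-size artifacts, batch effects, unequal
group variances, or real genome gene-density patterns. The generator is a
model of the inference's assumptions, not of a sequencer.

## Scale of the simulation-based checks

Calibration and recovery checks in the test suite use: 2,000 genes for
type-I calibration; 2,000 null draws for the exact-p super-uniformity check;
200 seeded replicates for the fold-change recovery example; and 50 seeded
replicates of the `paper_like` scenario (300 planted-pair observations)
against a 20,000-draw Monte-Carlo oracle of the same generative model for
noisy recall. These sizes give standard errors comfortably below the margins
asserted.

## Other choices and degenerate inputs

- Overlapping exons within one transcript are merged with a warning
  (assemblers occasionally emit them); the strict constructor rejects them.
- A gene whose transcripts disagree on chromosome is an error; disagreement
  on strand collapses to "." with a warning (pairing ignores strand anyway).
- Genes matching both coding and noncoding references resolve to coding with
  a warning; genes with neither class (undefined, or novel failing the
  filter) are excluded from stratified counts and pairing.
- FPKM summarization is per gene, not per transcript, throughout.
- The NAFLD activity score takes pathologist-assigned integers as given
  (steatosis 0–3, lobular inflammation 0–3, ballooning 0–2; total ≥ 5 ⇒
  steatohepatitis); fibrosis staging is not part of the score as used here.
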