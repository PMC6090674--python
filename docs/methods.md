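# Methods

## The ceRNA calling model

A candidate ceRNA pair is any unordered pair of expressed transcripts
(mRNA, lncRNA or circRNA) whose predicted miRNA target sets intersect.
Candidates are enumerated through an inverted miRNA → targets index; this
is provably identical to all-pairs enumeration with a `k ≥ 1` filter,
because any pair with `k ≥ 1` co-occurs in at least one miRNA's target
list.

Acceptance requires both published criteria, applied with strict
inequalities and no multiple-testing correction (fixed raw thresholds; a
Benjamini–Hochberg variant sits behind `bh_correct`):

* **Shared-regulator test.** With `N` the number of expressed miRNAs
  present in the restricted target table, and `K_a`, `K_b` the two target
  set sizes, the p-value is the upper tail `P(X ≥ k)` of
  `Hypergeom(N, K_a, K_b)` — the probability of sharing at least the
  observed number of miRNAs if the two sets were drawn independently from
  the universe. The tail is symmetric in `(K_a, K_b)`, equals 1 at `k = 0`
  and is non-increasing in `k`; the test suite checks it against an
  exhaustive enumeration oracle over every configuration with `N ≤ 12` at
  1e-12.
* **Co-expression.** Sample Pearson correlation of the two log2(x+1)
  temporal profiles; two-sided p from `t = r·sqrt((n−2)/(1−r²))` on `n−2`
  df. The `r > 0.5` requirement already enforces positive co-expression,
  so a two-sided p is used.

The default universe `N` is the set of expressed miRNAs backing at least
one edge of the restricted target table; pass `universe_size` to use all
expressed miRNAs instead. Stage-specific networks re-run only the
correlation on that stage's samples — target sets, and hence the
hypergeometric part, are stage-independent. Pairs between a circRNA and
its own parent gene remain eligible but are flagged (`parent_pair`).

## Quantification and filtering

* mRNA/lncRNA: FPKM = count / (length/1e3) / (mapped/1e6); circRNA:
  junction reads and RPM; miRNA: RPM against the small-RNA library. All
  downstream statistics use log2(x+1).
* Reproducibility filter: per transcript, Pearson between the two
  replicate series; retained iff `r > 0.5` and `p < 0.05` (strict).
  Skipped when only one replicate series exists. With more than two
  replicate series, the first two are compared.
* Abundance filter (inclusive thresholds, ≥ 1 sample): circRNA counts ≥ 2,
  mRNA/lncRNA FPKM ≥ 1, miRNA RPM ≥ 1.
* Junction merge: calls with identical (chrom, start, end, strand) are
  unified across callers, per-sample support is the max across callers,
  and a junction is kept iff it reaches `min_reads = 2` in at least one
  sample (a summed-across-samples mode exists behind `support_mode`,
  since the threshold's per-sample vs summed reading is ambiguous).
* Novel-lncRNA filter: class code `i`/`x`/`u`, length ≥ 200 nt, longest
  ATG-initiated forward-frame ORF ≤ 120 aa (both bounds inclusive); a
  precomputed coding-potential flag, when present, rejects first.
* Stage differential expression: per-transcript two-sample t-test between
  the growth (Day ≤ 18) and senescence (Day ≥ 20) samples. The default is
  the pooled-variance Student's t, which is exactly calibrated under an
  equal-variance Gaussian null; Welch's test (`equal_var=False`) is
  available but measurably conservative at 8-vs-6 samples (empirical
  type-I ≈ 0.047 at α = 0.05), which is why it is not the default.
  Degenerate rows where both groups are constant get p = 1 (equal means)
  or p = 0 (unequal), logged.

## circRNA genomic classification

Coordinates are 0-based half-open internally; GFF3 is converted on ingest.
With the genes overlapping the back-splice span (both strands when the
junction strand is '.', same strand otherwise):

* no gene → **intergenic**;
* ≥ 2 protein-coding genes → **other**;
* exactly one protein-coding gene: both span endpoints inside exons →
  **exonic**; whole span inside one intron → **intronic**; any remaining
  single-gene geometry, or only non-coding overlap → **other** (the
  partition must be total; the published classes only define the first
  cases).

Endpoint containment is exact (0 nt slack) and junctions match across
callers only on exact coordinates; no tolerance is defined upstream, so
none is invented here.

## Clustering

* Transcript clustering: Euclidean k-means, k = 6, best of 50 restarts,
  on per-transcript standardized profiles. The scale is floored at
  0.5 × the median row standard deviation: a pure z-score inflates a
  near-constant profile into a unit-norm noise vector that scatters over
  clusters, whereas the floor keeps low-variability transcripts in a
  coherent group near the origin. Constant rows are excluded with a
  warning. k is fixed at 6 to match the six observed temporal classes; no
  model-selection criterion is implemented.
* Sample clustering: agglomerative, average linkage, distance
  1 − Pearson between sample columns; the two-group cut is the stage
  hypothesis. The method is recorded in the output metadata since the
  upstream analysis did not specify one.
* Fixed-day stage partition: growth = Day ≤ 18, senescence = Day ≥ 20.

## Hubs and enrichment

Hubs are the top `ceil(0.10 · n)` RNA nodes by degree over competing edges
only (miRNA nodes and regulatory edges excluded — hub *ceRNAs*); nodes
tied with the last selected degree are all included, and the tie policy is
recorded. An `all-edges` degree mode exists. Randomization enrichment
draws `n_perm` uniform same-size node sets from the background and uses
the add-one estimator `p = (1 + #{overlap ≥ observed}) / (1 + n_perm)`, so
p is never 0 and converges to the exact hypergeometric tail. The
hypergeometric route applies BH FDR across all tested set combinations.
The default background is the expressed transcripts of the matching class.

## The synthetic-data generator

The generator emulates the study design, not its sequencing: 14 time
points (Day 4–30), four RNA classes (defaults 200/20/30/50), two replicate
series, and negative-binomial counts (dispersion 0.1) around means set by
latent log2 profiles — FPKM-scaled via transcript length and a jittered
5e6-read library for mRNA/lncRNA, RPM-scaled via a 2e6-read small-RNA
library for miRNA, and direct junction-read means for circRNA.

Planted structure and the reasoning behind it:

* **Pairs.** 30 pairs (18 mRNA–mRNA, 6 mRNA–lncRNA, 6 mRNA–circRNA) share
  exactly 5 of 50 miRNAs plus 2 independent background targets each
  (tail p ≈ 2e-4 at `N = 50`), and share a temporal archetype with
  amplitude 1.2 log2 units against member-level noise sd 0.3.
* **Archetypes.** Six shapes: early-high-decaying, rise-then-fall, flat,
  late-rising, mid-peak, monotone-increasing. Pairs cycle over the five
  dynamic shapes — a flat profile carries no co-expression signal, so a
  flat "pair" would be undetectable by construction; the flat class is
  instead represented by dedicated carrier transcripts (6 per archetype)
  so all six shapes appear in the clustering ground truth. The
  late-rising shape is a sharp sigmoid at ~Day 25; a gentler slope
  correlates ≈ 0.9 with the linear ramp and the two classes stop being
  distinguishable at any noise level.
* **Background.** Half of the background transcripts are "dynamic"
  (i.i.d. temporal variation, sd 1.0, plus a transcript-specific
  growth/senescence step offset with sd 0.7 — the stage-differential
  majority seen in real leaves, and the signal the sample 2-cut
  discovers); the other half are "unstable" (sub-noise variation,
  sd 0.15) and are intentionally eliminated by the reproducibility
  filter. Predicted miRNA target sites cover only 10% of background
  transcripts (2 sites each), mirroring the sparsity of plant target
  prediction, where predicted targets are a small fraction of the
  transcriptome.
* **Truth identifiability.** Shared 5-sets of distinct pairs overlap by
  at most 1 miRNA and member background draws avoid pushing any
  cross-pair shared count to 3 (which would itself be significant at
  `N = 50`). Without this, a handful of cross-pairs per bundle would
  genuinely satisfy both published criteria while being labelled false
  positives — the ground truth would be ill-defined, not merely noisy.
* **Genome.** Two chromosomes sized to fit ~24 two-to-five-exon genes
  plus intergenic gaps (~50–80 kb each). circRNA junctions are placed to
  realize all four genomic classes (defaults 21/3/4/2
  exonic/intronic/intergenic/other), one extra exonic junction carries a
  single supporting read to exercise the ≥ 2 filter, and 15% of exonic
  circRNAs copy their parent gene's profile (the designed co-expressed
  fraction; the measured fraction is computed over the post-filter
  denominator and is therefore higher than 0.15).
* **Predictors/callers.** Every target edge lands in predictor file A
  (p = 0.75), B (p ≥ 0.6), or both, so the union equals the designed
  sets; caller B reports ~75% of junctions with binomially thinned
  support, so the per-sample max across callers equals the true counts.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: read-level artifacts (mapping bias, GC
effects, positional coverage), miRNA-mediated repression dynamics (planted
co-expression is imposed, not mechanistically generated), hierarchical
noise between biological replicates beyond independent draws, unbalanced
library compositions, and genuine target-prediction errors (the planted
target sets are exact, so recovered precision reflects the statistics, not
predictor quality).

Determinism: one `numpy` Generator seeded from `SimConfig.seed` drives
every draw sequentially, so equal seeds give byte-identical bundles
(checksums in the manifest).

## Problem sizes used by tests and the acceptance script

Recovery, clustering and stage-cut experiments use 10 seeds at the default
conditions above; the enumeration oracle covers all `N ≤ 12`
configurations; calibration uses 1e4 null transcripts / correlation reps;
the randomization-vs-exact check uses 1e5 permutations. These sizes give
Monte-Carlo errors comfortably below the tolerances they are compared
against while keeping a full run in the order of a minute.

## Known limitations

* The hypergeometric universe choice (`N` = miRNAs in the restricted
  table) is a convention; the upstream analysis never defines it, and
  p-values shift with `N`.
* With only one replicate series the reproducibility filter silently
  passes everything, matching the stated design but weakening the funnel.
* Tie expansion can make the hub set much larger than 10% when the degree
  distribution is flat (many degree-1 nodes), as happens on small planted
  networks.
* The correlation criterion ignores time ordering; a time-warped or
  lagged relationship counts only through its instantaneous Pearson r.
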