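# Methods

## Model and procedure

The pipeline treats bulk RNA-seq abundance (FPKM) for a mixed catalog of
protein-coding genes and lncRNAs across many samples as the primary signal.
Its stages, in order:

1. **Normalization.** Upper-quartile scaling: per sample *i*, kᵢ is the
   75th percentile of the nonzero values and ρᵢ = (Σⱼkⱼ/n)/kᵢ; all of
   sample *i*'s values are multiplied by ρᵢ. After scaling, every sample's
   nonzero upper quartile equals the cross-sample mean of the original kᵢ,
   which makes the operation idempotent. Zeros are preserved. The quartile
   estimator is the linear-interpolation ("type 7") rule; any single
   consistent estimator yields the same cross-sample-equality property.
2. **Variance filter.** Genes are ranked by unbiased sample variance of the
   normalized values and the top `ceil(0.75·G)` kept ("top 75 percentile"
   read as retaining the most-variable 75% of genes). Normalization happens
   before the variance computation; a flag allows the reverse order.
3. **Edge test.** Spearman's Rs computed as the Pearson correlation of
   mid-ranks (handling ties), Fisher-transformed, and scaled to
   Z = √((n−3)/1.06)·F(Rs), treated as standard normal. The 1.06 constant
   is the classical variance correction for Spearman coefficients under the
   null. |Rs| = 1 is clamped to ±(1−10⁻¹⁵) before the transform. n is the
   number of samples after optional replicate merging (arithmetic mean of
   FPKM).
4. **Network assembly.** All unordered pairs are tested. The Bonferroni
   family is per-gene (a gene's p-values are multiplied by the number of
   tests it participates in, capped at 1), and an edge must satisfy the
   adjusted α at *both* endpoints — the conservative symmetric reading of a
   per-gene adjustment. Edges further require Rs ≥ 0.5 (one-sided:
   anticorrelation never forms an edge; an `absolute` flag exists but is
   off by default). Constant-expression genes are excluded with a warning.
5. **Statistics.** Cᵢ = triangles at node i / (deg·(deg−1)/2), with Cᵢ = 0
   for degree < 2; C is the mean over all nodes (zeros included), and
   T = 3·triangles / connected triples. Both are authored directly from
   those definitions and cross-checked in tests against brute-force
   enumeration and networkx.
6. **Annotation.** Hypergeometric upper tail evaluated by summing the tail
   directly in log space (gammaln + logsumexp), which avoids the
   catastrophic cancellation of the one-minus-lower-tail form. N is all
   genes in the network, not only annotated ones (a flag switches to the
   annotated-only universe); no multiple-testing correction is applied to
   enrichment p-values (p < 0.05 raw), with BH available but off by
   default. For lncRNA annotation only coding neighbors are counted; the
   generic per-gene operation counts all neighbors.
7. **Prediction evaluation.** Test genes are coding genes with ≥ 10
   annotated coding neighbors. Each test gene's own annotations are hidden,
   terms are predicted from its neighborhood, and sensitivity is
   |predicted ∩ true| / |true| averaged over test genes. The baseline
   replaces each neighborhood with a uniformly random same-size set of
   annotated coding genes (default 100 draws; 20 in the bundled analysis
   scripts, where the gap between network and baseline is an order of
   magnitude and does not need tighter Monte-Carlo error). This
   per-gene recovered-fraction definition of sensitivity is this package's
   explicit choice; ancestor terms count as matches only if the annotation
   map was explicitly closed with `propagate_ancestors`.
8. **Conservation.** RBH with E ≤ 10⁻⁵; the best hit per query is the
   lowest E-value, ties broken by higher bit score then lexicographic
   subject id. Orthology can be resolved at transcript level and collapsed
   to genes (a gene counts once if any transcript has a partner).
   TSI = max/sum over per-tissue means. TF-family IoU excludes pairs where
   both sets are empty (0/0 undefined) rather than scoring 0. Conservation
   scores are length-weighted means over exonic bases via interval
   intersection (never per-base expansion), with uncovered bases scored 0.
   KS comparisons use the asymptotic limiting-series p only; the sample
   sizes in use make exact small-sample corrections unnecessary.
9. **Subtypes.** Precedence: same-strand exon-exon overlap →
   sense-overlapping; else any opposite-strand span overlap → antisense;
   else same-strand containment in a coding span → intronic; else
   intergenic. The exact overlap rules are not standardized anywhere; this
   precedence is a declared convention, validated against the generator's
   planted labels. Gene-level labels take the first transcript by
   coordinate order when transcripts disagree (logged).

## Synthetic data: what it emulates and what it does not

Each of the 5 modules draws one latent per-sample profile; member genes
(12 coding + 6 lncRNA by default) observe
`softplus(module_effect·profile + N(0, noise_sd))`, giving nonnegative
FPKM-like values whose rank structure is shared within a module and
independent across modules. Defaults — 60 coding + 30 lncRNA genes, 20
samples over 5 tissues, module_effect 3.0, noise_sd 0.5, 3 planted terms
per module, 40% of lncRNAs conserved — are chosen so that the within-module
Spearman correlation (~0.95 at the default noise) sits comfortably above
the 0.5 cutoff while cross-module pairs are independent, i.e. a clearly
detectable but not degenerate regime. Module 0 is damped by ×0.05 outside
its home tissue so TSI has spread. Coding genes receive their module's
terms plus background terms at rate 0.05; lncRNA truth is withheld from the
emitted annotation map. Hit tables plant mutual best hits at E ∈
[10⁻³⁰, 10⁻¹⁰] and decoys at E ∈ [10⁻⁴, 1] — entirely above the 10⁻⁵
threshold, so decoys are excluded by the cutoff alone. The genome layout
realizes the four subtypes deterministically around three-exon coding genes
spaced 100 kb apart.

The generator does **not** emulate: library-size or GC biases,
count-mantissa noise (values are continuous, not negative-binomial counts),
overlapping or hierarchical modules, hub genes, batch effects, partially
annotated ontologies with realistic term DAGs, paralog-confounded hit
tables, or sequence-level conservation. Passing the recovery tests
therefore demonstrates correctness of the algorithms under the stated
generative model, not performance on real transcriptome compendia.

## Numerical choices

- Hypergeometric tail summed upward from k in log space; exact to ~1e-12
  against rational-arithmetic enumeration for N ≤ 25.
- Fisher-Z p clamped into (0, 1]; Rs clamped before the transform as above.
- Edge output ordering is lexicographic in (gene_a, gene_b) with
  gene_a < gene_b, making edge lists byte-reproducible.
- The all-pairs correlation uses a rank-matrix product (O(G²n) memory-light
  at the scales used here: ≤ a few hundred genes in tests and analysis;
  the chunk size is the full matrix at these sizes).
- KS p = Kolmogorov limiting function at √(nm/(n+m))·D. This intentionally
  differs from scipy's small-sample-corrected "asymp" mode; tests verify
  the statistic against scipy and the p against the series itself.
- Percentile, variance and mean operations delegate to numpy/pandas;
  normal tails, rank data, gammaln/logsumexp and the Kolmogorov function to
  scipy; graph storage to networkx. The statistics defined above (edge
  test, C, T, hypergeometric tail, TSI, IoU, RBH, KS) are implemented in
  this package and cross-checked against independent oracles in the tests.

## Problem sizes

The bundled analysis and the test suite run at desk scale: 90 genes × 20
samples (≈ 4 000 gene pairs), 100-node graphs for the statistics oracles,
and 10-seed Monte-Carlo loops for the network-vs-random sign test. These
sizes give stable results for every planted-truth check while keeping the
full suite in the low minutes on one CPU.

## Known limitations

- The per-gene Bonferroni family is ambiguous in the underlying method
  description ("the sets of P-value for each gene were adjusted"); the
  both-endpoints rule implemented here is the conservative reading, and
  with all-pairs testing both endpoints share the same family size anyway.
- Evaluation sensitivity (stage 7) is a defined proxy, not a standardized
  metric; comparisons should be within-pipeline (network vs baseline, or
  across cutoffs), not across publications.
- Subtype precedence (stage 9) is a convention; real annotations contain
  edge cases (bidirectional promoters, nested genes) the four labels cannot
  express.
- The scale-free character of real networks is only exported as a log-log
  degree histogram; no power-law fit is claimed.
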