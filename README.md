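# lncnet

Most long non-coding RNAs (lncRNAs) have no known function: they are too
poorly conserved for homology transfer and carry no protein domains. A
productive alternative is **guilt by association**: if a lncRNA is
consistently co-expressed with a set of protein-coding genes across many
tissues and conditions, it plausibly participates in the same processes.
`lncnet` implements that analysis end to end for a coding-lncRNA expression
compendium (the motivating system is the zebrafish transcriptome, but the
pipeline is organism-agnostic): normalization, co-expression network
construction, network statistics, neighbor-enrichment annotation, and a set
of lncRNA conservation analyses. A synthetic-data module generates every
input with planted ground truth, so the whole pipeline is testable on a
laptop without downloads.

## Method

**Network.** FPKM matrices are upper-quartile normalized per sample
(ρᵢ = mean(k)/kᵢ with kᵢ the 75th percentile of sample *i*'s nonzero
values), and the top-75%-variance genes are kept. Every gene pair is tested
with Spearman's Rs (Pearson on mid-ranks); significance comes from the
Fisher transformation,

    F(Rs) = ½ ln((1+Rs)/(1−Rs)),   Z = √((n−3)/1.06) · F(Rs),

with Z approximately standard normal under independence. Each gene's
p-values are Bonferroni-adjusted by its number of tests, and an edge is kept
iff Rs ≥ 0.5 and both endpoints' adjusted p ≤ 0.01. Network quality is
summarized by the mean local clustering coefficient C and the transitivity
T = 3·triangles / connected triples.

**Annotation.** A lncRNA inherits a GO/KEGG term when the term is enriched
among its annotated coding neighbors by the hypergeometric upper tail
P(X ≥ k) with population N (network genes), M term carriers, n neighbors and
k term-carrying neighbors, at p < 0.05. Prediction quality is evaluated by
leave-one-out recovery on well-connected coding genes against a
random-neighbor baseline.

**Conservation.** Cross-species lncRNA orthologs are reciprocal best hits
in bidirectional tabular alignment hits (E ≤ 10⁻⁵); conserved lncRNAs are
then profiled by tissue specificity (TSI = max(x)/Σx), matched-tissue
expression correlation, intersection-over-union of upstream TF-family sets,
and exon-averaged per-base conservation scores, with distributions compared
by two-sample Kolmogorov-Smirnov tests.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1, moderate noise):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_network.py
python analysis/03_annotate.py
```

which prints (abridged):

```
network: 90 nodes, 757 edges
  coding-coding: 327 edges (43.2%)
  coding-lnc: 356 edges (47.03%)
  lnc-lnc: 74 edges (9.78%)
  clustering coefficient C = 0.9905
  transitivity T = 0.9905
annotated 30/30 lncRNAs with at least one enriched term
mean recovery of planted lncRNA terms: 1.0000
leave-one-out prediction sensitivity: network 0.8994 vs random neighbors 0.1016
```

The five planted modules are near-cliques (C ≈ 0.99); every lncRNA recovers
its module's planted terms through its coding neighbors, and real
neighborhoods predict held-out coding annotations about nine times better
than random same-size neighbor sets. `analysis/04_conserve.py` and
`analysis/05_features.py` continue with ortholog recovery (12/12 planted
pairs), TSI/conservation-score KS comparisons, and perfect positional
subtype classification. The same flow is available as a library call
(`lncnet.demo(seed=1)`) or through the `lncnet` CLI (`lncnet demo`,
`lncnet build`, `lncnet annotate`, `lncnet conserve`, `lncnet run`).

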