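"""Guilt-by-association functional annotation of lncRNAs.

An unannotated gene inherits the functions that are over-represented among
its immediate network neighbors.  For a term carried by M of the N network
genes, with the focal gene having n neighbors of which k carry the term,
the enrichment p-value is the hypergeometric upper tail

    P = 1 - sum_{i=0}^{k-1} C(M, i) C(N-M, n-i) / C(N, n)
      = sum_{i=k}^{min(M, n)} C(M, i) C(N-M, n-i) / C(N, n)

computed term-by-term in log space.  GO and KEGG annotations share this
code path; only the input table differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationMap:
    """gene -> set of term ids over a defined term universe.

    ``parents`` optionally maps each term to its parent terms (a DAG) for
    ancestor propagation.
    """

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)
    kind: str = "generic"  # GO-BP | KEGG | generic
    parents: Optional[dict[str, set[str]]] = None

    def __post_init__(self) -> None:
        annotated = set().union(*self.terms.values()) if self.terms else set()
        if not self.universe:
            self.universe = set(annotated)
        elif not annotated <= self.universe:
            raise AnnotationError(
                f"terms outside universe: {sorted(annotated - self.universe)[:5]}"
            )

    def get(self, gene: str) -> set[str]:
        return self.terms.get(gene, set())

    def __contains__(self, gene: str) -> bool:
        return gene in self.terms and bool(self.terms[gene])


def read_annotation_map(path, kind: str = "generic", parents_path=None) -> AnnotationMap:
    """Read a two-column (gene_id, term_id) TSV, one row per association."""
    df = pd.read_csv(path, sep="\t", header=0)
    terms: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False):
        terms.setdefault(str(gene), set()).add(str(term))
    parents = None
    if parents_path is not None:
        pdf = pd.read_csv(parents_path, sep="\t", header=0)
        parents = {}
        for child, parent in pdf.itertuples(index=False):
            parents.setdefault(str(child), set()).add(str(parent))
    return AnnotationMap(terms=terms, kind=kind, parents=parents)


def write_annotation_map(ann: AnnotationMap, path) -> None:
    rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(ann.terms)
        for t in sorted(ann.terms[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        path, sep="\t", index=False
    )


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(N: int, M: int, n: int, k: int) -> float:
    """P(X >= k) for X hypergeometric(N, M, n), exact, in log space.

    N: population size; M: successes in the population; n: draws;
    k: observed successes.  Summing the upper tail directly avoids the
    cancellation of the printed 1-minus-lower-tail form.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= k <= min(M, n)):
        raise AnnotationError(
            f"invalid hypergeometric parameters N={N} M={M} n={n} k={k}"
        )
    if k == 0:
        return 1.0
    hi = min(M, n)
    lo = max(k, n - (N - M))
    if lo > hi:
        return 0.0
    i = np.arange(lo, hi + 1)
    log_terms = _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene/term enrichment with the counts entering the test."""

    gene: str
    term: str
    N: int
    M: int
    n: int
    k: int
    p: float


def _term_counts(net: nx.Graph, ann: AnnotationMap) -> dict[str, int]:
    counts: dict[str, int] = {}
    for g in net.nodes:
        for t in ann.get(g):
            counts[t] = counts.get(t, 0) + 1
    return counts


def annotate_gene(
    net: nx.Graph,
    ann: AnnotationMap,
    gene: str,
    p_threshold: float = 0.05,
    coding_only: bool = False,
    universe_annotated_only: bool = False,
    neighbors: Optional[Sequence[str]] = None,
    exclude: Optional[set[str]] = None,
    term_counts: Optional[dict[str, int]] = None,
) -> list[EnrichmentResult]:
    """Enrich the immediate neighborhood of ``gene`` against ``ann``.

    N = genes in the network (or annotated genes only, with
    ``universe_annotated_only``); M = network genes carrying the term;
    n = neighbor count; k = neighbors carrying the term.  Results with
    p < p_threshold are returned sorted by p then term id.

    ``neighbors`` overrides the network neighborhood (used by the
    random-baseline evaluation); ``exclude`` removes genes from the
    annotation source (used to hide a test gene's own annotations).
    """
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in network")
    exclude = exclude or set()

    def gene_terms(g: str) -> set[str]:
        return set() if g in exclude else ann.get(g)

    if neighbors is None:
        neighbors = list(net.neighbors(gene))
    if coding_only:
        neighbors = [
            g for g in neighbors if net.nodes[g].get("biotype") == "coding"
        ]
    if universe_annotated_only:
        pool = [g for g in net.nodes if gene_terms(g)]
        N = len(pool)
        counts: dict[str, int] = {}
        for g in pool:
            for t in gene_terms(g):
                counts[t] = counts.get(t, 0) + 1
    else:
        N = net.number_of_nodes()
        if term_counts is not None and not exclude:
            counts = term_counts
        else:
            counts = {}
            for g in net.nodes:
                for t in gene_terms(g):
                    counts[t] = counts.get(t, 0) + 1
    n = len(neighbors)
    k_by_term: dict[str, int] = {}
    for nb in neighbors:
        for t in gene_terms(nb):
            k_by_term[t] = k_by_term.get(t, 0) + 1
    results = []
    for term, k in k_by_term.items():
        M = counts[term]
        p = hypergeom_upper_tail(N, M, n, k)
        if p < p_threshold:
            results.append(EnrichmentResult(gene, term, N, M, n, k, p))
    results.sort(key=lambda r: (r.p, r.term))
    return results


def annotate_all_lncrnas(
    net: nx.Graph,
    ann: AnnotationMap,
    p_threshold: float = 0.05,
    coding_only: bool = True,
) -> dict[str, list[EnrichmentResult]]:
    """Apply neighbor enrichment to every lncRNA node.

    By default only coding neighbors are counted, matching the convention of
    annotating a lncRNA from its annotated protein-coding partners.  Genes
    with no enriched term map to an empty list.
    """
    counts = _term_counts(net, ann)
    out = {}
    for gene in sorted(net.nodes):
        if net.nodes[gene].get("biotype") != "lncRNA":
            continue
        out[gene] = annotate_gene(
            net, ann, gene,
            p_threshold=p_threshold,
            coding_only=coding_only,
            term_counts=counts,
        )
    return out


def annotation_summary(results: Mapping[str, list[EnrichmentResult]]) -> dict:
    annotated = sum(1 for v in results.values() if v)
    return {
        "n_genes": len(results),
        "n_annotated": annotated,
        "n_unannotated": len(results) - annotated,
    }


def propagate_ancestors(ann: AnnotationMap) -> AnnotationMap:
    """Close every gene's term set under the term-parent relation."""
    if ann.parents is None:
        raise AnnotationError("no parent relation provided")
    ancestors: dict[str, set[str]] = {}

    def visit(term: str, trail: tuple) -> set[str]:
        if term in trail:
            cycle = trail[trail.index(term):] + (term,)
            raise AnnotationError(f"cycle in term hierarchy: {' -> '.join(cycle)}")
        if term in ancestors:
            return ancestors[term]
        acc: set[str] = set()
        for parent in ann.parents.get(term, ()):
            acc.add(parent)
            acc |= visit(parent, trail + (term,))
        ancestors[term] = acc
        return acc

    new_terms = {}
    for gene, terms in ann.terms.items():
        closed = set(terms)
        for t in terms:
            closed |= visit(t, ())
        new_terms[gene] = closed
    universe = set(ann.universe)
    for s in new_terms.values():
        universe |= s
    return AnnotationMap(
        terms=new_terms, universe=universe, kind=ann.kind, parents=ann.parents
    )


def evaluate_prediction(
    net: nx.Graph,
    ann: AnnotationMap,
    min_neighbors: int = 10,
    n_random: int = 100,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Leave-one-out sensitivity of neighbor enrichment on coding test genes.

    Test genes are coding genes with at least ``min_neighbors`` annotated
    coding neighbors.  For each, its own annotations are hidden, terms are
    predicted from its real neighborhood, and sensitivity is the fraction of
    its true terms recovered; the baseline repeats the prediction with the
    neighborhood replaced by a uniformly random same-size set of annotated
    coding genes, averaged over ``n_random`` draws.
    """
    rng = np.random.default_rng(seed)
    coding = [g for g in net.nodes if net.nodes[g].get("biotype") == "coding"]
    annotated_coding = [g for g in coding if ann.get(g)]
    test_genes = []
    for g in sorted(coding):
        if not ann.get(g):
            continue
        known_nbrs = [
            nb for nb in net.neighbors(g)
            if net.nodes[nb].get("biotype") == "coding" and ann.get(nb)
        ]
        if len(known_nbrs) >= min_neighbors:
            test_genes.append((g, known_nbrs))
    if not test_genes:
        raise AnnotationError("no test genes with enough annotated neighbors")

    def sensitivity(gene: str, neighbors: list[str]) -> float:
        true_terms = ann.get(gene)
        predicted = {
            r.term
            for r in annotate_gene(
                net, ann, gene,
                p_threshold=p_threshold,
                neighbors=neighbors,
                exclude={gene},
            )
        }
        return len(predicted & true_terms) / len(true_terms)

    net_scores = [sensitivity(g, nbrs) for g, nbrs in test_genes]
    base_scores = []
    for g, nbrs in test_genes:
        pool = [x for x in annotated_coding if x != g]
        size = min(len(nbrs), len(pool))
        draws = [
            sensitivity(g, list(rng.choice(pool, size=size, replace=False)))
            for _ in range(n_random)
        ]
        base_scores.append(float(np.mean(draws)))
    return float(np.mean(net_scores)), float(np.mean(base_scores))


def write_enrichment(results: Mapping[str, list[EnrichmentResult]], path) -> None:
    rows = [
        {"gene": r.gene, "term": r.term, "N": r.N, "M": r.M, "n": r.n,
         "k": r.k, "p": r.p}
        for gene in sorted(results)
        for r in results[gene]
    ]
    pd.DataFrame(rows, columns=["gene", "term", "N", "M", "n", "k", "p"]).to_csv(
        path, sep="\t", index=False
    )
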