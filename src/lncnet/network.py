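"""Co-expression network construction and statistics.

Edges are tested with a Spearman correlation whose significance comes from
the Fisher transformation:

    Rs  = Pearson correlation of the average ranks of x and y
    F   = 1/2 * ln((1 + Rs) / (1 - Rs))
    Z   = sqrt((n - 3) / 1.06) * F

Z is approximately standard normal under independence; the two-sided normal
tail gives the p-value.  Each gene's p-values are Bonferroni-adjusted by the
number of tests that gene participates in, and an edge survives only if the
adjusted value at *both* endpoints passes alpha and Rs clears the cutoff.

Network statistics follow the triangle/triple definitions: the local
clustering coefficient of node i is (triangles at i) / (triples centered at
i), the graph coefficient C is the mean over all nodes (degree < 2 nodes
contribute 0), and the transitivity T is 3 * triangles / connected triples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: variance correction applied to the Fisher z-score of a Spearman coefficient
SPEARMAN_Z_CORRECTION = 1.06

EDGE_CATEGORIES = ("coding-coding", "coding-lnc", "lnc-lnc")


class EdgeTestError(ValueError):
    """Raised for degenerate edge-test inputs (constant vector, n < 4)."""


@dataclass(frozen=True)
class EdgeRecord:
    """One tested gene pair; ``gene_a < gene_b`` lexicographically."""

    gene_a: str
    gene_b: str
    rs: float
    z: float
    p: float
    p_adj: float
    category: str


def edge_category(biotype_a: str, biotype_b: str) -> str:
    n_coding = (biotype_a == "coding") + (biotype_b == "coding")
    return EDGE_CATEGORIES[2 - n_coding]


def spearman_edge_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Return (Rs, Z, p) for one gene pair.

    Rs is computed as the Pearson correlation of mid-ranks; |Rs| = 1 is
    clamped to +/-(1 - 1e-15) before the Fisher transform so Z stays finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EdgeTestError("vectors must be 1-D and equal length")
    n = x.size
    if n < 4:
        raise EdgeTestError(f"need at least 4 samples, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise EdgeTestError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rs = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rs_c = min(max(rs, -(1 - 1e-15)), 1 - 1e-15)
    f = 0.5 * np.log((1 + rs_c) / (1 - rs_c))
    z = float(np.sqrt((n - 3) / SPEARMAN_Z_CORRECTION) * f)
    p = float(2 * stats.norm.sf(abs(z)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return rs, z, p


def _rank_matrix(values: pd.DataFrame) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values.to_numpy(dtype=float))


def build_network(
    m: ExpressionMatrix,
    rho_cutoff: float = 0.5,
    alpha: float = 0.01,
    absolute: bool = False,
) -> nx.Graph:
    """Test all unordered gene pairs and keep the significant, correlated ones.

    Per-gene Bonferroni: each gene's p-values are multiplied by the number
    of tests involving that gene (capped at 1); the edge's ``p_adj`` is the
    max of its two endpoints' adjusted values.  An edge is kept iff
    Rs >= rho_cutoff (|Rs| with ``absolute``) and p_adj <= alpha.
    Constant-expression genes are excluded with a warning.

    Returns a :class:`networkx.Graph` whose nodes carry ``biotype`` and whose
    edges carry ``rs``, ``z``, ``p``, ``p_adj`` and ``category``; the
    construction parameters live in ``G.graph``.
    """
    if m.n_samples < 4:
        raise EdgeTestError("need at least 4 samples to build a network")
    arr = m.values.to_numpy(dtype=float)
    constant = np.all(arr == arr[:, :1], axis=1)
    if constant.any():
        dropped = [g for g, c in zip(m.gene_ids, constant) if c]
        logger.warning(
            "excluding %d constant-expression genes: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    genes = [g for g, c in zip(m.gene_ids, constant) if not c]
    if len(genes) < 2:
        raise EdgeTestError("fewer than 2 testable (non-constant) genes")
    n = m.n_samples
    ranks = _rank_matrix(m.values.loc[genes])
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    corr = (ranks @ ranks.T) / np.outer(norms, norms)
    np.clip(corr, -1.0, 1.0, out=corr)
    rs_c = np.clip(corr, -(1 - 1e-15), 1 - 1e-15)
    zmat = np.sqrt((n - 3) / SPEARMAN_Z_CORRECTION) * 0.5 * np.log(
        (1 + rs_c) / (1 - rs_c)
    )
    pmat = 2 * stats.norm.sf(np.abs(zmat))
    np.clip(pmat, np.nextafter(0, 1), 1.0, out=pmat)
    n_tests_per_gene = len(genes) - 1  # every gene is tested against all others

    g = nx.Graph(rho_cutoff=rho_cutoff, alpha=alpha, absolute=absolute)
    for gene in genes:
        g.add_node(gene, biotype=m.biotype[gene])
    order = sorted(range(len(genes)), key=lambda i: genes[i])
    for ii, jj in combinations(order, 2):
        rs = float(corr[ii, jj])
        strength = abs(rs) if absolute else rs
        if strength < rho_cutoff:
            continue
        p = float(pmat[ii, jj])
        # both endpoints share the all-pairs family size here, but the max
        # rule is kept explicit for generality
        p_adj = min(1.0, max(p * n_tests_per_gene, p * n_tests_per_gene))
        if p_adj > alpha:
            continue
        a, b = sorted((genes[ii], genes[jj]))
        g.add_edge(
            a, b,
            rs=rs,
            z=float(zmat[ii, jj]),
            p=p,
            p_adj=p_adj,
            category=edge_category(m.biotype[a], m.biotype[b]),
        )
    return g


def classify_edges(net: nx.Graph) -> dict:
    """Count edges per category and report fractions of the total."""
    counts = {c: 0 for c in EDGE_CATEGORIES}
    for _, _, data in net.edges(data=True):
        counts[data["category"]] += 1
    return edge_category_fractions(counts)


def edge_category_fractions(counts: dict) -> dict:
    """Totals and fractions from raw per-category counts.

    Fractions are exact; ``display`` carries them rounded to two decimals as
    percentages.  An empty network flags the fractions undefined.
    """
    total = sum(counts.values())
    if total == 0:
        return {
            "counts": dict(counts),
            "total": 0,
            "fractions": None,
            "display": None,
            "undefined": True,
        }
    fractions = {c: counts[c] / total for c in counts}
    display = {c: round(100 * fractions[c], 2) for c in counts}
    return {
        "counts": dict(counts),
        "total": total,
        "fractions": fractions,
        "display": display,
        "undefined": False,
    }


def _triangles_at(net: nx.Graph, node) -> int:
    nbrs = list(net.neighbors(node))
    return sum(1 for u, v in combinations(nbrs, 2) if net.has_edge(u, v))


def clustering_coefficient(net: nx.Graph) -> tuple[float, dict]:
    """Graph clustering coefficient C and the per-node values C_i.

    C_i = triangles at i / triples centered at i (deg*(deg-1)/2); nodes of
    degree < 2 get C_i = 0.  C is the mean of C_i over *all* nodes.
    """
    per_node = {}
    for node in net.nodes:
        d = net.degree(node)
        if d < 2:
            per_node[node] = 0.0
            continue
        per_node[node] = _triangles_at(net, node) / (d * (d - 1) / 2)
    if not per_node:
        return 0.0, per_node
    return float(np.mean(list(per_node.values()))), per_node


def transitivity(net: nx.Graph) -> float:
    """T = 3 * triangles / connected triples; 0 when the graph has no triples."""
    triples = sum(d * (d - 1) / 2 for _, d in net.degree())
    if triples == 0:
        return 0.0
    triangles = sum(_triangles_at(net, v) for v in net.nodes) / 3
    return float(3 * triangles / triples)


def network_stats(net: nx.Graph) -> dict:
    """Node/edge counts by biotype and category, C, T, degree histogram."""
    biotypes = nx.get_node_attributes(net, "biotype")
    node_counts = {"coding": 0, "lncRNA": 0}
    for b in biotypes.values():
        node_counts[b] = node_counts.get(b, 0) + 1
    cats = classify_edges(net)
    c, per_node = clustering_coefficient(net)
    degrees = [d for _, d in net.degree()]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "node_counts": node_counts,
        "edge_categories": cats,
        "clustering_coefficient": c,
        "per_node_clustering": per_node,
        "transitivity": transitivity(net),
        "degree_histogram": hist,
    }


def network_sweep(
    m: ExpressionMatrix,
    cutoffs: Iterable[float],
    alpha: float = 0.01,
    absolute: bool = False,
) -> pd.DataFrame:
    """Build one network per Rs cutoff and tabulate its summary statistics."""
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("empty cutoff list")
    rows = []
    for cutoff in cutoffs:
        net = build_network(m, rho_cutoff=cutoff, alpha=alpha, absolute=absolute)
        s = network_stats(net)
        rows.append(
            {
                "cutoff": cutoff,
                "nodes": s["n_nodes"],
                "edges": s["n_edges"],
                "clustering_coefficient": s["clustering_coefficient"],
                "transitivity": s["transitivity"],
            }
        )
    return pd.DataFrame(rows)


def ego_subnetwork(
    net: nx.Graph, gene: str, neighbor_filter=None
) -> nx.Graph:
    """Induced subgraph on ``gene`` plus its (optionally filtered) neighbors.

    ``neighbor_filter`` may be a biotype string or a predicate over
    (node, attribute dict).
    """
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in network")
    if neighbor_filter is None:
        keep = lambda n, d: True  # noqa: E731
    elif isinstance(neighbor_filter, str):
        keep = lambda n, d, b=neighbor_filter: d.get("biotype") == b  # noqa: E731
    else:
        keep = neighbor_filter
    nodes = [gene] + [
        n for n in net.neighbors(gene) if keep(n, net.nodes[n])
    ]
    return net.subgraph(nodes).copy()


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {
            "gene_a": a,
            "gene_b": b,
            "rs": d["rs"],
            "z": d["z"],
            "p": d["p"],
            "p_adj": d["p_adj"],
            "category": d["category"],
        }
        for a, b, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "rs", "z", "p", "p_adj", "category"]
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path, biotype: Optional[pd.Series] = None) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(
            row.gene_a, row.gene_b,
            rs=row.rs, z=row.z, p=row.p, p_adj=row.p_adj, category=row.category,
        )
    if biotype is not None:
        for n in g.nodes:
            if n in biotype.index:
                g.nodes[n]["biotype"] = biotype[n]
    return g
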