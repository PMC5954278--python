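"""lncRNA conservation analyses.

* Reciprocal best hits (RBH) between two species' transcript sets from
  tabular alignment hits, a standard orthology proxy.
* Tissue specificity index, TSI = max(x) / sum(x); 1 means expression in a
  single tissue, 1/n means uniform expression over n tissues.
* Spearman correlation of matched-tissue expression for each ortholog pair.
* Intersection-over-union of upstream transcription-factor family sets,
  S = |TF_A intersect TF_B| / |TF_A union TF_B|.
* Length-weighted mean of a per-base conservation score track over a
  transcript's exons.
* Two-sample Kolmogorov-Smirnov comparison of score distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .network import spearman_edge_test

logger = logging.getLogger(__name__)

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class HitTableError(ValueError):
    pass


def read_hit_table(path) -> pd.DataFrame:
    """Read a 12-column tabular alignment hit table (BLAST outfmt 6)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    except Exception as exc:
        raise HitTableError(f"cannot parse hit table {path}: {exc}")
    for i, ev in enumerate(df["evalue"]):
        if not np.isfinite(ev) or ev < 0:
            raise HitTableError(f"{path}: bad E-value at line {i + 1}: {ev!r}")
    return df


def write_hit_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    forward_evalue: float
    reverse_evalue: float


def _best_hits(df: pd.DataFrame, e_max: float) -> dict[str, tuple[str, float]]:
    kept = df[df["evalue"] <= e_max]
    best: dict[str, tuple[str, float, float]] = {}
    for row in kept.itertuples(index=False):
        cur = best.get(row.qseqid)
        cand = (row.sseqid, float(row.evalue), float(row.bitscore))
        if cur is None:
            best[row.qseqid] = cand
            continue
        # lowest E-value wins; ties by highest bit score, then subject id
        if (cand[1], -cand[2], cand[0]) < (cur[1], -cur[2], cur[0]):
            best[row.qseqid] = cand
    return {q: (s, e) for q, (s, e, _) in best.items()}


def reciprocal_best_hits(
    forward: pd.DataFrame, reverse: pd.DataFrame, e_max: float = 1e-5
) -> list[OrthologPair]:
    """Mutual-best pairs: best(a) = b in forward AND best(b) = a in reverse."""
    fwd = _best_hits(forward, e_max)
    rev = _best_hits(reverse, e_max)
    pairs = []
    for a in sorted(fwd):
        b, ev_f = fwd[a]
        if b in rev and rev[b][0] == a:
            pairs.append(OrthologPair(a, b, ev_f, rev[b][1]))
    return pairs


def collapse_to_genes(
    pairs: Iterable[OrthologPair],
    tx2gene_a: Mapping[str, str],
    tx2gene_b: Mapping[str, str],
) -> list[OrthologPair]:
    """Collapse transcript-level RBH pairs to gene pairs.

    A gene is counted once however many of its transcripts found a partner;
    the representative pair is the one with the lowest forward E-value.
    """
    best: dict[tuple[str, str], OrthologPair] = {}
    for p in pairs:
        key = (tx2gene_a.get(p.gene_a, p.gene_a), tx2gene_b.get(p.gene_b, p.gene_b))
        cur = best.get(key)
        if cur is None or p.forward_evalue < cur.forward_evalue:
            best[key] = OrthologPair(key[0], key[1], p.forward_evalue, p.reverse_evalue)
    return [best[k] for k in sorted(best)]


def tsi(x: Sequence[float]) -> float:
    """Tissue specificity index max(x)/sum(x) of a nonnegative profile."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("TSI requires nonnegative expression")
    total = x.sum()
    if total == 0:
        raise ValueError("TSI undefined for an all-zero profile")
    return float(x.max() / total)


@dataclass
class TissueProfile:
    """Per-gene expression over a fixed, shared tissue order."""

    tissues: list[str]
    values: dict[str, np.ndarray]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TissueProfile":
        return cls(
            tissues=list(df.columns),
            values={g: df.loc[g].to_numpy(dtype=float) for g in df.index},
        )


def read_tissue_profiles(path) -> TissueProfile:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TissueProfile.from_frame(df)


def ortholog_expression_correlation(
    pairs: Iterable[OrthologPair],
    profiles_a: TissueProfile,
    profiles_b: TissueProfile,
) -> pd.DataFrame:
    """Spearman Rs between matched-tissue profiles of each ortholog pair.

    Pairs with a constant profile (rank correlation undefined) are skipped
    with a warning.
    """
    if profiles_a.tissues != profiles_b.tissues:
        raise ValueError(
            f"tissue lists differ: {profiles_a.tissues} vs {profiles_b.tissues}"
        )
    rows = []
    for p in pairs:
        xa = profiles_a.values.get(p.gene_a)
        xb = profiles_b.values.get(p.gene_b)
        if xa is None or xb is None:
            logger.warning("pair (%s, %s) not profiled; skipped", p.gene_a, p.gene_b)
            continue
        if np.all(xa == xa[0]) or np.all(xb == xb[0]):
            logger.warning(
                "pair (%s, %s) has a constant profile; skipped", p.gene_a, p.gene_b
            )
            continue
        rs, _, _ = spearman_edge_test(xa, xb)
        rows.append({"gene_a": p.gene_a, "gene_b": p.gene_b, "rs": rs})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rs"])


def tf_family_iou(set_a: set, set_b: set) -> float:
    """Intersection-over-union of two TF family sets; undefined when both empty."""
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if not union:
        raise ValueError("IoU undefined for two empty sets")
    return len(set_a & set_b) / len(union)


def read_tf_families(path) -> dict[str, set[str]]:
    """Two-column (gene_id, tf_family) TSV -> gene -> family set."""
    df = pd.read_csv(path, sep="\t", header=0)
    out: dict[str, set[str]] = {}
    for gene, fam in df.itertuples(index=False):
        out.setdefault(str(gene), set()).add(str(fam))
    return out


def read_bedgraph(path) -> dict[str, list[tuple[int, int, float]]]:
    """4-column bedGraph (chrom, start, end, value), 0-based half-open."""
    track: dict[str, list[tuple[int, int, float]]] = {}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    for row in df.itertuples(index=False):
        if row.end <= row.start or row.start < 0:
            raise ValueError(
                f"{path}: bad interval {row.chrom}:{row.start}-{row.end}"
            )
        track.setdefault(str(row.chrom), []).append(
            (int(row.start), int(row.end), float(row.value))
        )
    for chrom in track:
        track[chrom].sort()
    return track


def conservation_score(
    exons: Sequence[tuple[int, int]],
    chrom: str,
    track: Mapping[str, list[tuple[int, int, float]]],
) -> float:
    """Length-weighted mean track value over exonic bases; uncovered bases = 0.

    Intervals are intersected arithmetically, never expanded per base, so
    splitting an exon into adjacent pieces cannot change the score.
    """
    total_len = 0
    weighted = 0.0
    intervals = track.get(chrom, [])
    for start, end in exons:
        if end <= start:
            raise ValueError(f"bad exon {start}-{end}")
        total_len += end - start
        for istart, iend, value in intervals:
            lo, hi = max(start, istart), min(end, iend)
            if lo < hi:
                weighted += (hi - lo) * value
    if total_len == 0:
        raise ValueError("transcript has no exonic bases")
    return weighted / total_len


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic D = sup|ECDF_a - ECDF_b| and its asymptotic p.

    p uses the Kolmogorov limiting distribution evaluated at
    sqrt(n*m/(n+m)) * D.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = np.sqrt(a.size * b.size / (a.size + b.size))
    p = float(np.clip(special.kolmogorov(en * d), 0.0, 1.0))
    return d, p
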