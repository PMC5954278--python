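"""Gene models, genomic-location subtype classification, transcript filters
and structure summaries.

A lncRNA is placed in one of four positional subtypes relative to the
protein-coding annotation, by precedence:

1. any exon-exon overlap with a coding gene on the same strand
   -> ``sense_overlapping``;
2. else any overlap with a coding gene's span on the opposite strand
   -> ``antisense``;
3. else fully contained in a same-strand coding span without exon overlap
   -> ``intronic``;
4. else ``intergenic``.

Coordinates are 0-based half-open internally; GFF3 (1-based closed) is
converted on read/write, BED12 is consumed natively.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SUBTYPES = ("intergenic", "sense_overlapping", "antisense", "intronic")


@dataclass
class GeneModel:
    """One transcript: sorted, disjoint exons on a chromosome strand."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s or s < 0:
                raise ValueError(f"{self.transcript_id}: bad exon {s}-{e}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


def _span_overlap(a_start, a_end, b_start, b_end) -> bool:
    return max(a_start, b_start) < min(a_end, b_end)


def classify_subtype(lnc: GeneModel, coding_models: Sequence[GeneModel]) -> str:
    """Positional subtype of a lncRNA relative to the coding annotation."""
    chroms = {m.chrom for m in coding_models}
    if chroms and lnc.chrom not in chroms:
        logger.warning(
            "%s: chromosome %s has no coding annotation; intergenic",
            lnc.transcript_id, lnc.chrom,
        )
        return "intergenic"
    overlapping = [
        m for m in coding_models
        if m.chrom == lnc.chrom and _span_overlap(lnc.start, lnc.end, m.start, m.end)
    ]
    # 1: exon-exon overlap, same strand
    for m in overlapping:
        if m.strand != lnc.strand:
            continue
        for ls, le in lnc.exons:
            if any(_span_overlap(ls, le, cs, ce) for cs, ce in m.exons):
                return "sense_overlapping"
    # 2: any opposite-strand span overlap
    if any(m.strand != lnc.strand for m in overlapping):
        return "antisense"
    # 3: fully inside a same-strand coding span (no exon overlap by above)
    for m in overlapping:
        if m.strand == lnc.strand and m.start <= lnc.start and lnc.end <= m.end:
            return "intronic"
    return "intergenic"


def classify_gene_subtypes(
    lnc_models: Sequence[GeneModel], coding_models: Sequence[GeneModel]
) -> dict[str, str]:
    """Gene-level subtype: the first transcript's label (coordinate order)."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in lnc_models:
        by_gene.setdefault(m.gene_id, []).append(m)
    out = {}
    for gene, models in by_gene.items():
        models = sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id))
        labels = [classify_subtype(m, coding_models) for m in models]
        if len(set(labels)) > 1:
            logger.info(
                "gene %s: transcripts disagree on subtype %s; using first", gene, labels
            )
        out[gene] = labels[0]
    return out


@dataclass
class TranscriptMetrics:
    transcript_id: str
    fpkm: float
    length: int
    exon_count: int


def transcript_filter(
    t: TranscriptMetrics, biotype_known_coding: bool = False
) -> tuple[bool, str]:
    """Expression/length filter for candidate lncRNA transcripts.

    Multi-exon transcripts need FPKM > 0.1; single-exon transcripts need
    FPKM > 5 and length > 2000; everything under 200 nt is dropped, as is
    anything already annotated as coding.  Returns (keep, reason) where the
    reason names the first failing rule (or "pass").
    """
    if biotype_known_coding:
        return False, "known coding"
    if t.length < 200:
        return False, "length < 200"
    if t.exon_count == 1:
        if t.fpkm <= 5:
            return False, "single-exon FPKM <= 5"
        if t.length <= 2000:
            return False, "single-exon length <= 2000"
        return True, "pass"
    if t.fpkm <= 0.1:
        return False, "multi-exon FPKM <= 0.1"
    return True, "pass"


def chromosome_density(
    models: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    window: int = 10_000_000,
) -> dict:
    """Genes per window, counted at the 5'-most coordinate, per biotype.

    Returns per-chromosome window counts and per-biotype genome-wide mean
    density (genes per window over all windows of all chromosomes).
    """
    seen: set[tuple[str, str]] = set()
    counts: dict[str, dict[str, Counter]] = {}
    for m in models:
        key = (m.gene_id, m.biotype)
        if key in seen:  # count genes once, not per transcript
            continue
        seen.add(key)
        size = chrom_sizes.get(m.chrom)
        pos = m.five_prime
        if size is not None and pos >= size:
            logger.warning(
                "%s at %d beyond %s size %d; clamped", m.gene_id, pos, m.chrom, size
            )
            pos = size - 1
        win = pos // window
        counts.setdefault(m.biotype, {}).setdefault(m.chrom, Counter())[win] += 1
    n_windows = sum(
        max(1, math.ceil(size / window)) for size in chrom_sizes.values()
    )
    means = {
        biotype: sum(sum(c.values()) for c in per_chrom.values()) / n_windows
        for biotype, per_chrom in counts.items()
    }
    return {
        "window": window,
        "per_chrom": {
            b: {c: dict(cnt) for c, cnt in per.items()} for b, per in counts.items()
        },
        "mean_per_window": means,
    }


def structure_summaries(models: Sequence[GeneModel]) -> dict:
    """Isoform-count and exon-count histograms per biotype.

    Isoforms are binned 1/2/3/">=4", exon counts 1/2/3/4/">=5", with
    fractions alongside raw counts.
    """
    out: dict[str, dict] = {}
    by_biotype: dict[str, list[GeneModel]] = {}
    for m in models:
        by_biotype.setdefault(m.biotype, []).append(m)
    for biotype, ms in by_biotype.items():
        iso = Counter()
        for m in ms:
            iso[m.gene_id] += 1
        iso_hist = Counter(iso.values())
        exon_hist = Counter(m.exon_count for m in ms)
        iso_bins = _bin_counts(iso_hist, [1, 2, 3], ">=4")
        exon_bins = _bin_counts(exon_hist, [1, 2, 3, 4], ">=5")
        out[biotype] = {
            "n_genes": len(iso),
            "n_transcripts": len(ms),
            "isoform_bins": iso_bins,
            "exon_bins": exon_bins,
            "isoform_hist": dict(iso_hist),
            "exon_hist": dict(exon_hist),
        }
    return out


def _bin_counts(hist: Counter, singles: list[int], tail_label: str) -> dict:
    total = sum(hist.values())
    bins = {str(s): hist.get(s, 0) for s in singles}
    bins[tail_label] = sum(v for k, v in hist.items() if k > singles[-1])
    fractions = {k: (v / total if total else 0.0) for k, v in bins.items()}
    return {"counts": bins, "fractions": fractions}


# --- GFF3 / BED12 (gene -> mRNA/transcript -> exon dialect) -----------------

def write_gff3(models: Iterable[GeneModel], path) -> None:
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(by_gene):
            ms = sorted(by_gene[gene_id], key=lambda m: (m.chrom, m.start))
            g_start = min(m.start for m in ms)
            g_end = max(m.end for m in ms)
            first = ms[0]
            fh.write(
                f"{first.chrom}\tlncnet\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{first.strand}\t.\tID={gene_id};biotype={first.biotype}\n"
            )
            for m in ms:
                fh.write(
                    f"{m.chrom}\tlncnet\ttranscript\t{m.start + 1}\t{m.end}\t.\t"
                    f"{m.strand}\t.\tID={m.transcript_id};Parent={gene_id};"
                    f"biotype={m.biotype}\n"
                )
                for i, (s, e) in enumerate(m.exons, 1):
                    fh.write(
                        f"{m.chrom}\tlncnet\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                    )


def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for field_ in text.strip().split(";"):
        if "=" in field_:
            k, v = field_.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Read the gene/transcript/exon GFF3 dialect written by this package."""
    tx_meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            attrs = _gff3_attributes(attrs)
            if ftype in ("transcript", "mRNA"):
                tx_meta[attrs["ID"]] = {
                    "gene_id": attrs.get("Parent", attrs["ID"]),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("biotype", "coding"),
                }
            elif ftype == "exon":
                exons.setdefault(attrs["Parent"], []).append(
                    (int(start) - 1, int(end))
                )
    models = []
    for tx_id, meta in tx_meta.items():
        if tx_id not in exons:
            raise ValueError(f"{path}: transcript {tx_id} has no exons")
        models.append(
            GeneModel(
                gene_id=meta["gene_id"],
                transcript_id=tx_id,
                chrom=meta["chrom"],
                strand=meta["strand"],
                exons=exons[tx_id],
                biotype=meta["biotype"],
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


def write_bed12(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id)):
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - m.start) for s, _ in m.exons) + ","
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.transcript_id}\t0\t{m.strand}\t"
                f"{m.start}\t{m.end}\t0\t{len(m.exons)}\t{sizes}\t{starts}\n"
            )


def read_bed12(
    path, gene_map: Optional[Mapping[str, str]] = None, biotype: str = "coding"
) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}: BED12 needs 12 columns: {line!r}")
            chrom, start, _end, name, _, strand = parts[:6]
            start = int(start)
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            gene_id = gene_map.get(name, name) if gene_map else name
            models.append(
                GeneModel(
                    gene_id=gene_id, transcript_id=name, chrom=chrom,
                    strand=strand, exons=exons, biotype=biotype,
                )
            )
    return models
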