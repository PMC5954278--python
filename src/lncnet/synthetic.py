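"""Synthetic data with planted ground truth for every pipeline stage.

The expression model is a latent tissue profile per module: gene g in
module m has

    expr_g = softplus(module_effect * profile_m + eps_g),   eps_g ~ N(0, noise_sd)

per sample, which keeps values nonnegative and FPKM-like while preserving
the rank structure that a Spearman-based network detects.  Each module
contains both coding genes and lncRNAs; module 0 is made tissue-restricted
(expression outside its home tissue damped) so the tissue-specificity index
has a nontrivial spread.  Coding genes receive their module's planted terms
(plus background noise terms); lncRNA term truth is withheld from the
emitted annotation map so annotation recovery can be scored against it.

Ortholog hit tables plant one reciprocal best hit per true pair with
E-values far below the 1e-5 threshold; decoys draw E-values log-uniform in
[1e-4, 1], above the threshold, so the cutoff alone excludes them.  The
genome layout places lncRNAs to realize the four positional subtypes with
known labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .conserve import OUTFMT6_COLUMNS, TissueProfile
from .expression import ExpressionMatrix
from .features import GeneModel, SUBTYPES

N_BACKGROUND_TERMS = 10


@dataclass(frozen=True)
class SyntheticConfig:
    n_coding: int = 60
    n_lnc: int = 30
    n_modules: int = 5
    n_samples: int = 20
    n_tissues: int = 5
    module_effect: float = 3.0
    noise_sd: float = 0.5
    terms_per_module: int = 3
    n_decoy_hits: int = 20
    seed: int = 0
    background_term_rate: float = 0.05
    conserved_fraction: float = 0.4
    tf_shared: int = 2           # TF families shared within a true ortholog pair
    tf_unique: int = 1           # families private to each side
    tissue_restrict_factor: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_coding", "n_lnc", "n_modules", "n_samples",
                     "n_tissues", "terms_per_module"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4 (edge test degenerate below)")
        if self.n_tissues > self.n_samples:
            raise ValueError("n_tissues cannot exceed n_samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_decoy_hits < 0:
            raise ValueError("n_decoy_hits must be >= 0")
        if self.n_coding < self.n_modules or self.n_lnc < self.n_modules:
            raise ValueError("every module needs both biotypes: "
                             "n_coding and n_lnc must be >= n_modules")


@dataclass
class GroundTruth:
    """Planted truth retained alongside the emitted files."""

    gene_module: dict[str, int] = field(default_factory=dict)
    module_terms: dict[int, frozenset[str]] = field(default_factory=dict)
    lnc_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    subtype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_a = [a for a, _ in self.ortholog_pairs]
        seen_b = [b for _, b in self.ortholog_pairs]
        if len(set(seen_a)) != len(seen_a) or len(set(seen_b)) != len(seen_b):
            raise ValueError("ortholog pairs must be one-to-one")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def coding_ids(config: SyntheticConfig) -> list[str]:
    return [f"cod{i:04d}" for i in range(config.n_coding)]


def lnc_ids(config: SyntheticConfig) -> list[str]:
    return [f"lnc{i:04d}" for i in range(config.n_lnc)]


def module_term_set(module: int, terms_per_module: int) -> frozenset[str]:
    return frozenset(f"TERM:m{module}_{j}" for j in range(terms_per_module))


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Gene x sample FPKM-like matrix with planted co-expression modules."""
    rng = np.random.default_rng(config.seed)
    samples = [f"s{i:03d}" for i in range(config.n_samples)]
    tissue = pd.Series(
        {
            s: f"tissue{(i * config.n_tissues) // config.n_samples}"
            for i, s in enumerate(samples)
        }
    )
    genes = coding_ids(config) + lnc_ids(config)
    biotype = pd.Series(
        {g: ("coding" if g.startswith("cod") else "lncRNA") for g in genes}
    )
    # round-robin module assignment within each biotype guarantees both
    # biotypes in every module
    gene_module = {
        g: i % config.n_modules for i, g in enumerate(coding_ids(config))
    }
    gene_module.update(
        {g: i % config.n_modules for i, g in enumerate(lnc_ids(config))}
    )
    profiles = rng.normal(size=(config.n_modules, config.n_samples))
    noise = rng.normal(
        scale=config.noise_sd or 1.0, size=(len(genes), config.n_samples)
    )
    if config.noise_sd == 0:
        noise[:] = 0.0
    values = np.empty((len(genes), config.n_samples))
    for gi, g in enumerate(genes):
        m = gene_module[g]
        values[gi] = _softplus(config.module_effect * profiles[m] + noise[gi])
    # tissue-restrict module 0: damp its genes outside the first tissue
    home = tissue == "tissue0"
    damp = np.where(home.to_numpy(), 1.0, config.tissue_restrict_factor)
    for gi, g in enumerate(genes):
        if gene_module[g] == 0:
            values[gi] *= damp
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), biotype, tissue
    )
    module_terms = {
        m: module_term_set(m, config.terms_per_module)
        for m in range(config.n_modules)
    }
    lnc_terms = {g: module_terms[gene_module[g]] for g in lnc_ids(config)}
    n_conserved = int(round(config.conserved_fraction * config.n_lnc))
    conserved = list(lnc_ids(config))[:n_conserved]
    pairs = [(g, f"hsa{idx:04d}") for idx, g in enumerate(conserved)]
    truth = GroundTruth(
        gene_module=gene_module,
        module_terms=module_terms,
        lnc_terms=lnc_terms,
        ortholog_pairs=pairs,
    )
    return matrix, truth


def generate_annotations(truth: GroundTruth, config: SyntheticConfig):
    """Emit the coding-gene annotation map; lncRNA truth stays held out."""
    from .annotate import AnnotationMap

    rng = np.random.default_rng(config.seed + 1)
    background = [f"TERM:bg{j}" for j in range(N_BACKGROUND_TERMS)]
    terms: dict[str, set[str]] = {}
    for g in coding_ids(config):
        t = set(truth.module_terms[truth.gene_module[g]])
        if config.background_term_rate > 0:
            mask = rng.random(len(background)) < config.background_term_rate
            t |= {b for b, hit in zip(background, mask) if hit}
        terms[g] = t
    universe = set(background)
    for s in truth.module_terms.values():
        universe |= s
    return AnnotationMap(terms=terms, universe=universe, kind="generic")


def generate_hit_tables(
    truth: GroundTruth, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward (A->B) and reverse (B->A) alignment hit tables.

    True pairs get mutual best hits with E-value <= 1e-10; decoys are
    non-reciprocal with E-values in [1e-4, 1].
    """
    rng = np.random.default_rng(config.seed + 2)

    def hit_row(q, s, evalue, bitscore):
        length = int(rng.integers(150, 600))
        return {
            "qseqid": q, "sseqid": s,
            "pident": round(float(rng.uniform(75, 99)), 2),
            "length": length,
            "mismatch": int(rng.integers(0, 30)),
            "gapopen": int(rng.integers(0, 5)),
            "qstart": 1, "qend": length, "sstart": 1, "send": length,
            "evalue": evalue, "bitscore": bitscore,
        }

    fwd_rows, rev_rows = [], []
    for a, b in truth.ortholog_pairs:
        ev = 10.0 ** rng.uniform(-30, -10)
        bs = float(np.round(rng.uniform(200, 500), 1))
        fwd_rows.append(hit_row(a, b, ev, bs))
        rev_rows.append(hit_row(b, a, ev, bs))
    all_a = lnc_ids(config)
    all_b = [b for _, b in truth.ortholog_pairs] + [
        f"hsa_x{i:03d}" for i in range(10)
    ]
    for _ in range(config.n_decoy_hits):
        q = all_a[rng.integers(len(all_a))]
        s = all_b[rng.integers(len(all_b))]
        ev = 10.0 ** rng.uniform(-4, 0)  # above the 1e-5 cutoff
        fwd_rows.append(hit_row(q, s, ev, float(np.round(rng.uniform(20, 50), 1))))
        q2 = all_b[rng.integers(len(all_b))]
        s2 = all_a[rng.integers(len(all_a))]
        ev2 = 10.0 ** rng.uniform(-4, 0)
        rev_rows.append(hit_row(q2, s2, ev2, float(np.round(rng.uniform(20, 50), 1))))
    fwd = pd.DataFrame(fwd_rows, columns=OUTFMT6_COLUMNS)
    rev = pd.DataFrame(rev_rows, columns=OUTFMT6_COLUMNS)
    return fwd, rev


def generate_genome_layout(
    config: SyntheticConfig,
) -> tuple[list[GeneModel], GroundTruth]:
    """Coding + lncRNA gene models realizing all four positional subtypes.

    Coding genes are spaced 100 kb apart, three exons each; lncRNA i is
    placed relative to coding gene (i mod n_coding) to realize subtype
    SUBTYPES[i mod 4], alternating chromosome between chr1 and chr2.
    """
    models: list[GeneModel] = []
    truth = GroundTruth()
    spacing = 100_000
    for i, g in enumerate(coding_ids(config)):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        o = 10_000 + (i // 2) * spacing
        strand = "+" if i % 4 < 2 else "-"
        models.append(
            GeneModel(
                gene_id=g, transcript_id=f"{g}.t1", chrom=chrom, strand=strand,
                exons=[(o, o + 200), (o + 1000, o + 1200), (o + 2000, o + 2300)],
                biotype="coding",
            )
        )
        truth.subtype[g] = "coding"
    coding_models = list(models)
    for i, g in enumerate(lnc_ids(config)):
        host = coding_models[i % len(coding_models)]
        o = host.start
        subtype = SUBTYPES[i % 4]
        flip = {"+": "-", "-": "+"}
        if subtype == "intergenic":
            exons = [(o + 40_000, o + 40_400), (o + 41_000, o + 41_600)]
            strand = host.strand
        elif subtype == "sense_overlapping":
            exons = [(o + 100, o + 400), (o + 700, o + 900)]
            strand = host.strand
        elif subtype == "antisense":
            exons = [(o + 300, o + 600)]
            strand = flip[host.strand]
        else:  # intronic: inside the first intron (o+200, o+1000), same strand
            exons = [(o + 250, o + 550)]
            strand = host.strand
        models.append(
            GeneModel(
                gene_id=g, transcript_id=f"{g}.t1", chrom=host.chrom,
                strand=strand, exons=exons, biotype="lncRNA",
            )
        )
        truth.subtype[g] = subtype
    return models, truth


def generate_tissue_profiles(
    matrix: ExpressionMatrix, truth: GroundTruth, config: SyntheticConfig
) -> tuple[TissueProfile, TissueProfile]:
    """Per-tissue mean profiles for lncRNAs and their synthetic counterparts.

    The counterpart species' profile for a true ortholog is a noisy positive
    rescaling of the source profile, so matched pairs correlate while
    shuffled pairs do not.
    """
    rng = np.random.default_rng(config.seed + 3)
    tissues = sorted(set(matrix.tissue))
    by_tissue = {
        t: [s for s in matrix.sample_ids if matrix.tissue[s] == t] for t in tissues
    }
    lncs = matrix.genes_of_biotype("lncRNA")
    prof_a = {
        g: np.array(
            [matrix.values.loc[g, by_tissue[t]].mean() for t in tissues]
        )
        for g in lncs
    }
    prof_b = {}
    for a, b in truth.ortholog_pairs:
        base = prof_a[a]
        jitter = _softplus(rng.normal(scale=0.25 * (base.std() + 1e-9), size=base.size))
        prof_b[b] = base * rng.uniform(0.5, 2.0) + jitter
    return (
        TissueProfile(tissues=tissues, values=prof_a),
        TissueProfile(tissues=tissues, values=prof_b),
    )


def generate_tf_families(
    truth: GroundTruth, config: SyntheticConfig
) -> dict[str, set[str]]:
    """Upstream TF-family sets with controlled overlap for true pairs."""
    rng = np.random.default_rng(config.seed + 4)
    pool = [f"TFfam{j:02d}" for j in range(30)]
    out: dict[str, set[str]] = {}
    for a, b in truth.ortholog_pairs:
        chosen = rng.choice(len(pool), size=config.tf_shared + 2 * config.tf_unique,
                            replace=False)
        shared = {pool[j] for j in chosen[: config.tf_shared]}
        ua = {pool[j] for j in chosen[config.tf_shared: config.tf_shared + config.tf_unique]}
        ub = {pool[j] for j in chosen[config.tf_shared + config.tf_unique:]}
        out[a] = shared | ua
        out[b] = shared | ub
    return out


def generate_conservation_track(
    models: list[GeneModel], truth: GroundTruth, config: SyntheticConfig
) -> dict[str, list[tuple[int, int, float]]]:
    """bedGraph-style track: conserved genes score high, the rest low."""
    rng = np.random.default_rng(config.seed + 5)
    conserved = {a for a, _ in truth.ortholog_pairs}
    track: dict[str, list[tuple[int, int, float]]] = {}
    for m in models:
        if m.biotype == "coding" or m.gene_id in conserved:
            base = rng.uniform(0.6, 0.95)
        else:
            base = rng.uniform(0.02, 0.25)
        for s, e in m.exons:
            track.setdefault(m.chrom, []).append((s, e, round(float(base), 4)))
    for chrom in track:
        track[chrom].sort()
    return track


# --- bundle writer ----------------------------------------------------------

def write_bundle(config: SyntheticConfig, outdir) -> dict:
    """Generate every input the pipeline consumes and write it under outdir.

    Returns a manifest of written paths plus the in-memory truth objects.
    """
    from .annotate import write_annotation_map
    from .conserve import write_hit_table
    from .expression import write_expression
    from .features import write_bed12, write_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    matrix, truth = generate_expression(config)
    layout, layout_truth = generate_genome_layout(config)
    truth.subtype = layout_truth.subtype
    ann = generate_annotations(truth, config)
    fwd, rev = generate_hit_tables(truth, config)
    prof_a, prof_b = generate_tissue_profiles(matrix, truth, config)
    tf = generate_tf_families(truth, config)
    track = generate_conservation_track(layout, truth, config)

    paths = {
        "expression": outdir / "expression.tsv",
        "biotype": outdir / "biotype.tsv",
        "tissue": outdir / "tissue.tsv",
        "terms": outdir / "terms.tsv",
        "gff3": outdir / "models.gff3",
        "bed12": outdir / "models.bed",
        "hits_fwd": outdir / "hits_fwd.tsv",
        "hits_rev": outdir / "hits_rev.tsv",
        "tf_families": outdir / "tf_families.tsv",
        "track": outdir / "conservation.bedgraph",
        "profiles_a": outdir / "tissue_profiles_a.tsv",
        "profiles_b": outdir / "tissue_profiles_b.tsv",
    }
    write_expression(matrix, paths["expression"], paths["biotype"], paths["tissue"])
    write_annotation_map(ann, paths["terms"])
    write_gff3(layout, paths["gff3"])
    write_bed12(layout, paths["bed12"])
    write_hit_table(fwd, paths["hits_fwd"])
    write_hit_table(rev, paths["hits_rev"])
    pd.DataFrame(
        [(g, f) for g in sorted(tf) for f in sorted(tf[g])],
        columns=["gene_id", "tf_family"],
    ).to_csv(paths["tf_families"], sep="\t", index=False)
    pd.DataFrame(
        [(c, s, e, v) for c in sorted(track) for s, e, v in track[c]],
    ).to_csv(paths["track"], sep="\t", index=False, header=False)
    for key, prof in (("profiles_a", prof_a), ("profiles_b", prof_b)):
        pd.DataFrame(
            {t: [prof.values[g][i] for g in sorted(prof.values)]
             for i, t in enumerate(prof.tissues)},
            index=sorted(prof.values),
        ).to_csv(paths[key], sep="\t", index_label="gene_id")

    # truth tables
    pd.Series(truth.gene_module).rename("module").to_csv(
        outdir / "truth" / "gene_module.tsv", sep="\t", index_label="gene_id"
    )
    pd.DataFrame(
        [(g, t) for g in sorted(truth.lnc_terms) for t in sorted(truth.lnc_terms[g])],
        columns=["gene_id", "term_id"],
    ).to_csv(outdir / "truth" / "lnc_terms.tsv", sep="\t", index=False)
    pd.DataFrame(truth.ortholog_pairs, columns=["gene_a", "gene_b"]).to_csv(
        outdir / "truth" / "ortholog_pairs.tsv", sep="\t", index=False
    )
    pd.Series(truth.subtype).rename("subtype").to_csv(
        outdir / "truth" / "subtype.tsv", sep="\t", index_label="gene_id"
    )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "config": asdict(config),
        "truth": truth,
    }
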