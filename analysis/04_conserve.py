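#!/usr/bin/env python
"""Conservation analysis: orthologs, tissue specificity, regulatory overlap.

Resolves reciprocal best hits from the bidirectional hit tables (E-value
<= 1e-5), computes the tissue specificity index for every gene, correlates
matched-tissue expression of ortholog pairs, scores the TF-family
intersection-over-union, aggregates the per-base conservation track over
exons, and compares conserved vs non-conserved lncRNA distributions with
two-sample KS tests.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lncnet.conserve import (
    compare_distributions, conservation_score, ortholog_expression_correlation,
    read_bedgraph, read_hit_table, read_tf_families, read_tissue_profiles,
    reciprocal_best_hits, tf_family_iou, tsi,
)
from lncnet.expression import read_expression
from lncnet.features import read_gff3


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/conservation"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fwd = read_hit_table(args.inputs / "hits_fwd.tsv")
    rev = read_hit_table(args.inputs / "hits_rev.tsv")
    pairs = reciprocal_best_hits(fwd, rev, e_max=1e-5)
    truth = pd.read_csv(args.inputs / "truth" / "ortholog_pairs.tsv", sep="\t")
    true_set = set(zip(truth.gene_a, truth.gene_b))
    found = {(p.gene_a, p.gene_b) for p in pairs}
    print(f"reciprocal best hits: {len(found)} pairs "
          f"(recovered {len(found & true_set)}/{len(true_set)} planted)")
    pd.DataFrame(sorted(found), columns=["gene_a", "gene_b"]).to_csv(
        args.out / "rbh.tsv", sep="\t", index=False)

    m = read_expression(args.inputs / "expression.tsv",
                        args.inputs / "biotype.tsv",
                        args.inputs / "tissue.tsv")
    tissues = sorted(set(m.tissue))
    by_tissue = {t: [s for s in m.sample_ids if m.tissue[s] == t]
                 for t in tissues}
    conserved = {a for a, _ in found}
    rows = []
    for g in m.gene_ids:
        prof = np.array([m.values.loc[g, by_tissue[t]].mean() for t in tissues])
        if prof.sum() > 0:
            group = ("coding" if m.biotype[g] == "coding"
                     else "conserved_lnc" if g in conserved else "other_lnc")
            rows.append({"gene_id": g, "group": group, "tsi": tsi(prof)})
    tsi_df = pd.DataFrame(rows)
    tsi_df.to_csv(args.out / "tsi.tsv", sep="\t", index=False)
    ks = {}
    cons = tsi_df[tsi_df.group == "conserved_lnc"].tsi
    other = tsi_df[tsi_df.group == "other_lnc"].tsi
    if len(cons) and len(other):
        d, p = compare_distributions(cons, other)
        ks["tsi_conserved_vs_other_lnc"] = {"D": d, "p": p}
        print(f"TSI conserved vs other lncRNA: D={d:.3f}, p={p:.3g}")

    pa = read_tissue_profiles(args.inputs / "tissue_profiles_a.tsv")
    pb = read_tissue_profiles(args.inputs / "tissue_profiles_b.tsv")
    corr = ortholog_expression_correlation(pairs, pa, pb)
    corr.to_csv(args.out / "ortholog_corr.tsv", sep="\t", index=False)
    if len(corr):
        print(f"ortholog expression correlation: mean Rs = {corr.rs.mean():.3f} "
              f"over {len(corr)} pairs")

    tf = read_tf_families(args.inputs / "tf_families.tsv")
    ious = []
    for p_ in pairs:
        a, b = tf.get(p_.gene_a, set()), tf.get(p_.gene_b, set())
        if a | b:
            ious.append({"gene_a": p_.gene_a, "gene_b": p_.gene_b,
                         "iou": tf_family_iou(a, b)})
    iou_df = pd.DataFrame(ious, columns=["gene_a", "gene_b", "iou"])
    iou_df.to_csv(args.out / "tf_iou.tsv", sep="\t", index=False)
    if len(iou_df):
        print(f"TF-family IoU of ortholog pairs: mean S = {iou_df.iou.mean():.3f}")

    track = read_bedgraph(args.inputs / "conservation.bedgraph")
    models = read_gff3(args.inputs / "models.gff3")
    score_rows = []
    for mod in models:
        group = ("coding" if mod.biotype == "coding"
                 else "conserved_lnc" if mod.gene_id in conserved
                 else "other_lnc")
        score_rows.append({
            "transcript_id": mod.transcript_id, "group": group,
            "score": conservation_score(mod.exons, mod.chrom, track),
        })
    scores = pd.DataFrame(score_rows)
    scores.to_csv(args.out / "conservation_scores.tsv", sep="\t", index=False)
    cs = scores[scores.group == "conserved_lnc"].score
    os_ = scores[scores.group == "other_lnc"].score
    if len(cs) and len(os_):
        d, p = compare_distributions(cs, os_)
        ks["phastcons_conserved_vs_other_lnc"] = {"D": d, "p": p}
        print(f"conservation score, conserved vs other lncRNA: "
              f"D={d:.3f}, p={p:.3g}")
    with open(args.out / "ks_tests.json", "w") as fh:
        json.dump(ks, fh, indent=2)


if __name__ == "__main__":
    main()
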