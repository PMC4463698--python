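#!/usr/bin/env python
"""Scan cher sequences for binding-site motifs and compute TSS distances.

Extracts each cher's genomic sequence, scans both strands with the
simulation's PWM (two-stage CSS/MSS filter at 0.9/0.9), and reports for
every hit the signed distance to the most proximal TSS of each assigned
gene.  Writes results/motif_hits.tsv and results/tfbs_tss_distances.tsv.
"""

import argparse
import dataclasses

import pandas as pd

from pycher.annotation import most_proximal_tss, read_gene_models_gff3, tss_distance
from pycher.cli import _chers_from_table
from pycher.motif_scan import fetch_cher_sequences, hits_to_table, load_pwm, scan_chers


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", default="results")
    parser.add_argument("--css-cutoff", type=float, default=0.9)
    parser.add_argument("--mss-cutoff", type=float, default=0.9)
    args = parser.parse_args()

    chers = _chers_from_table(f"{args.results}/chers.tsv")
    seqs = fetch_cher_sequences(f"{args.results}/sim/genome.fa", chers)
    pwm = load_pwm(f"{args.results}/sim/motif.jaspar", "jaspar",
                   css_cutoff=args.css_cutoff, mss_cutoff=args.mss_cutoff)
    hits = scan_chers([pwm], seqs)
    hits_to_table(hits).to_csv(f"{args.results}/motif_hits.tsv", sep="\t",
                               index=False, float_format="%.4f")

    with_hit = {h.seq_id for h in hits}
    print(f"{len(hits)} motif hits in {len(with_hit)}/{len(chers)} chers "
          f"({100 * len(with_hit) / len(chers):.1f}% of chers contain a TFBS)")

    # signed TSS distance for every (hit, assigned gene) pair
    assignments = pd.read_csv(f"{args.results}/cher_gene_assignments.tsv", sep="\t")
    genes = {g.gene_id: g for g in read_gene_models_gff3(f"{args.results}/sim/genes.gff3")}
    by_cher = {c.cher_id: c for c in chers}
    rows = []
    for h in hits:
        cher = by_cher[h.seq_id]
        absolute = cher.start + h.position - 1
        for gid in assignments.loc[assignments["cher_id"] == h.seq_id, "gene_id"]:
            gene = genes[gid]
            tss = most_proximal_tss(gene, absolute)
            dist = tss_distance(tss, cher.start, h.position - 1, gene.strand)
            rows.append((h.seq_id, gid, absolute, h.strand, tss, dist))
    table = pd.DataFrame(rows, columns=["cher_id", "gene_id", "tfbs_position",
                                        "hit_strand", "tss", "tss_distance"])
    table.to_csv(f"{args.results}/tfbs_tss_distances.tsv", sep="\t", index=False)
    if len(table):
        print(f"median |TSS distance| of {len(table)} site-gene pairs: "
              f"{int(table['tss_distance'].abs().median())} bp")
    print(f"wrote {args.results}/motif_hits.tsv and tfbs_tss_distances.tsv")


if __name__ == "__main__":
    main()
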