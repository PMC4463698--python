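#!/usr/bin/env python
"""Assign chers to target genes via the promoter rule.

A cher annotates a gene when it overlaps the 10-kb strand-aware window
upstream of any TSS, or the gene body itself.  Writes
results/cher_gene_assignments.tsv.
"""

import argparse

from pycher.annotation import assign_chers_to_genes, assignments_to_table, read_gene_models_gff3
from pycher.cli import _chers_from_table


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", default="results")
    args = parser.parse_args()

    chers = _chers_from_table(f"{args.results}/chers.tsv")
    genes = read_gene_models_gff3(f"{args.results}/sim/genes.gff3")
    assignments = assign_chers_to_genes(chers, genes)
    assignments_to_table(assignments).to_csv(
        f"{args.results}/cher_gene_assignments.tsv", sep="\t", index=False
    )

    genes_hit = {a.gene_id for a in assignments}
    upstream = sum(1 for a in assignments if a.relation == "upstream")
    print(f"{len(chers)} chers -> {len(genes_hit)} target genes "
          f"({upstream} upstream assignments, {len(assignments) - upstream} within-gene)")
    print(f"wrote {args.results}/cher_gene_assignments.tsv")


if __name__ == "__main__":
    main()
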