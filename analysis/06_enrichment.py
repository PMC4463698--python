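#!/usr/bin/env python
"""GO-style over-representation of differentially expressed target genes.

Intersects the cher target genes with the DE list, then tests every term
of the simulated ontology with the upper-tail hypergeometric test and
Benjamini-Hochberg FDR, separately for all DE targets and the up/down
subsets.  Writes results/enrichment_{all,up,down}.tsv and a DOT graph of
the significant sub-DAG.
"""

import argparse

import pandas as pd

from pycher.enrichment import (
    enrich,
    intersect_with_expression,
    propagate_annotations,
    read_annotations,
    read_term_graph,
    results_to_table,
    significant_subdag_dot,
)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", default="results")
    parser.add_argument("--min-k", type=int, default=2)
    args = parser.parse_args()
    sim = f"{args.results}/sim"

    graph = read_term_graph(f"{sim}/term_edges.tsv", f"{sim}/term_names.tsv")
    ann = propagate_annotations(graph, read_annotations(f"{sim}/annotations.tsv"))
    de = pd.read_csv(f"{sim}/de_genes.tsv", sep="\t")
    assignments = pd.read_csv(f"{args.results}/cher_gene_assignments.tsv", sep="\t")
    targets = set(assignments["gene_id"].astype(str))

    all_de, up, down = intersect_with_expression(targets, de)
    print(f"{len(targets)} target genes; {len(all_de)} differentially expressed "
          f"({len(up)} up, {len(down)} down)")

    reference = set(ann.propagated)
    for label, subset in (("all", all_de), ("up", up), ("down", down)):
        if not subset & reference:
            print(f"  [{label}] no annotated genes; skipped")
            continue
        results = enrich(subset, reference, ann, graph, min_k=args.min_k)
        results_to_table(results).to_csv(
            f"{args.results}/enrichment_{label}.tsv", sep="\t", index=False
        )
        if label == "all":
            with open(f"{args.results}/enrichment_dag.dot", "w") as fh:
                fh.write(significant_subdag_dot(graph, results))
        top = results[0]
        print(f"  [{label}] {len(results)} terms tested; top: {top.term_id} "
              f"(level {top.level}, {top.k}/{top.K} genes, expected {top.expected:.1f}, "
              f"p={top.p:.3g}, FDR={top.fdr:.3g})")
    print(f"wrote {args.results}/enrichment_*.tsv and enrichment_dag.dot")


if __name__ == "__main__":
    main()
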