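"""Over-representation analysis of target gene sets.

Gene sets (e.g. differentially expressed genes whose promoters carry an
enriched region) are tested term-by-term against a reference universe
with the upper-tail hypergeometric test, with Benjamini-Hochberg control
of the false discovery rate across all tested terms.  Ontology terms live
in a directed acyclic graph; gene annotations are propagated to all
ancestor terms before testing, and each term carries a depth ("level",
roots at level 1) so results can be reported at a fixed level of the
hierarchy.  Flat pathway collections reuse the same machinery with an
edgeless graph.

Only genes with at least one propagated annotation count toward the
universe size N and the sample size n, mirroring the usual "reference set
annotated to at least one category" convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TermGraph:
    """An acyclic term hierarchy with child -> parent edges."""

    graph: nx.DiGraph
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValidationError("term graph must be acyclic")

    @classmethod
    def from_edges(cls, edges, names: dict[str, str] | None = None, extra_terms=()) -> "TermGraph":
        g = nx.DiGraph()
        g.add_edges_from((child, parent) for child, parent in edges)
        g.add_nodes_from(extra_terms)
        if names:
            g.add_nodes_from(names)
        return cls(g, names or {})

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def ancestors(self, term: str) -> set[str]:
        # edges point child -> parent, so ancestors are the descendants in nx terms
        return set(nx.descendants(self.graph, term))


@dataclass
class AnnotationSet:
    """Direct gene -> term annotations plus their ancestor closure."""

    direct: dict[str, set]
    propagated: dict[str, set]
    n_skipped: int = 0


def read_term_graph(edges_path, names_path=None) -> TermGraph:
    """Edge list TSV (child_id, parent_id[, relation]) plus optional name TSV."""
    edges = pd.read_csv(edges_path, sep="\t")
    cols = list(edges.columns)
    if len(cols) < 2:
        raise ValidationError(f"{edges_path}: expected at least two columns")
    names = {}
    if names_path is not None:
        name_table = pd.read_csv(names_path, sep="\t")
        names = dict(zip(name_table.iloc[:, 0].astype(str), name_table.iloc[:, 1].astype(str)))
    pairs = zip(edges.iloc[:, 0].astype(str), edges.iloc[:, 1].astype(str))
    return TermGraph.from_edges(pairs, names)


def read_annotations(path) -> dict[str, set]:
    """GAF-like TSV (gene, term) -> gene -> set of term ids."""
    table = pd.read_csv(path, sep="\t")
    direct: dict[str, set] = {}
    for gene, term in zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)):
        direct.setdefault(gene, set()).add(term)
    return direct


def propagate_annotations(graph: TermGraph, direct: dict[str, set]) -> AnnotationSet:
    """Close each gene's annotations under the parent relation.

    Annotations to terms absent from the graph are skipped with a warning
    and counted in ``n_skipped``.
    """
    known = graph.terms
    closure_cache: dict[str, set] = {}
    propagated: dict[str, set] = {}
    clean_direct: dict[str, set] = {}
    skipped = 0
    for gene, terms in direct.items():
        kept = terms & known
        skipped += len(terms) - len(kept)
        if not kept:
            continue
        clean_direct[gene] = set(kept)
        full: set = set()
        for term in kept:
            if term not in closure_cache:
                closure_cache[term] = {term} | graph.ancestors(term)
            full |= closure_cache[term]
        propagated[gene] = full
    if skipped:
        logger.warning("propagate_annotations: skipped %d annotations to unknown terms", skipped)
    return AnnotationSet(direct=clean_direct, propagated=propagated, n_skipped=skipped)


def term_level(graph: TermGraph, term_id: str) -> int:
    """Depth of a term: shortest path from any root, with roots at level 1."""
    levels = term_levels(graph)
    if term_id not in levels:
        raise ValidationError(f"unknown term {term_id!r}")
    return levels[term_id]


def term_levels(graph: TermGraph) -> dict[str, int]:
    """Breadth-first levels for every term (roots = 1)."""
    reversed_graph = graph.graph.reverse(copy=False)  # parent -> child
    levels: dict[str, int] = {}
    frontier = sorted(graph.roots)
    for root in frontier:
        levels[root] = 1
    depth = 1
    while frontier:
        depth += 1
        nxt = []
        for node in frontier:
            for child in reversed_graph.successors(node):
                if child not in levels:
                    levels[child] = depth
                    nxt.append(child)
        frontier = nxt
    return levels


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail (inclusive) hypergeometric probability P(X >= k).

    X counts annotated genes in a sample of n drawn without replacement
    from N genes of which K carry the annotation.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValidationError(
            f"invalid hypergeometric configuration k={k}, K={K}, n={n}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, in the input order.

    q_(i) = min_{j >= i} (m p_(j) / j), clamped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    level: int | None
    K: int  # reference genes in term
    k: int  # target genes in term
    n: int  # annotated target genes
    N: int  # annotated reference genes
    expected: float  # n * K / N
    p: float
    fdr: float


def enrich(
    target_genes,
    reference_genes,
    annotations: AnnotationSet | dict,
    graph: TermGraph | None = None,
    min_k: int = 2,
    level_filter: int | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of target genes per term.

    Target genes absent from the reference are dropped (and logged); the
    universe N and sample n count only genes with at least one propagated
    annotation.  One test runs per term with K >= 1 and k >= ``min_k``;
    BH adjustment spans all tested terms jointly, before any level
    filtering.  With ``graph=None`` (flat collections, e.g. pathways) the
    annotations are used as-is and levels are undefined.
    """
    target = set(target_genes)
    reference = set(reference_genes)
    dropped = target - reference
    if dropped:
        logger.info("enrich: dropped %d target genes absent from the reference", len(dropped))
    target &= reference

    if isinstance(annotations, AnnotationSet):
        gene_terms = annotations.propagated
    else:
        gene_terms = {g: set(t) for g, t in annotations.items()}

    annotated_ref = {g for g in reference if gene_terms.get(g)}
    annotated_target = {g for g in target if gene_terms.get(g)}
    if not annotated_target:
        raise ValidationError("enrich: no target gene carries any annotation")
    N, n = len(annotated_ref), len(annotated_target)

    term_ref: dict[str, int] = {}
    term_hit: dict[str, int] = {}
    for gene in annotated_ref:
        in_target = gene in annotated_target
        for term in gene_terms[gene]:
            term_ref[term] = term_ref.get(term, 0) + 1
            if in_target:
                term_hit[term] = term_hit.get(term, 0) + 1

    levels = term_levels(graph) if graph is not None else {}
    tested = sorted(t for t, k in term_hit.items() if k >= min_k and term_ref[t] >= 1)
    if not tested:
        return []
    pvals = np.array([hypergeometric_test(term_hit[t], term_ref[t], n, N) for t in tested])
    fdrs = bh_adjust(pvals)
    results = []
    for t, p, fdr in zip(tested, pvals, fdrs):
        results.append(
            EnrichmentResult(
                term_id=t,
                term_name=(graph.names.get(t, t) if graph is not None else t),
                level=levels.get(t) if graph is not None else None,
                K=term_ref[t],
                k=term_hit[t],
                n=n,
                N=N,
                expected=n * term_ref[t] / N,
                p=float(p),
                fdr=float(fdr),
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    if level_filter is not None:
        results = [r for r in results if r.level == level_filter]
    return results


def intersect_with_expression(
    cher_target_genes,
    de_table: pd.DataFrame,
    fdr_max: float | None = None,
) -> tuple[set, set, set]:
    """Split cher target genes by differential-expression status.

    ``de_table`` needs columns ``gene`` and ``log2fc`` (and ``fdr`` when
    ``fdr_max`` is given).  Returns (all DE targets, up-regulated targets,
    down-regulated targets); set sizes are logged, not asserted.
    """
    targets = set(cher_target_genes)
    table = de_table
    if fdr_max is not None:
        table = table[table["fdr"] <= fdr_max]
    de_genes = set(table["gene"].astype(str))
    up = set(table.loc[table["log2fc"] > 0, "gene"].astype(str))
    down = set(table.loc[table["log2fc"] < 0, "gene"].astype(str))
    all_de, up_t, down_t = targets & de_genes, targets & up, targets & down
    logger.info(
        "intersect_with_expression: %d DE targets (%d up, %d down)",
        len(all_de), len(up_t), len(down_t),
    )
    return all_de, up_t, down_t


def results_to_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """TSV-ready table mirroring the usual GO report columns."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "level": [r.level for r in results],
            "reference_set": [r.K for r in results],
            "target_set": [r.k for r in results],
            "expected": [r.expected for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
        }
    )


def significant_subdag_dot(
    graph: TermGraph,
    results: list[EnrichmentResult],
    fdr_max: float = 0.05,
) -> str:
    """DOT export of significant terms and their ancestor paths to the roots."""
    significant = {r.term_id for r in results if r.fdr <= fdr_max}
    keep = set(significant)
    for term in significant:
        keep |= graph.ancestors(term)
    lines = ["digraph enrichment {", '  rankdir="BT";']
    for term in sorted(keep):
        label = graph.names.get(term, term).replace('"', "'")
        color = ' style=filled fillcolor="tomato"' if term in significant else ""
        lines.append(f'  "{term}" [label="{label}"{color}];')
    for child, parent in graph.graph.edges:
        if child in keep and parent in keep:
            lines.append(f'  "{child}" -> "{parent}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
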