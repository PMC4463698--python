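"""Promoter assignment of enriched regions and TSS/assay distance arithmetic.

A cher annotates a gene when it overlaps the gene's promoter, defined as
the 10 kb strand-aware window 5' of any transcription start site (TSS),
or when it lies within the gene body itself.  For binding sites found
inside a cher, the signed distance to the most proximal TSS is reported
(positive = site upstream of the TSS on the coding strand), and qPCR
validation assays are related to predicted sites through a simple signed
offset (assay midpoint minus predicted site position).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cher_calling import Cher
from .errors import ValidationError


@dataclass
class GeneModel:
    """A gene with one TSS per transcript and its genomic extent."""

    gene_id: str
    symbol: str
    chrom: str
    strand: int  # +1 / -1
    tss_list: list[int]
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in (+1, -1):
            raise ValidationError(f"{self.gene_id}: strand must be +1 or -1")
        if self.gene_start > self.gene_end:
            raise ValidationError(f"{self.gene_id}: gene_start > gene_end")
        if any(t < 1 for t in self.tss_list):
            raise ValidationError(f"{self.gene_id}: TSS positions must be >= 1")


@dataclass(frozen=True)
class CherGeneAssignment:
    cher_id: str
    gene_id: str
    relation: str  # "upstream" | "within_gene"
    tss_used: int


def read_gene_models_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene + transcript/mRNA features).

    The TSS of each transcript is its 5' end by strand; genes without
    annotated transcripts fall back to the gene's own 5' end.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        strand = +1 if g.strand == "+" else -1
        tss_list = []
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            tss_list.append(t.start if strand == +1 else t.end)
        if not tss_list:
            tss_list = [g.start if strand == +1 else g.end]
        symbol = (g.attributes.get("Name") or g.attributes.get("gene_name") or [g.id])[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                symbol=symbol,
                chrom=g.seqid,
                strand=strand,
                tss_list=sorted(set(tss_list)),
                gene_start=g.start,
                gene_end=g.end,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.gene_start, g.gene_id))
    return genes


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def promoter_window(tss: int, strand: int, upstream_bp: int = 10000) -> tuple[int, int]:
    """The strand-aware upstream window 5' of a TSS (TSS base excluded)."""
    if strand == +1:
        return max(1, tss - upstream_bp), tss - 1
    return tss + 1, tss + upstream_bp


def assign_chers_to_genes(
    chers: list[Cher],
    genes: list[GeneModel],
    upstream_bp: int = 10000,
) -> list[CherGeneAssignment]:
    """Assign each cher to every gene whose promoter or body it overlaps.

    One record per (cher, gene) pair; when both the gene body and an
    upstream window overlap, the relation is recorded as within_gene.
    A cher may annotate several genes.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for cher in sorted(chers, key=lambda c: (c.chrom, c.start)):
        mid = (cher.start + cher.end) // 2
        for gene in by_chrom.get(cher.chrom, []):
            if _overlaps(cher.start, cher.end, gene.gene_start, gene.gene_end):
                out.append(
                    CherGeneAssignment(
                        cher.cher_id, gene.gene_id, "within_gene",
                        most_proximal_tss(gene, mid),
                    )
                )
                continue
            hit_tss = [
                tss for tss in gene.tss_list
                if _overlaps(cher.start, cher.end, *promoter_window(tss, gene.strand, upstream_bp))
            ]
            if hit_tss:
                tss_used = min(hit_tss, key=lambda t: (abs(t - mid), t))
                out.append(CherGeneAssignment(cher.cher_id, gene.gene_id, "upstream", tss_used))
    return out


def most_proximal_tss(gene: GeneModel, reference_point: int) -> int:
    """The gene's TSS nearest the reference point; ties go to the smaller coordinate."""
    if not gene.tss_list:
        raise ValidationError(f"{gene.gene_id}: empty tss_list")
    return min(gene.tss_list, key=lambda t: (abs(t - reference_point), t))


def tss_distance(
    tss: int,
    cher_start: int,
    tfbs_offset: int,
    strand: int,
    convention: str = "signed_distance",
) -> int:
    """Signed bp distance between a TSS and a binding site inside a cher.

    The site's absolute position is cher_start + tfbs_offset.  The default
    convention returns (TSS - absolute site position) x strand, so a
    positive value means the site lies upstream of the TSS on the coding
    strand.  ``convention="literal"`` instead evaluates
    (TSS - cher_start + tfbs_offset) x strand, kept for comparison.
    """
    if tfbs_offset < 0:
        raise ValidationError("tfbs_offset must be >= 0")
    if strand not in (+1, -1):
        raise ValidationError("strand must be +1 or -1")
    if convention == "signed_distance":
        return (tss - (cher_start + tfbs_offset)) * strand
    if convention == "literal":
        return (tss - cher_start + tfbs_offset) * strand
    raise ValidationError(f"unknown convention {convention!r}")


def tfbs_assay_offset(tfbs_position: int, assay_position: int) -> int:
    """Signed offset from a predicted binding site to a qPCR assay midpoint.

    Defined as assay_position - tfbs_position (negative when the assay
    amplicon midpoint lies 5' of the predicted site on the plus strand).
    """
    return int(assay_position) - int(tfbs_position)


def load_qpcr_assays() -> pd.DataFrame:
    """Published qPCR validation assays bundled with the package.

    Columns: tf, gene, chrom, cher_start, cher_end, max_peak, score,
    tfbs_position, assay_id, assay_position.  The ``delta`` offset is not
    stored; compute it with :func:`tfbs_assay_offset`.
    """
    with resources.files("pycher.data").joinpath("qpcr_assays.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def assignments_to_table(assignments: list[CherGeneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cher_id": [a.cher_id for a in assignments],
            "gene_id": [a.gene_id for a in assignments],
            "relation": [a.relation for a in assignments],
            "tss_used": [a.tss_used for a in assignments],
        }
    )
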