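"""Annotation of variants and deletion calls against gene models.

Distances are strand-aware and signed: negative upstream of the gene's
transcriptional start (the promoter side), positive downstream of its end,
zero on overlap.  The promoter is a fixed window upstream of the
strand-aware gene start — a proxy for distance to the start codon that does
not require CDS-resolved annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .mm_filter import FilteredVariant
from .sv_scan import DeletionCall
from .vcfio import GeneFeature

log = logging.getLogger(__name__)


@dataclass
class Annotation:
    target_chrom: str
    target_start: int
    target_end: int
    gene_id: str
    distance: int  # signed, strand-aware: upstream < 0 < downstream; 0 = overlap
    region: str  # coding | intron | promoter | intergenic
    promoter_bp: int


def _signed_distance(start: int, end: int, gene: GeneFeature) -> int:
    """Strand-aware signed distance from an interval to a gene body."""
    if end >= gene.start and start <= gene.end:
        return 0
    if end < gene.start:
        gap = gene.start - end  # interval left of the gene
        return -gap if gene.strand == "+" else gap
    gap = start - gene.end  # interval right of the gene
    return gap if gene.strand == "+" else -gap


def _classify(
    start: int, end: int, gene: GeneFeature, distance: int, promoter_bp: int,
    exons: dict[str, list[tuple[int, int]]] | None,
) -> str:
    if distance == 0:
        if exons and gene.gene_id in exons:
            hits_exon = any(end >= s and start <= e for s, e in exons[gene.gene_id])
            return "coding" if hits_exon else "intron"
        return "coding"  # gene body approximated as coding without exon models
    if -promoter_bp <= distance < 0:
        return "promoter"
    return "intergenic"


def annotate_nearest_gene(
    target: tuple[str, int] | tuple[str, int, int],
    genes: Sequence[GeneFeature],
    promoter_bp: int = 2000,
    exons: dict[str, list[tuple[int, int]]] | None = None,
) -> Annotation:
    """Annotate a site (chrom, pos) or interval (chrom, start, end).

    The nearest gene minimizes the unsigned gap to the gene body; ties are
    broken by the lexicographically smaller gene id (logged).
    """
    if promoter_bp < 0:
        raise ValueError("promoter_bp must be >= 0")
    chrom = target[0]
    start = target[1]
    end = target[2] if len(target) == 3 else target[1]
    on_chrom = [g for g in genes if g.chrom == chrom]
    if not on_chrom:
        raise ValueError(f"no genes on chromosome {chrom!r}")
    ranked = sorted(
        on_chrom, key=lambda g: (abs(_signed_distance(start, end, g)), g.gene_id)
    )
    best = ranked[0]
    dist0 = abs(_signed_distance(start, end, best))
    ties = [g for g in ranked[1:] if abs(_signed_distance(start, end, g)) == dist0]
    if ties:
        log.info("nearest-gene tie at %d bp broken toward %s", dist0, best.gene_id)
    distance = _signed_distance(start, end, best)
    region = _classify(start, end, best, distance, promoter_bp, exons)
    return Annotation(
        target_chrom=chrom, target_start=start, target_end=end,
        gene_id=best.gene_id, distance=distance, region=region,
        promoter_bp=promoter_bp,
    )


def _overlap_or_promoter(start: int, end: int, gene: GeneFeature, promoter_bp: int,
                         exons=None) -> str | None:
    d = _signed_distance(start, end, gene)
    if d == 0 or -promoter_bp <= d < 0:
        return _classify(start, end, gene, d, promoter_bp, exons)
    return None


def candidate_gene_report(
    filtered_variants: Sequence[FilteredVariant],
    deletions: Sequence[DeletionCall],
    gene_list: Sequence[GeneFeature],
    annotated_genes: Sequence[GeneFeature] | None = None,
    promoter_bp: int = 2000,
    exons: dict[str, list[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Per-gene tally of overlapping variants and deletions, with a verdict.

    For each candidate gene, counts filtered variants by region class
    (coding / intron / promoter) and deletion calls hitting the gene body or
    promoter, then renders a verdict such as "promoter deletion" or
    "no variant".  Output order follows ``gene_list`` sorted by gene id, so
    the report is invariant under input order.
    """
    known_ids = {g.gene_id for g in (annotated_genes or gene_list)}
    rows = []
    for gene in sorted(gene_list, key=lambda g: g.gene_id):
        if gene.gene_id not in known_ids:
            rows.append({"gene_id": gene.gene_id, "coding": 0, "intron": 0,
                         "promoter": 0, "deletions": 0, "verdict": "not found"})
            continue
        counts = {"coding": 0, "intron": 0, "promoter": 0}
        for fv in filtered_variants:
            if fv.chrom != gene.chrom:
                continue
            cls = _overlap_or_promoter(fv.pos, fv.pos, gene, promoter_bp, exons)
            if cls in counts:
                counts[cls] += 1
        n_del = 0
        del_classes = []
        for dc in deletions:
            if dc.chrom != gene.chrom:
                continue
            cls = _overlap_or_promoter(dc.start, dc.end, gene, promoter_bp, exons)
            if cls is not None:
                n_del += 1
                del_classes.append(cls)
        if n_del and all(c == "promoter" for c in del_classes):
            verdict = "promoter deletion"
        elif n_del:
            verdict = "deletion in gene body"
        elif counts["coding"]:
            verdict = "coding variant"
        elif counts["intron"]:
            verdict = "intronic variant"
        elif counts["promoter"]:
            verdict = "promoter variant"
        else:
            verdict = "no variant"
        rows.append({"gene_id": gene.gene_id, **counts, "deletions": n_del,
                     "verdict": verdict})
    return pd.DataFrame(rows)
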