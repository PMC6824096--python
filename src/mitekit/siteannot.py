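"""Genomic context of each insertion: exon / UTR / intron / gene-proximal /
TE-adjacent / intergenic, with half-open distance arithmetic and a fixed
precedence order."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .genes import GeneModel

CONTEXT_PRECEDENCE = ("exon", "UTR", "intron", "gene_proximal",
                      "TE_adjacent", "intergenic")


@dataclass
class SiteContext:
    insertion_id: str
    context_class: str
    feature_id: str = ""
    distance: int = 0
    feature_strand: str = "."


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0])


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Half-open gap between spans; 0 when overlapping or abutting."""
    if _overlap(a, b) > 0:
        return 0
    return b[0] - a[1] if a[1] <= b[0] else a[0] - b[1]


def annotate_site(insertion_id: str, chrom: str, span: tuple[int, int],
                  genes: list[GeneModel], tes: pd.DataFrame | None = None,
                  proximity_window: int = 500,
                  exclude_self: bool = True) -> SiteContext:
    """Classify one insertion span against gene models and a TE annotation.

    Precedence: exon > UTR > intron > gene_proximal > TE_adjacent >
    intergenic. ``distance`` is the half-open gap to the nearest feature
    edge (0 when inside). A TE annotation row identical to the insertion
    span is ignored when ``exclude_self`` (the insertion usually appears in
    its own element BED). Features abutting the span (gap 0, no overlap)
    are treated as proximal at distance 0.
    """
    start, end = span
    if start >= end:
        raise ValueError("empty insertion span")

    chrom_genes = [g for g in genes if g.chrom == chrom]
    if genes and not chrom_genes and all(g.chrom != chrom for g in genes):
        warnings.warn(f"chromosome {chrom!r} absent from gene annotation")

    # inside-gene classes
    for g in chrom_genes:
        if _overlap(span, (g.start, g.end)) <= 0:
            continue
        if any(_overlap(span, c) > 0 for c in g.cds):
            return SiteContext(insertion_id, "exon", g.gene_id, 0, g.strand)
        if any(_overlap(span, u) > 0 for u in g.utrs()):
            return SiteContext(insertion_id, "UTR", g.gene_id, 0, g.strand)
        return SiteContext(insertion_id, "intron", g.gene_id, 0, g.strand)

    # gene-proximal
    best = None
    for g in chrom_genes:
        d = _gap(span, (g.start, g.end))
        if d <= proximity_window and (best is None or d < best[0]):
            best = (d, g)
    if best is not None:
        d, g = best
        return SiteContext(insertion_id, "gene_proximal", g.gene_id, d, g.strand)

    # TE-adjacent
    if tes is not None and len(tes):
        sub = tes[tes["chrom"] == chrom]
        best_te = None
        for row in sub.itertuples(index=False):
            te_span = (int(row.start), int(row.end))
            if exclude_self and te_span == span:
                continue
            d = _gap(span, te_span)
            if d <= proximity_window and (best_te is None or d < best_te[0]):
                name = getattr(row, "name", "") or ""
                strand = getattr(row, "strand", ".") or "."
                best_te = (d, name, strand)
        if best_te is not None:
            d, name, strand = best_te
            return SiteContext(insertion_id, "TE_adjacent", name, d, strand)

    return SiteContext(insertion_id, "intergenic")


def annotate_sites(hits: pd.DataFrame, genes: list[GeneModel],
                   tes: pd.DataFrame | None = None,
                   proximity_window: int = 500) -> pd.DataFrame:
    """Vector wrapper over `annotate_site` for a hits table with
    hit_id/chrom/start/end columns."""
    rows = []
    for h in hits.itertuples(index=False):
        ctx = annotate_site(h.hit_id, h.chrom, (int(h.start), int(h.end)),
                            genes, tes, proximity_window)
        rows.append({"insertion_id": ctx.insertion_id,
                     "class": ctx.context_class,
                     "feature": ctx.feature_id,
                     "distance": ctx.distance})
    return pd.DataFrame(rows)
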