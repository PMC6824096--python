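"""Gene models and GFF3 interchange.

Internally all coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted on read and write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

Span = tuple[int, int]


@dataclass
class GeneModel:
    """A protein-coding gene: ordered exon spans with a CDS subset.

    Exons must be non-overlapping and sorted; CDS spans must lie inside
    exons. Coordinates are 0-based half-open on the chromosome.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Span] = field(default_factory=list)
    cds: list[Span] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"{self.gene_id}: CDS segment outside exons")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def utrs(self) -> list[Span]:
        """Exonic regions not covered by CDS."""
        out = []
        for es, ee in self.exons:
            cursor = es
            for cs, ce in self.cds:
                if ce <= es or cs >= ee:
                    continue
                if cs > cursor:
                    out.append((cursor, cs))
                cursor = max(cursor, ce)
            if cursor < ee:
                out.append((cursor, ee))
        return out


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive."""
    lines = ["##gff-version 3"]
    for g in genes:
        gid, mid = g.gene_id, f"{g.gene_id}.1"
        lines.append("\t".join([
            g.chrom, "mitekit", "gene", str(g.start + 1), str(g.end), ".",
            g.strand, ".", f"ID={gid}"]))
        lines.append("\t".join([
            g.chrom, "mitekit", "mRNA", str(g.start + 1), str(g.end), ".",
            g.strand, ".", f"ID={mid};Parent={gid}"]))
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append("\t".join([
                g.chrom, "mitekit", "exon", str(s + 1), str(e), ".",
                g.strand, ".", f"ID={mid}.exon{i};Parent={mid}"]))
        for i, (s, e) in enumerate(g.cds, 1):
            lines.append("\t".join([
                g.chrom, "mitekit", "CDS", str(s + 1), str(e), ".",
                g.strand, "0", f"ID={mid}.cds;Parent={mid}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon/CDS) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, force=True)
    genes = []
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons += [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds += [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        genes.append(GeneModel(gene_id=gene.id, chrom=gene.seqid,
                               strand=gene.strand, exons=exons, cds=cds))
    return genes


def shift_for_insertion(gene: GeneModel, insert_at: int, added: int) -> GeneModel:
    """Return the gene model after `added` bases are inserted at `insert_at`.

    A feature boundary at or beyond the insertion point moves right; a span
    containing the point stretches.
    """

    def shift(span: Span) -> Span:
        s, e = span
        if s >= insert_at:
            return (s + added, e + added)
        if e > insert_at:
            return (s, e + added)
        return span

    return GeneModel(gene_id=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                     exons=[shift(x) for x in gene.exons],
                     cds=[shift(x) for x in gene.cds])
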