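"""Seed-and-extend retrieval of element copies from genome sequences.

A consensus query is searched against both strands of every chromosome:
exact word matches seed candidate regions, each region is aligned locally
(affine gaps) against the full query, and alignments are kept when their
Karlin-Altschul e-value passes the threshold. Overlapping hits at one locus
are merged to the best-scoring record, full-length status is called from
the unaligned query length at each end, and flanking sequence is extracted
for target-site characterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from Bio import Align

from ._util import check_alphabet, revcomp


@dataclass(frozen=True)
class SearchParams:
    """Retrieval thresholds and alignment scoring.

    ``end_mismatch_tol`` is the permitted *unaligned* query length at each
    end when calling a hit full-length (not a mismatch count).
    """

    evalue_max: float = 1e-3
    end_mismatch_tol: int = 20
    flank_length: int = 1000
    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    ka_lambda: float = 0.625
    ka_k: float = 0.41
    merge_overlap_fraction: float = 0.5

    def validate(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.end_mismatch_tol < 0:
            raise ValueError("end_mismatch_tol must be >= 0")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")


@dataclass
class InsertionHit:
    """One retrieved genomic copy of the query element."""

    hit_id: str
    chromosome: str
    start: int  # 0-based half-open genomic span
    end: int
    strand: str
    raw_score: float
    bit_score: float
    evalue: float
    query_start: int  # coverage span in original query orientation
    query_end: int
    identity: float  # percent of alignment columns (gaps count as mismatch)
    is_full_length: bool = False
    upstream_flank: str = ""
    downstream_flank: str = ""
    upstream_truncated: bool = False
    downstream_truncated: bool = False


def evalue(raw_score: float, query_len: int, genome_len: int,
           params: SearchParams = SearchParams()) -> float:
    """Karlin-Altschul expect value E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or genome_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return params.ka_k * query_len * genome_len * math.exp(
        -params.ka_lambda * raw_score)


def bit_score(raw_score: float, params: SearchParams = SearchParams()) -> float:
    return (params.ka_lambda * raw_score - math.log(params.ka_k)) / math.log(2)


def call_full_length(hit: InsertionHit, query_len: int,
                     end_mismatch_tol: int = 20) -> bool:
    """Full-length iff the unaligned query length at each end is within tolerance."""
    return (hit.query_start <= end_mismatch_tol
            and query_len - hit.query_end <= end_mismatch_tol)


def extract_flanks(chrom_seq: str, start: int, end: int,
                   flank_length: int = 1000) -> tuple[str, str, bool, bool]:
    """Genomic flanks around [start, end), clipped (never padded) at contig ends.

    Returns (upstream, downstream, upstream_truncated, downstream_truncated);
    both flanks are reported in genome-strand orientation.
    """
    if not 0 <= start < end <= len(chrom_seq):
        raise IndexError(f"span [{start}, {end}) outside contig of "
                         f"length {len(chrom_seq)}")
    up_from = max(0, start - flank_length)
    upstream = chrom_seq[up_from:start]
    downstream = chrom_seq[end:end + flank_length]
    return (upstream, downstream,
            len(upstream) < flank_length, len(downstream) < flank_length)


def _aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _candidate_regions(query: str, seq: str, word: int, margin: int
                       ) -> list[tuple[int, int]]:
    """Cluster exact word-match seed positions into candidate windows."""
    if len(seq) < word or len(query) < word:
        return []
    qwords = {query[i:i + word] for i in range(len(query) - word + 1)}
    positions = [i for i in range(len(seq) - word + 1) if seq[i:i + word] in qwords]
    regions = []
    for pos in positions:
        if regions and pos <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], pos + word)
        else:
            regions.append([pos, pos + word])
    merged: list[tuple[int, int]] = []
    for s, e in regions:
        s, e = max(0, s - margin), min(len(seq), e + margin)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _alignment_stats(alignment) -> tuple[int, int, int, int, float]:
    """(t_start, t_end, q_start, q_end, identity%) from a local alignment."""
    tblocks, qblocks = alignment.aligned
    t_start, t_end = int(tblocks[0][0]), int(tblocks[-1][1])
    q_start, q_end = int(qblocks[0][0]), int(qblocks[-1][1])
    target, query = alignment.target, alignment.query
    matches = columns = 0
    prev_t, prev_q = None, None
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)  # gap columns
        for a, b in zip(target[ts:te], query[qs:qe]):
            columns += 1
            matches += a == b
        prev_t, prev_q = te, qe
    identity = 100.0 * matches / columns if columns else 0.0
    return t_start, t_end, q_start, q_end, identity


def search_copies(query: str, genome: dict[str, str] | Iterable[tuple[str, str]],
                  params: SearchParams = SearchParams()) -> list[InsertionHit]:
    """Retrieve all significant copies of `query` from `genome`, both strands.

    Hits overlapping more than ``merge_overlap_fraction`` of the shorter
    span are merged to the best-scoring one (one insertion locus = one
    record); output is sorted by (chromosome, start).
    """
    params.validate()
    check_alphabet(query, "query")
    if len(query) < params.word_size:
        raise ValueError("query shorter than word_size")
    if len(set(query)) == 1:
        raise ValueError("degenerate homopolymer query")
    if isinstance(genome, dict):
        records = list(genome.items())
    else:
        records = list(genome)
    total_len = sum(len(s) for _, s in records)
    if total_len == 0:
        return []

    aligner = _aligner(params)
    qlen = len(query)
    raw_hits: list[InsertionHit] = []
    for chrom, seq in records:
        for strand in "+-":
            q = query if strand == "+" else revcomp(query)
            for rs, re_ in _candidate_regions(q, seq, params.word_size, qlen):
                window = seq[rs:re_]
                alignments = aligner.align(window, q)
                try:
                    aln = alignments[0]
                except IndexError:
                    continue
                score = float(aln.score)
                e = evalue(score, qlen, total_len, params)
                if e > params.evalue_max:
                    continue
                ts, te, qs, qe, ident = _alignment_stats(aln)
                # glocal projection: report the full-query span so hit
                # boundaries coincide with the element ends even when a
                # terminal mismatch was trimmed by the local alignment
                g_start = max(0, rs + ts - qs)
                g_end = min(len(seq), rs + te + (qlen - qe))
                if strand == "-":
                    qs, qe = qlen - qe, qlen - qs
                raw_hits.append(InsertionHit(
                    hit_id="", chromosome=chrom, start=g_start, end=g_end,
                    strand=strand, raw_score=score,
                    bit_score=bit_score(score, params), evalue=e,
                    query_start=qs, query_end=qe, identity=ident))

    hits = _merge_hits(raw_hits, params)
    hits.sort(key=lambda h: (h.chromosome, h.start))
    for i, h in enumerate(hits):
        h.hit_id = f"hit{i + 1:03d}"
        h.is_full_length = call_full_length(h, qlen, params.end_mismatch_tol)
        chrom_seq = dict(records)[h.chromosome]
        (h.upstream_flank, h.downstream_flank,
         h.upstream_truncated, h.downstream_truncated) = extract_flanks(
            chrom_seq, h.start, h.end, params.flank_length)
    return hits


def _merge_hits(hits: list[InsertionHit], params: SearchParams
                ) -> list[InsertionHit]:
    kept: list[InsertionHit] = []
    for h in sorted(hits, key=lambda h: -h.raw_score):
        redundant = False
        for k in kept:
            if k.chromosome != h.chromosome:
                continue
            overlap = min(k.end, h.end) - max(k.start, h.start)
            shorter = min(k.end - k.start, h.end - h.start)
            if shorter > 0 and overlap / shorter > params.merge_overlap_fraction:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def element_oriented_flanks(hit: InsertionHit) -> tuple[str, str]:
    """Flanks rotated into the element's own 5'->3' orientation."""
    if hit.strand == "+":
        return hit.upstream_flank, hit.downstream_flank
    return revcomp(hit.downstream_flank), revcomp(hit.upstream_flank)


def hits_to_dataframe(hits: list[InsertionHit]):
    import pandas as pd
    return pd.DataFrame([{
        "hit_id": h.hit_id, "chrom": h.chromosome, "start": h.start,
        "end": h.end, "strand": h.strand, "raw_score": h.raw_score,
        "bit_score": round(h.bit_score, 2), "evalue": h.evalue,
        "query_start": h.query_start, "query_end": h.query_end,
        "identity": round(h.identity, 2), "is_full_length": h.is_full_length,
    } for h in hits])
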