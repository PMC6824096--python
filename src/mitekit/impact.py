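"""Consequences of an exonic insertion: splice-aware transcripts, ORF
truncation, and relative-expression statistics.

An element that lands in an exon is retained in the mature mRNA together
with exactly one extra copy of the target-site duplication, so the
transcript grows by element + TSD; translation of the insertion allele is
compared with the reference allele to report premature termination and the
shortened protein. Expression is quantified with the comparative 2^-ddCT
method against an endogenous control and a calibrator accession, and
group differences are tested with one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._util import revcomp
from .genes import GeneModel, shift_for_insertion
from .synthdata import plant_insertion


@dataclass
class Transcript:
    """A spliced mRNA with CDS geometry and, optionally, the insertion span
    it carries (transcript coordinates, half-open)."""

    seq: str
    cds_start: int
    cds_end: int
    insertion_span: tuple[int, int] | None = None


@dataclass
class OrfReport:
    allele: str
    transcript_length: int
    premature_stop: bool
    stop_position_in_insertion: int | None  # 1-based nt within the insertion
    protein_length: int  # insertion allele (or the only allele)
    protein_length_reference: int | None
    lost_cds_fraction: float
    non_stop: bool = False


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float = 0.0

    @property
    def efficiency(self) -> float:
        return primer_efficiency(self.slope)


def _genomic_to_transcript(gene: GeneModel, gpos: int) -> int:
    """Map a plus-strand genomic offset inside an exon to transcript coords."""
    offset = 0
    for s, e in gene.exons:
        if s <= gpos <= e:
            return offset + (gpos - s)
        offset += e - s
    raise ValueError(f"position {gpos} not exonic")


def splice_transcript(gene: GeneModel, chrom_seq: str,
                      insertion: tuple[int, str, int] | None = None
                      ) -> Transcript:
    """Concatenate exon sequences into the mature mRNA.

    ``insertion=(position, element, tsd_length)`` models the with-insertion
    allele: the element is planted at `position` (TSD start, genomic
    coordinates) which must lie strictly inside one exon, and the retained
    insertion (element + one extra TSD copy) appears in the mRNA.
    Minus-strand genes are reverse-complemented.
    """
    if insertion is not None:
        position, element, tsd_length = insertion
        insert_at = position + tsd_length
        inside = any(s < insert_at < e for s, e in gene.exons)
        if not inside:
            raise ValueError("insertion does not fall strictly inside an exon "
                             "(junction-spanning insertions are unsupported)")
        chrom_seq, _ = plant_insertion(chrom_seq, element, position, tsd_length)
        added = len(element) + tsd_length
        span_start_g = insert_at
        gene = shift_for_insertion(gene, insert_at, added)

    mrna = "".join(chrom_seq[s:e] for s, e in gene.exons)
    cds_start = _genomic_to_transcript(gene, gene.cds[0][0])
    cds_end = cds_start + gene.cds_length
    span = None
    if insertion is not None:
        t0 = _genomic_to_transcript(gene, span_start_g)
        span = (t0, t0 + added)
    if gene.strand == "-":
        n = len(mrna)
        mrna = revcomp(mrna)
        cds_start, cds_end = n - cds_end, n - cds_start
        if span:
            span = (n - span[1], n - span[0])
    return Transcript(seq=mrna, cds_start=cds_start, cds_end=cds_end,
                      insertion_span=span)


def orf_report(mrna: str, cds_start_offset: int,
               insertion_span: tuple[int, int] | None = None,
               tsd_length: int = 0, allele: str = "insertion") -> OrfReport:
    """Translate from the CDS start and report the first in-frame stop.

    When the stop falls within the insertion span, its position is given
    1-based within the inserted nucleotides (the element occupies the
    first ``span length - tsd_length`` of them). The reference allele is
    reconstructed by excising the insertion span, so both protein lengths
    are reported.
    """
    if not 0 <= cds_start_offset < len(mrna):
        raise ValueError("cds_start_offset outside transcript")

    def translate_len(seq: str, start: int) -> tuple[int | None, int]:
        """(stop codon start offset or None, protein length in aa)."""
        prot = str(Seq(seq[start:start + (len(seq) - start) // 3 * 3]).translate())
        idx = prot.find("*")
        if idx < 0:
            return None, len(prot)
        return start + 3 * idx, idx

    stop_at, aa = translate_len(mrna, cds_start_offset)
    non_stop = stop_at is None

    ref_aa = None
    premature = False
    lost = 0.0
    stop_in_insertion = None
    if insertion_span is not None:
        a, b = insertion_span
        ref_mrna = mrna[:a] + mrna[b:]
        ref_start = cds_start_offset if cds_start_offset <= a else \
            cds_start_offset - (b - a)
        _, ref_aa = translate_len(ref_mrna, ref_start)
        premature = aa < ref_aa
        lost = 1.0 - aa / ref_aa if ref_aa else 0.0
        if stop_at is not None and a <= stop_at + 2 < b:
            # report the 1-based position of the stop codon's last base
            stop_in_insertion = (stop_at + 2) - a + 1
    return OrfReport(allele=allele, transcript_length=len(mrna),
                     premature_stop=premature,
                     stop_position_in_insertion=stop_in_insertion,
                     protein_length=aa, protein_length_reference=ref_aa,
                     lost_cds_fraction=lost, non_stop=non_stop)


def primer_efficiency(slope: float) -> float:
    """qPCR amplification efficiency, percent: ((10^(-1/slope)) - 1) x 100.

    A slope of -3.3219 (perfect doubling per cycle) gives 100%.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def relative_expression(table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Comparative 2^-ddCT relative quantities.

    `table` needs accession, ct_target, ct_control columns. RQ = 2^-(
    dCT_sample - dCT_calibrator) with dCT = CT_target - CT_control; the
    calibrator's RQ is exactly 1. Rows with missing CTs are dropped with a
    warning.
    """
    df = table.copy()
    missing = df["ct_target"].isna() | df["ct_control"].isna()
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} rows with missing CT")
        df = df[~missing]
    if calibrator not in set(df["accession"]):
        raise ValueError(f"calibrator {calibrator!r} not present")
    dct = df["ct_target"] - df["ct_control"]
    dct_cal = float(dct[df["accession"] == calibrator].iloc[0])
    df = df.assign(dct=dct, rq=np.exp2(-(dct - dct_cal)))
    return df


def anova_tukey(rq: pd.Series, groups: pd.Series, alpha: float = 0.05
                ) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across groups plus Tukey HSD pairwise contrasts.

    Groups with a single observation are excluded with a warning.
    Returns (F, p, tukey table with reject flags at `alpha`).
    """
    df = pd.DataFrame({"rq": rq, "group": groups}).dropna()
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding single-observation groups: {small}")
        df = df[~df["group"].isin(small)]
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    samples = [g["rq"].to_numpy() for _, g in df.groupby("group")]
    F, p = stats.f_oneway(*samples)
    tk = pairwise_tukeyhsd(df["rq"].to_numpy(), df["group"].to_numpy(),
                           alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=[str(c) for c in tk.summary().data[0]])
    return float(F), float(p), tukey
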