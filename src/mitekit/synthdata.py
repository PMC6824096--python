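"""Synthetic genomes, accession panels and qPCR CT tables with known ground truth.

The generator emulates the study system every downstream stage expects: a
low-copy ~307-bp miniature element planted with 9-bp target-site
duplications (TSDs) into random multi-chromosome backgrounds, one copy
inside exon 6 of a 7-exon gene, population-structured presence/absence of
each insertion across accession panels, and CT tables with group-level
expression shifts. Every planted feature is recorded in a truth table so
recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._util import (STOP_CODONS, check_alphabet, force_substitutions,
                    mutate_substitutions, random_seq, revcomp)
from .genes import GeneModel, shift_for_insertion, write_gff3

#: the 9-bp duplicated target site observed at the index (exon-6) insertion
INDEX_TARGET_SITE = "CCAAGAACT"

#: default wild-emmer population labels and accession-id prefixes
DEFAULT_POPULATIONS = ("MtHermon", "Amiad", "Tabgha", "Jaba", "MtAmasa")
_POP_PREFIX = {"MtHermon": "H", "Amiad": "A", "Tabgha": "T", "Jaba": "J",
               "MtAmasa": "M"}

TRUTH_COLUMNS = ["copy_id", "chromosome", "insert_position", "strand",
                 "tsd_sequence", "tsd_intact", "locus_id", "accession_id",
                 "present", "element_start", "element_end"]


@dataclass(frozen=True)
class GenePlan:
    """Layout of the 7-exon model gene hosting the exonic insertion.

    CDS spans exons 1-7 (843 nt, 280 aa); the element lands in exon 6 at
    CDS offset `insertion_cds_offset`, immediately 3' of the 9-bp target
    site written into the CDS. The long 3' UTR leaves room for an
    exon-5/exon-7 amplicon spanning the insertion.
    """

    utr5: int = 60
    utr3: int = 300
    cds_exon_lengths: tuple[int, ...] = (120, 120, 120, 120, 120, 150, 93)
    intron_length: int = 200
    insertion_cds_offset: int = 709
    target_exon: int = 6  # 1-based
    target_site: str = INDEX_TARGET_SITE

    @property
    def cds_length(self) -> int:
        return sum(self.cds_exon_lengths)

    @property
    def target_site_cds_offset(self) -> int:
        return self.insertion_cds_offset - len(self.target_site)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; a fixed seed makes output byte-identical."""

    n_chromosomes: int = 2
    chrom_length: int = 50_000
    element_length: int = 307
    tsd_length: int = 9
    copies_per_genome: int = 12
    copy_divergence: float = 0.03
    tsd_decay_fraction: float = 0.5
    n_populations: int = 5
    accessions_per_population: int = 9
    presence_profile: tuple[tuple[float, ...], ...] | None = None
    gene_plan: GenePlan = field(default_factory=GenePlan)
    seed: int = 0

    def validate(self) -> None:
        if self.element_length < self.tsd_length + 3:
            raise ValueError("element_length must be >= tsd_length + 3")
        for name in ("copy_divergence", "tsd_decay_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.tsd_decay_fraction > 0 and self.tsd_length < 3:
            raise ValueError("TSD decay needs tsd_length >= 3")
        if min(self.n_chromosomes, self.chrom_length, self.copies_per_genome,
               self.n_populations, self.accessions_per_population) < 1:
            raise ValueError("counts and lengths must be positive")
        if self.presence_profile is not None:
            for row in self.presence_profile:
                if len(row) != self.n_populations:
                    raise ValueError("presence_profile rows must match n_populations")
                if not all(0.0 <= p <= 1.0 for p in row):
                    raise ValueError("presence probabilities must be in [0, 1]")


@dataclass
class ReferenceSet:
    """A simulated reference genome with its annotation and ground truth."""

    genome: dict[str, str]
    genes: list[GeneModel]
    te_annotation: pd.DataFrame  # BED-like: chrom, start, end, name, score, strand
    truth: pd.DataFrame
    consensus: str
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.genome, outdir / "genome.fa")
        io.write_fasta({"consensus": self.consensus}, outdir / "consensus.fa")
        write_gff3(self.genes, outdir / "genes.gff3")
        io.write_bed(self.te_annotation, outdir / "elements.bed")
        io.write_table(self.truth, outdir / "truth.tsv")


@dataclass
class AccessionPanel:
    """Per-accession genomes realizing full/empty sites plus the panel truth."""

    accessions: dict[str, dict[str, str]]
    populations: dict[str, str]  # accession -> population
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for acc, genome in self.accessions.items():
            io.write_fasta(genome, outdir / f"{acc}.fa")
        io.write_table(self.truth, outdir / "panel_truth.tsv")


def plant_insertion(sequence: str, element: str, position: int,
                    tsd_length: int) -> tuple[str, dict]:
    """Insert `element` at `position`, duplicating the `tsd_length` bases there.

    The bases ``sequence[position:position+tsd_length]`` appear once before
    and once after the element, mimicking the staggered-cut repair that
    creates a target-site duplication. Output length grows by exactly
    ``len(element) + tsd_length``.
    """
    if not element:
        raise ValueError("element must be non-empty")
    if tsd_length < 0:
        raise ValueError("tsd_length must be >= 0")
    if not 0 <= position <= len(sequence) - tsd_length:
        raise IndexError(
            f"position {position} out of range for TSD of {tsd_length} bp in a "
            f"{len(sequence)}-bp sequence")
    check_alphabet(sequence)
    check_alphabet(element, "element")
    tsd = sequence[position:position + tsd_length]
    out = sequence[:position + tsd_length] + element + sequence[position:]
    record = {
        "insert_position": position,
        "tsd_sequence": tsd,
        "element_start": position + tsd_length,
        "element_end": position + tsd_length + len(element),
    }
    return out, record


def excise_site(sequence: str, insert_position: int, element_length: int,
                tsd_length: int) -> str:
    """Undo a planted insertion: remove the element plus one TSD copy.

    Leaves a single copy of the target site, i.e. the empty-site allele.
    """
    a = insert_position + tsd_length
    b = a + element_length + tsd_length
    return sequence[:a] + sequence[b:]


def _random_nonstop_codon(rng: np.random.Generator) -> str:
    while True:
        codon = random_seq(rng, 3)
        if codon not in STOP_CODONS:
            return codon


def build_element_consensus(rng: np.random.Generator, plan: GenePlan,
                            length: int) -> str:
    """Random element whose exonic insertion truncates the host ORF.

    When inserted at the plan's CDS offset the element presents an in-frame
    TAA whose last base is element nt 41 (counted 1-based), with no earlier
    in-frame stop, reproducing the observed premature-termination geometry.
    For elements shorter than 44 nt the stop engineering is skipped.
    """
    seq = list(random_seq(rng, length))
    if length < 44:
        return "".join(seq)
    off = plan.insertion_cds_offset
    # first full codon inside the element starts at element offset
    # ((3 - off % 3) % 3); the junction codon takes the last pre-insertion
    # base(s) plus the element 5' end.
    first = (3 - off % 3) % 3
    stop_start = None
    for i in range(first, length - 2, 3):
        if i >= 38:
            stop_start = i
            break
    # place the stop codon so that it is in frame and ends at nt >= 41
    if stop_start is None:
        return "".join(seq)
    seq[stop_start:stop_start + 3] = "TAA"
    # junction codon: last (off % 3 and partners) handled by caller's CDS;
    # make the element 5' bases safe against forming TAA/TAG/TGA with any prefix
    for j in range(0, first):
        seq[j] = "C"
    # clear earlier in-frame stops
    for i in range(first, stop_start, 3):
        while "".join(seq[i:i + 3]) in STOP_CODONS:
            seq[i] = str(rng.choice(["C", "G"]))
    return "".join(seq)


def _build_cds(rng: np.random.Generator, plan: GenePlan) -> str:
    n_codons = plan.cds_length // 3
    if plan.cds_length % 3:
        raise ValueError("gene plan CDS length must be divisible by 3")
    codons = ["ATG"] + [_random_nonstop_codon(rng) for _ in range(n_codons - 2)]
    codons.append("TGA")
    cds = list("".join(codons))
    site_at = plan.target_site_cds_offset
    cds[site_at:site_at + len(plan.target_site)] = plan.target_site
    # writing the target site may create an internal stop; patch outside the
    # motif (and outside the start/terminal codons) until the frame is clean
    protected = set(range(site_at, site_at + len(plan.target_site)))
    protected |= set(range(0, 3)) | set(range(len(cds) - 3, len(cds)))
    for _ in range(100):
        dirty = False
        for i in range(3, len(cds) - 3, 3):
            if "".join(cds[i:i + 3]) in STOP_CODONS:
                editable = [j for j in range(i, i + 3) if j not in protected]
                if not editable:
                    raise RuntimeError("cannot patch stop codon inside target site")
                j = editable[0]
                cds[j] = "C" if cds[j] != "C" else "G"
                dirty = True
        if not dirty:
            break
    return "".join(cds)


def _build_gene_cassette(rng: np.random.Generator, plan: GenePlan
                         ) -> tuple[str, GeneModel, int]:
    """Assemble the gene sequence; returns (cassette, model@0, TSD-start offset)."""
    cds = _build_cds(rng, plan)
    exon_seqs, cds_spans, exons = [], [], []
    cursor = 0  # position within cassette
    cds_cursor = 0
    n_exons = len(plan.cds_exon_lengths)
    site_at = plan.target_site_cds_offset
    tsd_start_offset = None
    for i, clen in enumerate(plan.cds_exon_lengths):
        parts = []
        estart = cursor
        if i == 0:
            parts.append(random_seq(rng, plan.utr5))
            cursor += plan.utr5
        cds_spans.append((cursor, cursor + clen))
        if cds_cursor <= site_at < cds_cursor + clen:
            tsd_start_offset = cursor + (site_at - cds_cursor)
        parts.append(cds[cds_cursor:cds_cursor + clen])
        cds_cursor += clen
        cursor += clen
        if i == n_exons - 1:
            parts.append(random_seq(rng, plan.utr3))
            cursor += plan.utr3
        exons.append((estart, cursor))
        exon_seqs.append("".join(parts))
        if i < n_exons - 1:
            exon_seqs.append(random_seq(rng, plan.intron_length))
            cursor += plan.intron_length
    cassette = "".join(exon_seqs)
    model = GeneModel(gene_id="gene1", chrom="", strand="+",
                      exons=exons, cds=cds_spans)
    assert tsd_start_offset is not None
    return cassette, model, tsd_start_offset


def _pick_positions(rng: np.random.Generator, n: int, chrom_names: list[str],
                    chrom_length: int, forbidden: dict[str, list[tuple[int, int]]],
                    footprint: int, min_gap: int = 2_500, edge: int = 300,
                    max_attempts: int = 2_000) -> list[tuple[str, int]]:
    placed: list[tuple[str, int]] = []
    for _ in range(n):
        for attempt in range(max_attempts):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos = int(rng.integers(edge, chrom_length - footprint - edge))
            span = (pos - min_gap, pos + footprint + min_gap)
            clashes = any(s < span[1] and span[0] < e
                          for s, e in forbidden.get(chrom, []))
            clashes = clashes or any(c == chrom and abs(p - pos) < min_gap
                                     for c, p in placed)
            if not clashes:
                placed.append((chrom, pos))
                break
        else:
            raise RuntimeError("could not place all element copies without overlap")
    return placed


def generate_reference(config: SimulationConfig) -> ReferenceSet:
    """Build the reference genome with planted element copies and annotation.

    Exactly ``round((1 - tsd_decay_fraction) * copies_per_genome)`` copies
    retain intact TSDs (the exonic index copy always does); the rest get
    >=3 substitutions in the downstream TSD copy so the exact-match TSD
    caller fails on them. Copy bodies diverge from the consensus at
    ``copy_divergence`` substitutions per site (the index copy stays exact:
    it is the consensus source).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    plan = config.gene_plan

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: random_seq(rng, config.chrom_length) for c in chrom_names}

    cassette, model0, tsd_off = _build_gene_cassette(rng, plan)
    consensus = build_element_consensus(rng, plan, config.element_length)

    gene_chrom = chrom_names[0]
    gene_pos = int(rng.integers(2_000, config.chrom_length - len(cassette) - 2_000))
    genome[gene_chrom] = (genome[gene_chrom][:gene_pos] + cassette +
                          genome[gene_chrom][gene_pos + len(cassette):])
    gene = GeneModel(gene_id=model0.gene_id, chrom=gene_chrom, strand="+",
                     exons=[(s + gene_pos, e + gene_pos) for s, e in model0.exons],
                     cds=[(s + gene_pos, e + gene_pos) for s, e in model0.cds])
    gene_site = gene_pos + tsd_off  # TSD start of the exonic insertion

    footprint = config.element_length + 2 * config.tsd_length
    forbidden = {gene_chrom: [(gene_pos - 1_200,
                               gene_pos + len(cassette) + 1_200)]}
    others = _pick_positions(rng, config.copies_per_genome - 1, chrom_names,
                             config.chrom_length, forbidden, footprint)

    n_intact = round((1 - config.tsd_decay_fraction) * config.copies_per_genome)
    n_intact = max(1, n_intact)  # the index copy is always intact
    decayed_pool = list(range(1, config.copies_per_genome))
    rng.shuffle(decayed_pool)
    decayed = set(decayed_pool[:config.copies_per_genome - n_intact])

    plans = [{"copy_idx": 0, "chrom": gene_chrom, "pos": gene_site,
              "strand": "+", "decayed": False, "seq": consensus}]
    for k, (chrom, pos) in enumerate(others, start=1):
        body = mutate_substitutions(rng, consensus, config.copy_divergence)
        plans.append({"copy_idx": k, "chrom": chrom, "pos": pos,
                      "strand": str(rng.choice(["+", "-"])),
                      "decayed": k in decayed, "seq": body})

    truth_rows = []
    for chrom in chrom_names:
        todo = sorted((p for p in plans if p["chrom"] == chrom),
                      key=lambda p: p["pos"])
        offset = 0
        seq = genome[chrom]
        for p in todo:
            pos = p["pos"] + offset
            body = p["seq"] if p["strand"] == "+" else revcomp(p["seq"])
            seq, rec = plant_insertion(seq, body, pos, config.tsd_length)
            if p["decayed"]:
                a, b = rec["element_end"], rec["element_end"] + config.tsd_length
                broken = force_substitutions(rng, seq[a:b],
                                             min(3, config.tsd_length))
                seq = seq[:a] + broken + seq[b:]
            if chrom == gene.chrom:
                gene = shift_for_insertion(
                    gene, pos + config.tsd_length,
                    config.element_length + config.tsd_length)
            offset += config.element_length + config.tsd_length
            truth_rows.append({
                "copy_id": f"copy{p['copy_idx']:02d}",
                "chromosome": chrom,
                "insert_position": rec["insert_position"],
                "strand": p["strand"],
                "tsd_sequence": rec["tsd_sequence"],
                "tsd_intact": not p["decayed"],
                "locus_id": f"L{p['copy_idx']:02d}",
                "accession_id": "reference",
                "present": True,
                "element_start": rec["element_start"],
                "element_end": rec["element_end"],
            })
        genome[chrom] = seq

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["chromosome", "insert_position"]).reset_index(drop=True)
    bed = pd.DataFrame({
        "chrom": truth["chromosome"], "start": truth["element_start"],
        "end": truth["element_end"], "name": truth["locus_id"],
        "score": 0, "strand": truth["strand"]})
    return ReferenceSet(genome=genome, genes=[gene], te_annotation=bed,
                        truth=truth, consensus=consensus, config=config)


def default_presence_profile(n_loci: int, n_populations: int
                             ) -> tuple[tuple[float, ...], ...]:
    """Per-locus per-population full-site probabilities shaped like the
    published 11-locus wild-emmer panel (codes 0/1/2 -> p = 0/0.5/1); extra
    loci beyond the panel are fixed present."""
    from .popdyn import EMMER_PANEL_CODES
    code_to_p = {0: 0.0, 1: 0.5, 2: 1.0}
    rows = []
    panel = list(EMMER_PANEL_CODES.values())
    for i in range(n_loci):
        if i < len(panel):
            codes = panel[i][:n_populations]
            row = tuple(code_to_p[c] for c in codes)
            if len(row) < n_populations:
                row = row + (1.0,) * (n_populations - len(row))
        else:
            row = (1.0,) * n_populations
        rows.append(row)
    return tuple(rows)


def generate_accession_panel(reference: ReferenceSet,
                             config: SimulationConfig | None = None,
                             seed: int | None = None) -> AccessionPanel:
    """Realize full/empty sites per accession by Bernoulli draws per locus.

    Empty sites are excised copies: the element and one TSD copy removed,
    leaving a single target-site copy, as in the empty-site allele.
    """
    config = config or reference.config
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    loci = reference.truth.sort_values(["chromosome", "insert_position"])
    n_loci = len(loci)
    profile = config.presence_profile or default_presence_profile(
        n_loci, config.n_populations)
    if len(profile) != n_loci:
        raise ValueError("presence_profile must have one row per locus")

    pops = list(DEFAULT_POPULATIONS[:config.n_populations])
    while len(pops) < config.n_populations:
        pops.append(f"Pop{len(pops) + 1}")
    accessions: dict[str, dict[str, str]] = {}
    pop_of: dict[str, str] = {}
    rows = []
    locus_list = list(loci.itertuples(index=False))
    for pi, pop in enumerate(pops):
        prefix = _POP_PREFIX.get(pop, pop[0].upper())
        for ai in range(config.accessions_per_population):
            acc = f"{prefix}{ai + 1}"
            pop_of[acc] = pop
            genome = dict(reference.genome)
            present = {t.locus_id: bool(rng.random() < profile[j][pi])
                       for j, t in enumerate(locus_list)}
            # excise right-to-left so upstream coordinates stay valid
            for t in sorted(locus_list, key=lambda t: -t.insert_position):
                if not present[t.locus_id]:
                    genome[t.chromosome] = excise_site(
                        genome[t.chromosome], t.insert_position,
                        config.element_length, config.tsd_length)
            accessions[acc] = genome
            for t in locus_list:
                rows.append({"locus_id": t.locus_id, "accession_id": acc,
                             "population": pop, "present": present[t.locus_id]})
    truth = pd.DataFrame(rows)
    return AccessionPanel(accessions=accessions, populations=pop_of, truth=truth)


def generate_ct_table(design: dict[str, int | list[str]],
                      effects: dict[str, float] | None = None,
                      seed: int = 0, *, target_baseline: float = 24.0,
                      control_baseline: float = 20.0, noise_sd: float = 0.2,
                      calibrator: str | None = None) -> pd.DataFrame:
    """Simulate a qPCR CT table with per-group shifts on the target gene.

    A +1 CT shift on the target alone halves the group's expected relative
    quantity under the 2^-ddCT model. Noise is i.i.d. Gaussian on each CT.
    """
    effects = effects or {}
    rng = np.random.default_rng(seed)
    rows = []
    for group, members in design.items():
        ids = ([f"{group}{i + 1}" for i in range(members)]
               if isinstance(members, int) else list(members))
        shift = effects.get(group, 0.0)
        for acc in ids:
            rows.append({
                "accession": acc,
                "group": group,
                "ct_target": target_baseline + shift + rng.normal(0, noise_sd),
                "ct_control": control_baseline + rng.normal(0, noise_sd),
            })
    df = pd.DataFrame(rows)
    calibrator = calibrator or df["accession"].iloc[0]
    if calibrator not in set(df["accession"]):
        raise ValueError(f"calibrator {calibrator!r} not in design")
    df["is_calibrator"] = df["accession"] == calibrator
    return df
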