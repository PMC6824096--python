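# Methods

This note documents the models and procedures implemented in `mitekit`,
the defaults they ship with, and what the synthetic data used by the test
suite does and does not establish.

## The biological setting

Miniature non-autonomous DNA transposons (MITE-like elements) are short
(a few hundred bp), carry no coding capacity, and are recognized
structurally: a target-site duplication (TSD) created on insertion,
usually terminal inverted repeats (TIRs), and — for SINEs — an internal
RNA-Pol-III promoter (A/B boxes) plus a 3' poly-A tail. The element this
package was built around is atypical: 307 bp, a 9-bp TSD (the motif
`CCAAGAACT` at its index site in exon 6 of a 7-exon
5-formyltetrahydrofolate cyclo-ligase gene), no TIRs and no SINE
hallmarks. Because 9-bp TSDs are characteristic of *Mutator*-superfamily
elements, the classifier's rule table sends a TIR-less, SINE-negative,
9-bp-TSD element to "Mutator-derived MITE candidate (TSD only)".

## Homology retrieval (`homologyscan`)

Copies are found by seed-and-extend: exact `word_size` (default 11) word
matches between query and genome are clustered into candidate regions,
each region is aligned against the full query with a local affine-gap
aligner (+1 match, −2 mismatch, −5 open, −2 extend), and alignments pass
when the Karlin–Altschul expect value E = K·m·n·e^(−λS) (λ = 0.625,
K = 0.41 for this scoring, both exposed in `SearchParams`) is at most
`evalue_max` (default 10⁻³). Both strands are searched; hits overlapping
more than half the shorter span are merged to the best-scoring record
(one insertion locus = one record).

Hit coordinates are reported as the *glocal* projection of the alignment:
the local alignment's genomic span extended by the unaligned query length
at each end. This makes hit boundaries coincide with the element
boundaries even when a terminal mismatch was trimmed by the local
aligner, which matters downstream because the TSD caller assumes flanks
abut the element. Full-length status allows up to `end_mismatch_tol`
(default 20) unaligned query nt per end — a coverage tolerance, not a
mismatch count. Flanks of `flank_length` (default 1000) bp are clipped,
never padded, at contig edges, with truncation recorded.

## Structural classification (`elementchar`)

*TSD*: exhaustive search over duplication lengths k ∈ [8, 12] by default
(any range may be requested), exact matching (`max_mismatch = 0`), with
each copy allowed to start within `boundary_slack = 2` bp of the element
boundary. Exact matching deliberately reproduces a binary clear/absent
split rather than introducing a similarity threshold; the slack absorbs
small boundary uncertainty from the aligner. Ties at equal k break toward
fewer mismatches, then smaller offsets. The caller is verified against a
brute-force enumeration of every (k, offset, offset) triple.

*TIR*: the 5' window (30 bp) is compared with the reverse complement of
the 3' window over all ungapped offsets; arm pairs need ≥ 10 bp and ≥ 80%
identity, and the winner maximizes the ungapped alignment score
(+1/−2), so a short perfect repeat beats a longer sloppy one. These
thresholds are conventional MITE TIR ranges.

*SINE hallmarks*: poly-A = ≥ 8 adenines with at most one interruption
inside the 3'-terminal 20 bp; A box `TRGCNNARYNNG` and B box `GTTCGANNC`
scanned over the 5' half with an IUPAC match fraction ≥ 0.8 over
informative positions; the combined promoter call requires 25–75 bp
between A-box end and B-box start. The classifier's SINE branch requires
tail plus both boxes.

*Logos*: per-column nucleotide frequencies over aligned target sites with
information content IC = 2 − H bits, optionally minus the small-sample
correction 3/(2·ln2·n), clipped to [0, 2]. By default one site per
insertion (the upstream copy) is used; matrices are plain DataFrames and
can be rendered by any plotting layer.

*Conservation*: percent identity from global alignment with the same
scoring as the search engine; gaps count as mismatch columns. Both the
mean and the minimum of the off-diagonal values are reported, since
"high conservation" claims can refer to either.

## Site annotation (`siteannot`)

All coordinates are 0-based half-open internally; GFF3 is converted on
read/write. Precedence is exon > UTR > intron > gene-proximal >
TE-adjacent > intergenic, with a 500-bp proximity window for genes and
(by decision, absent a stated value) the same window for TEs. Distances
are half-open gaps; a feature abutting the span (gap 0 without overlap)
is classified proximal at distance 0, an edge case the caller documents.
An insertion's own record in the element BED is excluded before
TE-adjacency is assessed.

## Population dynamics (`popdyn`)

In-silico PCR reports a product for every forward-primer site paired with
every downstream reverse-complemented reverse-primer site within 5 kb
(default), exact matching by default; when up to 2 mismatches are
allowed, the three 3'-terminal bases of each primer must still match
exactly (polymerase extension is 3'-end sensitive). Locus scoring calls
1/0 by product size within ± tol of the expected full/empty sizes
(expected sizes are per-locus inputs, not derived from a fixed element
length, because observed gel sizes round). Population codes follow the
0/1/2 rule: empty in all accessions / full in some / full in all.

Clustering uses Bray–Curtis dissimilarity (equal to 1 − Sørensen on
binary data, an identity the tests assert) and group-average (UPGMA)
linkage via scipy, cross-checked against a naive hand-rolled UPGMA in the
tests. All-zero accession pairs get dissimilarity 1 with a warning.

SIMPROF is implemented from its definition: the node's resemblance
profile is the sorted vector of pairwise similarities; null data permute
each locus column independently across the node's accessions; the mean
profile is the rank-wise mean of `n_mean_perms` (default 1000) null
profiles; π is the L1 deviation of a profile from the mean profile; and
p = (1 + #{π_null ≥ π_obs}) / (1 + `n_null_perms`) with 999 null
permutations by default, α = 0.05. Traversal is root-down and stops at
non-significant nodes; nodes with fewer than three accessions auto-pass
as non-significant. Because column permutation preserves i.i.d. data
exactly, the test is a valid permutation test, and the suite verifies its
type-I error on Bernoulli(0.5) panels (10 accessions × 11 loci, 500
seeds) stays within [0.02, 0.08], with ≥ 95% power on two disjoint
planted groups of 10. Each node's permutation stream is seeded from a
CRC32 hash of its label-sorted member profiles combined with the user
seed, making results invariant to accession ordering.

## Gene impact (`impact`)

An exonic insertion is retained in the mature mRNA together with exactly
one extra TSD copy, so the transcript grows by element + TSD (316 nt for
the default geometry); this convention reproduces the observed empty/full
RT-PCR product pair (626 vs 942 bp for the packaged gene plan). The
genomic site-specific product arithmetic (full site = empty + element +
TSD) is available through the same planting primitive; observed gel
sizes that differ from the exact sum are treated as gel rounding, with
expected sizes always configurable per locus. Translation uses the
standard nuclear code from the annotated CDS start; the report gives the
first in-frame stop (1-based position within the inserted nucleotides
when it falls there), both alleles' protein lengths (the reference allele
is reconstructed by excising the insertion span), and the lost CDS
fraction. For the default synthetic gene the reference allele encodes
280 aa and the insertion allele truncates to 249 aa with the stop ending
at insertion nt 41.

Expression: RQ = 2^−ΔΔCT against an endogenous control and a calibrator
accession (whose RQ is exactly 1); adding any constant to all CTs leaves
RQ unchanged (asserted as a property). Efficiency
= ((10^(−1/slope)) − 1) × 100. Group comparisons use one-way ANOVA
(scipy) with Tukey HSD contrasts (statsmodels); single-observation groups
are excluded with a warning.

## The synthetic study system (`synthdata`)

Defaults mirror the study conditions the pipeline was designed around:
2 chromosomes × 50 kb of i.i.d. uniform ACGT background (uniform noise
avoids accidental homology), a 307-bp element with 9-bp TSDs, 12 copies
per genome, 3% per-site copy divergence (substitutions only; indels are
deliberately excluded from the default model), half the copies with
decayed TSDs (≥ 3 forced substitutions in the downstream copy, which
guarantees the exact-match caller fails), 5 populations × 9 accessions,
and per-locus presence probabilities mapped from the packaged 11-locus
0/1/2 code panel (0 → 0, 1 → 0.5, 2 → 1). The 7-exon gene plan places
843 nt of CDS (280 aa) across exons of 120/120/120/120/120/150/93 nt
with a 60-nt 5' UTR, 300-nt 3' UTR and 200-nt introns; the 9-bp target
site is written into exon 6 at CDS offset 700 and the element consensus
carries an engineered in-frame TAA ending at element nt 41 (with no
earlier in-frame stop for this insertion phase), so the full
truncation geometry is realized by construction. The index (exonic) copy
is planted unmutated — it is the consensus source — and always with an
intact TSD. Accession genomes are the reference with absent loci excised
(element + one TSD copy removed, leaving a single target-site copy,
i.e. the empty allele); accessions are simulated homozygous, reflecting a
predominantly self-pollinating species. Fixed seeds make every artifact
byte-identical.

What the generator does **not** emulate: real repeat landscapes and
nested/fragmented TEs, polyploid subgenome homeology, indel-driven decay,
heterozygosity, or sequencing noise. Passing recovery tests therefore
demonstrate correctness of the algorithms under the stated model, not
performance on real wheat assemblies; in particular the published
per-species copy counts depend on the real genome drafts and are out of
scope here, and copy recovery is validated only against planted truth
(≥ 95% of intact-TSD copies at ≤ 5% divergence).

## Problem sizes and numerics

The test suite runs the search oracle on ≤ 50-kb genomes, recovery on
three independently seeded 12-copy genomes, SIMPROF calibration on
10 × 11 panels (500 seeds × 1999 permutations each, fully vectorized with
batched Bray–Curtis via einsum), and the ANOVA power check on 200
simulated CT tables — sizes chosen so each stage's statistical claim is
testable at desk scale. Degenerate inputs are handled explicitly:
homopolymer queries are rejected, empty genomes return empty hit lists,
all-zero profile pairs get dissimilarity 1 with a warning, zero slopes
and missing calibrators raise, and non-stop transcripts are flagged
rather than silently truncated.

## Known limitations

- The search engine targets short consensus queries against moderate
  genomes; it indexes words per query/chromosome pair on the fly and is
  not tuned for gigabase-scale scans.
- TSD calling is exact-match by design; heavily decayed duplications are
  reported absent rather than scored by similarity.
- In-silico PCR considers primer pairs in one orientation (forward on the
  given strand, reverse downstream) and ignores thermodynamics.
- SIMPROF p-values are permutation-resolution bounded (minimum 1/(1+999)
  by default).
- The logo matrix is computed, not rendered; plotting is left to the
  caller.
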