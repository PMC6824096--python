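"""Search-engine behaviour: exact and diverged planting, strand symmetry,
e-value arithmetic, full-length calling, flank extraction, and the
brute-force sliding-window oracle."""

import math

import numpy as np
import pytest

from mitekit import homologyscan as hs
from mitekit import synthdata as sd
from mitekit._util import random_seq, revcomp


def brute_force_scan(query: str, genome: dict[str, str],
                     params: hs.SearchParams) -> list[tuple[str, str, int]]:
    """Independent oracle: ungapped full-query alignment at every offset of
    both strands, same Karlin-Altschul e-value filter, overlapping windows
    collapsed to the best-scoring offset. Returns (chrom, strand, start)."""
    total = sum(len(s) for s in genome.values())
    out = []
    m = len(query)
    for chrom, seq in genome.items():
        g = np.frombuffer(seq.encode(), dtype="S1")
        if len(g) < m:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, m)
        for strand in "+-":
            q = query if strand == "+" else revcomp(query)
            qa = np.frombuffer(q.encode(), dtype="S1")
            matches = (windows == qa).sum(axis=1)
            scores = matches * params.match + (m - matches) * params.mismatch
            evs = params.ka_k * m * total * np.exp(-params.ka_lambda * scores)
            passing = np.flatnonzero(evs <= params.evalue_max)
            # collapse runs of overlapping passing offsets to the best one
            cluster: list[int] = []
            for off in passing:
                if cluster and off - cluster[-1] > m:
                    best = max(cluster, key=lambda o: scores[o])
                    out.append((chrom, strand, int(best)))
                    cluster = []
                cluster.append(int(off))
            if cluster:
                best = max(cluster, key=lambda o: scores[o])
                out.append((chrom, strand, int(best)))
    return sorted(out, key=lambda x: (x[0], x[2]))


@pytest.fixture(scope="module")
def params():
    return hs.SearchParams(flank_length=100)


class TestEvalue:
    def test_zero_score_is_maximal(self):
        p = hs.SearchParams()
        assert hs.evalue(0, 307, 1000, p) == pytest.approx(p.ka_k * 307 * 1000)

    def test_linear_in_genome_length(self):
        p = hs.SearchParams()
        assert hs.evalue(50, 307, 2_000_000, p) == pytest.approx(
            2 * hs.evalue(50, 307, 1_000_000, p))

    def test_strictly_decreasing_in_score(self):
        p = hs.SearchParams()
        es = [hs.evalue(s, 307, 1e5, p) for s in range(0, 300, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_full_length_match_is_significant(self):
        # lambda=0.625, K=0.41, m=307, n=1e5, S=307
        e = hs.evalue(307, 307, 100_000, hs.SearchParams())
        assert e < 1e-3

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            hs.evalue(10, 0, 100)


class TestCallFullLength:
    @pytest.mark.parametrize("qs,qe,expected", [
        (0, 307, True),      # complete coverage
        (24, 307, False),    # 24 bp missing at 5' end exceeds 20
        (17, 300, True),     # 17 and 7 bp missing are both tolerated
    ])
    def test_end_tolerance_rule(self, qs, qe, expected):
        hit = hs.InsertionHit(hit_id="h", chromosome="c", start=0, end=1,
                              strand="+", raw_score=0, bit_score=0, evalue=0,
                              query_start=qs, query_end=qe, identity=100)
        assert hs.call_full_length(hit, 307, 20) is expected


class TestExtractFlanks:
    def test_mid_contig(self):
        seq = "A" * 50 + "C" * 10 + "G" * 50
        up, down, ut, dt = hs.extract_flanks(seq, 50, 60, 30)
        assert up == "A" * 30 and down == "G" * 30
        assert not ut and not dt

    def test_clipped_at_contig_start(self):
        up, down, ut, dt = hs.extract_flanks("ACGTACGT", 0, 4, 10)
        assert up == "" and ut
        assert down == "ACGT" and dt

    def test_concatenation_reproduces_genome(self, rng):
        seq = random_seq(rng, 2000)
        up, down, *_ = hs.extract_flanks(seq, 900, 1100, 100)
        assert up + seq[900:1100] + down == seq[800:1200]

    def test_out_of_bounds(self):
        with pytest.raises(IndexError):
            hs.extract_flanks("ACGT", 2, 9, 5)


class TestSearchCopies:
    def test_exact_planting_found_with_full_identity(self, rng, params):
        query = random_seq(rng, 307)
        genome = {}
        positions = {}
        for c in ("chr1", "chr2"):
            seq = random_seq(rng, 50_000)
            pos = [10_000, 30_000] if c == "chr1" else [20_000]
            final = []
            for k, p in enumerate(pos):  # earlier insertions shift later ones
                shifted = p + k * len(query)
                seq = seq[:shifted] + query + seq[shifted:]
                final.append(shifted)
            genome[c] = seq
            positions[c] = final
        hits = hs.search_copies(query, genome, params)
        assert len(hits) == 3
        for h in hits:
            assert h.identity == 100.0
            assert h.is_full_length
            assert h.start in positions[h.chromosome]
            assert h.end - h.start == 307

    def test_diverged_copies_recovered(self, rng, params):
        from mitekit._util import mutate_substitutions
        query = random_seq(rng, 307)
        seq = random_seq(rng, 60_000)
        for p in (50_000, 25_000, 5_000):
            copy = mutate_substitutions(rng, query, 0.05)
            seq = seq[:p] + copy + seq[p:]
        hits = hs.search_copies(query, {"chr1": seq}, params)
        assert len(hits) == 3
        assert all(h.identity >= 90.0 for h in hits)

    def test_reverse_complement_planting(self, rng, params):
        query = random_seq(rng, 307)
        seq = random_seq(rng, 20_000)
        seq = seq[:8_000] + revcomp(query) + seq[8_000:]
        hits = hs.search_copies(query, {"chr1": seq}, params)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-"
        assert (h.start, h.end) == (8_000, 8_307)
        up, down = hs.element_oriented_flanks(h)
        # element-oriented flanks must reproduce the planting neighbourhood
        assert up == revcomp(seq[8_307:8_307 + params.flank_length])
        assert down == revcomp(seq[8_000 - params.flank_length:8_000])

    def test_empty_genome(self, params):
        assert hs.search_copies("ACGT" * 20, {}, params) == []

    def test_homopolymer_query_rejected(self, params):
        with pytest.raises(ValueError):
            hs.search_copies("A" * 50, {"c": "ACGT" * 100}, params)

    def test_matches_brute_force_scan(self, params):
        """On small genomes the hit set equals an exhaustive ungapped
        sliding-window scan over all positions of both strands."""
        rng = np.random.default_rng(77)
        from mitekit._util import mutate_substitutions
        query = random_seq(rng, 200)
        for trial in range(3):
            seq = random_seq(rng, 20_000)
            n_plant = trial  # 0, 1, 2 copies
            for k in range(n_plant):
                p = 4_000 + 8_000 * k
                copy = mutate_substitutions(rng, query, 0.03)
                if k % 2:
                    copy = revcomp(copy)
                seq = seq[:p] + copy + seq[p:]
            genome = {"chr1": seq}
            expected = brute_force_scan(query, genome, params)
            hits = hs.search_copies(query, genome, params)
            assert len(hits) == len(expected)
            for h, (chrom, strand, start) in zip(
                    sorted(hits, key=lambda h: h.start), expected):
                assert h.chromosome == chrom
                assert h.strand == strand
                assert abs(h.start - start) <= 5

    def test_lowering_evalue_never_adds_hits(self, rng):
        query = random_seq(rng, 150)
        seq = random_seq(rng, 30_000)
        for p in (5_000, 15_000):
            seq = seq[:p] + query + seq[p:]
        loose = hs.search_copies(query, {"c": seq},
                                 hs.SearchParams(evalue_max=1.0,
                                                 flank_length=50))
        strict = hs.search_copies(query, {"c": seq},
                                  hs.SearchParams(evalue_max=1e-6,
                                                  flank_length=50))
        loose_keys = {(h.chromosome, h.start, h.strand) for h in loose}
        strict_keys = {(h.chromosome, h.start, h.strand) for h in strict}
        assert strict_keys <= loose_keys

    def test_reverse_complemented_genome_mirrors_hits(self, rng, params):
        query = random_seq(rng, 200)
        seq = random_seq(rng, 15_000)
        seq = seq[:6_000] + query + seq[6_000:]
        fwd = hs.search_copies(query, {"c": seq}, params)
        rev = hs.search_copies(query, {"c": revcomp(seq)}, params)
        assert len(fwd) == len(rev) == 1
        n = len(seq)
        assert rev[0].start == n - fwd[0].end
        assert rev[0].end == n - fwd[0].start
        assert {fwd[0].strand, rev[0].strand} == {"+", "-"}


class TestBitScore:
    def test_monotone_transform(self):
        p = hs.SearchParams()
        assert hs.bit_score(100, p) > hs.bit_score(50, p)
        expected = (p.ka_lambda * 100 - math.log(p.ka_k)) / math.log(2)
        assert hs.bit_score(100, p) == pytest.approx(expected)
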