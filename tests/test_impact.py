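"""Transcript reconstruction, ORF truncation, qPCR efficiency, relative
expression and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitekit import impact
from mitekit import synthdata as sd
from mitekit._util import random_seq, revcomp
from mitekit.genes import GeneModel


@pytest.fixture(scope="module")
def model_gene():
    """The default synthetic 7-exon gene, as its empty-site (reference)
    allele, plus the element consensus and insertion coordinates."""
    cfg = sd.SimulationConfig(seed=1)
    ref = sd.generate_reference(cfg)
    gene = ref.genes[0]
    idx = ref.truth[ref.truth.copy_id == "copy00"].iloc[0]
    add = cfg.element_length + cfg.tsd_length
    ins_at = int(idx.insert_position) + cfg.tsd_length

    def unshift(span):
        s, e = span
        if s >= ins_at + add:
            return (s - add, e - add)
        if e >= ins_at + add:
            return (s, e - add)
        return span

    empty_gene = GeneModel(gene.gene_id, gene.chrom, gene.strand,
                           [unshift(x) for x in gene.exons],
                           [unshift(x) for x in gene.cds])
    empty_chrom = sd.excise_site(ref.genome[gene.chrom],
                                 int(idx.insert_position),
                                 cfg.element_length, cfg.tsd_length)
    return {"cfg": cfg, "gene": empty_gene, "chrom": empty_chrom,
            "element": ref.consensus,
            "insert_position": int(idx.insert_position)}


class TestSpliceTranscript:
    def test_reference_length_is_exon_sum(self, model_gene):
        g = model_gene["gene"]
        tx = impact.splice_transcript(g, model_gene["chrom"])
        assert len(tx.seq) == sum(e - s for s, e in g.exons)
        assert tx.cds_end - tx.cds_start == g.cds_length

    def test_insertion_allele_grows_by_element_plus_tsd(self, model_gene):
        cfg = model_gene["cfg"]
        ref_tx = impact.splice_transcript(model_gene["gene"],
                                          model_gene["chrom"])
        ins_tx = impact.splice_transcript(
            model_gene["gene"], model_gene["chrom"],
            insertion=(model_gene["insert_position"], model_gene["element"],
                       cfg.tsd_length))
        assert len(ins_tx.seq) - len(ref_tx.seq) == \
            cfg.element_length + cfg.tsd_length
        a, b = ins_tx.insertion_span
        assert b - a == cfg.element_length + cfg.tsd_length
        # excising the insertion span restores the reference mRNA
        assert ins_tx.seq[:a] + ins_tx.seq[b:] == ref_tx.seq

    def test_minus_strand_gene_is_reverse_complemented(self, rng):
        seq = random_seq(rng, 1000)
        plus = GeneModel("g", "c", "+", [(100, 200), (300, 400)],
                         [(100, 200), (300, 400)])
        minus = GeneModel("g", "c", "-", [(100, 200), (300, 400)],
                          [(100, 200), (300, 400)])
        tx_p = impact.splice_transcript(plus, seq)
        tx_m = impact.splice_transcript(minus, seq)
        assert tx_m.seq == revcomp(tx_p.seq)

    def test_intronic_insertion_rejected(self, model_gene):
        g = model_gene["gene"]
        intron_pos = g.exons[0][1] + 10
        with pytest.raises(ValueError):
            impact.splice_transcript(g, model_gene["chrom"],
                                     insertion=(intron_pos, "ACGTACGT", 9))


class TestOrfReport:
    def test_reference_protein_280_aa_no_premature_stop(self, model_gene):
        tx = impact.splice_transcript(model_gene["gene"], model_gene["chrom"])
        rep = impact.orf_report(tx.seq, tx.cds_start, allele="reference")
        assert rep.protein_length == 280
        assert not rep.premature_stop and not rep.non_stop

    def test_insertion_stop_at_position_41_truncates_to_249(self, model_gene):
        cfg = model_gene["cfg"]
        tx = impact.splice_transcript(
            model_gene["gene"], model_gene["chrom"],
            insertion=(model_gene["insert_position"], model_gene["element"],
                       cfg.tsd_length))
        rep = impact.orf_report(tx.seq, tx.cds_start, tx.insertion_span,
                                cfg.tsd_length)
        assert rep.premature_stop
        assert rep.stop_position_in_insertion == 41
        assert rep.protein_length == 249
        assert rep.protein_length_reference == 280
        assert 0 < rep.lost_cds_fraction < 0.2

    def test_stop_free_insertion_flags_altered_terminus_only(self, rng):
        # engineered insertion with no stop in the read-through frame
        utr = "GGGTTTCCC" * 10
        cds = "ATG" + "GCA" * 50 + "TGA"
        mrna_ref = cds + utr
        insert = "GCC" * 20  # alanine-only, no stop in any frame
        pos = 3 + 3 * 25
        mrna = mrna_ref[:pos] + insert + mrna_ref[pos:]
        rep = impact.orf_report(mrna, 0, (pos, pos + len(insert)))
        assert not rep.premature_stop
        assert rep.stop_position_in_insertion is None
        assert rep.protein_length == 51 + 20

    def test_nonstop_transcript_flagged(self):
        rep = impact.orf_report("ATG" + "GCA" * 10, 0)
        assert rep.non_stop


class TestPrimerEfficiency:
    def test_reference_values(self):
        assert impact.primer_efficiency(-3.321928) == pytest.approx(100.0,
                                                                    abs=1e-3)
        assert impact.primer_efficiency(-1.0) == pytest.approx(900.0)
        assert impact.primer_efficiency(-10.0) == pytest.approx(25.89,
                                                                abs=0.01)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            impact.primer_efficiency(0.0)

    def test_standard_curve_wrapper(self):
        assert impact.StandardCurve(-3.321928).efficiency == pytest.approx(
            100.0, abs=1e-3)


class TestRelativeExpression:
    def test_calibrator_rq_exactly_one(self):
        ct = sd.generate_ct_table({"A": 4, "B": 4}, {"B": 0.7}, seed=2)
        cal = ct[ct.is_calibrator].accession.iloc[0]
        rq = impact.relative_expression(ct, cal)
        assert float(rq.loc[rq.accession == cal, "rq"].iloc[0]) == 1.0

    def test_one_cycle_delta_gives_half(self):
        df = pd.DataFrame({"accession": ["cal", "s"],
                           "ct_target": [24.0, 25.0],
                           "ct_control": [20.0, 20.0]})
        rq = impact.relative_expression(df, "cal")
        assert float(rq.loc[rq.accession == "s", "rq"].iloc[0]) == 0.5

    @given(st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_free_under_global_ct_shift(self, shift):
        base = sd.generate_ct_table({"A": 3, "B": 3}, {"B": 1.2}, seed=9)
        shifted = base.assign(ct_target=base.ct_target + shift,
                              ct_control=base.ct_control + shift)
        a = impact.relative_expression(base, "A1")["rq"].to_numpy()
        b = impact.relative_expression(shifted, "A1")["rq"].to_numpy()
        assert np.allclose(a, b)

    def test_missing_ct_rows_excluded_with_warning(self):
        df = pd.DataFrame({"accession": ["cal", "s", "bad"],
                           "ct_target": [24.0, 25.0, np.nan],
                           "ct_control": [20.0, 20.0, 20.0]})
        with pytest.warns(UserWarning):
            rq = impact.relative_expression(df, "cal")
        assert len(rq) == 2


class TestAnovaTukey:
    def test_identical_groups_f_near_zero(self):
        rq = pd.Series([1.0, 1.1, 0.9, 1.0, 1.1, 0.9])
        groups = pd.Series(["A", "A", "A", "B", "B", "B"])
        F, p, _ = impact.anova_tukey(rq, groups)
        assert F == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_large_separation_significant(self, rng):
        rq = pd.Series(np.r_[rng.normal(0, 0.1, 5), rng.normal(10, 0.1, 5)])
        groups = pd.Series(["A"] * 5 + ["B"] * 5)
        F, p, tukey = impact.anova_tukey(rq, groups)
        assert p < 0.001
        assert tukey["reject"].astype(bool).all()

    def test_low_population_flagged_in_tukey(self):
        """A five-group design with one shifted-down group: that group's
        pairwise contrasts are the ones rejected."""
        ct = sd.generate_ct_table(
            {g: 5 for g in "ABCDE"}, {"A": 1.5}, seed=4, noise_sd=0.15)
        rq = impact.relative_expression(ct, "B1")
        F, p, tukey = impact.anova_tukey(rq["rq"], rq["group"])
        assert p < 0.05
        involves_a = ("A" == tukey["group1"]) | ("A" == tukey["group2"])
        assert tukey.loc[involves_a, "reject"].astype(bool).all()

    def test_singleton_group_excluded(self):
        rq = pd.Series([1.0, 1.2, 0.8, 2.0, 2.2, 3.0])
        groups = pd.Series(["A", "A", "A", "B", "B", "C"])
        with pytest.warns(UserWarning):
            F, p, _ = impact.anova_tukey(rq, groups)
        assert np.isfinite(F)

    def test_power_at_one_cycle_effect(self):
        """n=5 per group, a 1-CT target shift and 0.2 CT noise is detected
        by the ANOVA at alpha=0.05 in at least 90% of simulations."""
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            ct = sd.generate_ct_table({"A": 5, "B": 5}, {"B": 1.0},
                                      seed=100_000 + seed, noise_sd=0.2)
            rq = impact.relative_expression(ct, "A1")
            _, p, _ = impact.anova_tukey(rq["rq"], rq["group"])
            hits += p < 0.05
        assert hits / n_sim >= 0.90
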