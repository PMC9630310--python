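"""Gene/TSS/SNP/conservation annotations and allele injection."""

import numpy as np
import pandas as pd
import pytest

import crisprkit as ck
from crisprkit.annotation import GeneModel, Transcript, Variant
from crisprkit.guides import Guide, GuideSet


def _guide(coord, strand="+", gid="g1", spacer="A" * 20, seq_id="chr1"):
    start, end = (coord - 20, coord) if strand == "+" else (coord + 1, coord + 21)
    return Guide(id=gid, spacer=spacer, protospacer=spacer, pam="AGG",
                 seq_id=seq_id, pam_coordinate=coord, strand=strand,
                 start=start, end=end, cut_position=coord - 4 if strand == "+"
                 else coord + 3)


def _single_exon_model(n_isoforms=1, cds=(100, 202), exon=(50, 250),
                       strand="+"):
    txs = {}
    for i in range(n_isoforms):
        txs[f"t{i}"] = Transcript(
            id=f"t{i}", gene_id="geneA", seq_id="chr1", strand=strand,
            exons=[exon], cds=[cds] if i == 0 or n_isoforms == 1 else [cds],
            canonical=(i == 0),
        )
    return GeneModel(txs)


class TestGeneModel:
    def test_cds_must_be_inside_exons(self):
        with pytest.raises(ValueError, match="not contained"):
            GeneModel({"t": Transcript(id="t", gene_id="g", seq_id="c",
                                       strand="+", exons=[(100, 200)],
                                       cds=[(150, 250)])})

    def test_cds_not_multiple_of_three_warns(self):
        with pytest.warns(UserWarning, match="divisible"):
            GeneModel({"t": Transcript(id="t", gene_id="g", seq_id="c",
                                       strand="+", exons=[(0, 100)],
                                       cds=[(10, 20)])})

    def test_cds_index_minus_strand_reads_in_translation_order(self):
        model = GeneModel({"t": Transcript(
            id="t", gene_id="g", seq_id="c", strand="-",
            exons=[(0, 30), (50, 80)], cds=[(0, 30), (50, 80)])})
        # translation starts at the genomic end for a minus-strand CDS
        assert model.cds_index("t", 79) == 0
        assert model.cds_index("t", 50) == 29
        assert model.cds_index("t", 29) == 30
        assert model.cds_index("t", 40) is None

    def test_cds_sequence_spliced_and_stranded(self):
        genome = {"c": "ATGAAA" + "GTGTGT" + "CCCTAA"}
        model = GeneModel({"t": Transcript(
            id="t", gene_id="g", seq_id="c", strand="+",
            exons=[(0, 6), (12, 18)], cds=[(0, 6), (12, 18)])})
        assert model.cds_sequence("t", genome) == "ATGAAACCCTAA"


class TestGeneAnnotation:
    def test_pct_cds_midpoint(self):
        model = _single_exon_model(cds=(100, 202))
        # cut lands on the 51st base of a 102-nt CDS -> 50%
        g = _guide(154)  # cut = 150 -> CDS index 50
        ck.add_gene_annotation(GuideSet([g], ck.builtin_nuclease("SpCas9")),
                               model)
        assert g.annotations["pct_cds"] == pytest.approx(50.0)

    def test_isoform_fraction_three_of_four(self):
        txs = {}
        for i in range(4):
            exon = (50, 250) if i < 3 else (400, 600)
            txs[f"t{i}"] = Transcript(id=f"t{i}", gene_id="geneA",
                                      seq_id="chr1", strand="+",
                                      exons=[exon], cds=[],
                                      canonical=(i == 0))
        model = GeneModel(txs)
        g = _guide(150)
        ck.add_gene_annotation(GuideSet([g], ck.builtin_nuclease("SpCas9")),
                               model)
        assert g.annotations["isoform_fraction"] == pytest.approx(0.75)

    def test_downstream_inframe_atg(self):
        # CDS "ATG AAA ATG TAA": cut inside codon 2 -> downstream in-frame
        # ATG at codon 3
        genome = {"chr1": "C" * 100 + "ATGAAAATGTAA" + "C" * 100}
        model = GeneModel({"t": Transcript(
            id="t", gene_id="g", seq_id="chr1", strand="+",
            exons=[(100, 112)], cds=[(100, 112)], canonical=True)})
        g = _guide(108)  # cut at 104, codon 2
        gs = GuideSet([g], ck.builtin_nuclease("SpCas9"))
        ck.add_gene_annotation(gs, model)
        ck.add_downstream_atg_flag(gs, model, genome)
        assert g.annotations["downstream_inframe_atg"] is True

    def test_no_downstream_atg(self):
        genome = {"chr1": "C" * 100 + "ATGAAAAAATAA" + "C" * 100}
        model = GeneModel({"t": Transcript(
            id="t", gene_id="g", seq_id="chr1", strand="+",
            exons=[(100, 112)], cds=[(100, 112)], canonical=True)})
        g = _guide(108)
        gs = GuideSet([g], ck.builtin_nuclease("SpCas9"))
        ck.add_gene_annotation(gs, model)
        ck.add_downstream_atg_flag(gs, model, genome)
        assert g.annotations["downstream_inframe_atg"] is False

    def test_annotations_are_additive(self):
        model = _single_exon_model()
        g = _guide(150)
        g.annotations["precomputed"] = 42
        before = (g.id, g.spacer, g.pam_coordinate, g.strand, g.start, g.end)
        ck.add_gene_annotation(GuideSet([g], ck.builtin_nuclease("SpCas9")),
                               model)
        assert g.annotations["precomputed"] == 42
        assert (g.id, g.spacer, g.pam_coordinate, g.strand, g.start,
                g.end) == before


class TestTssAnnotation:
    def _table(self, tss, strand):
        return pd.DataFrame([{"gene": "geneA", "seq_id": "chr1",
                              "tss": tss, "strand": strand}])

    def test_cut_100nt_upstream_in_window(self):
        g = _guide(604)  # cut at 600
        ck.add_tss_annotation(GuideSet([g], ck.builtin_nuclease("SpCas9")),
                              self._table(700, "+"))
        assert g.annotations["dist_to_tss"] == -100
        assert g.annotations["tss_in_window"] is True

    def test_cut_downstream_not_in_window(self):
        g = _guide(714)  # cut at 710
        ck.add_tss_annotation(GuideSet([g], ck.builtin_nuclease("SpCas9")),
                              self._table(700, "+"))
        assert g.annotations["dist_to_tss"] == 10
        assert g.annotations["tss_in_window"] is False

    def test_minus_strand_mirror_same_annotation(self):
        g = _guide(804)  # cut at 800, 100 nt upstream of a minus-strand TSS
        ck.add_tss_annotation(GuideSet([g], ck.builtin_nuclease("SpCas9")),
                              self._table(700, "-"))
        assert g.annotations["dist_to_tss"] == -100
        assert g.annotations["tss_in_window"] is True


class TestSnpAnnotation:
    def test_snv_in_protospacer_flagged(self, spcas9):
        g = _guide(100)  # protospacer [80, 100), PAM [100, 103)
        ck.add_snp_annotation(GuideSet([g], spcas9),
                              [Variant("chr1", 90, "rs1", "A", "G", 0.1)])
        assert g.annotations["snp_overlap"] is True
        assert g.annotations["snp_ids"] == "rs1"

    def test_snv_in_pam_flagged(self, spcas9):
        g = _guide(100)
        ck.add_snp_annotation(GuideSet([g], spcas9),
                              [Variant("chr1", 101, "rs2", "A", "G", 0.1)])
        assert g.annotations["snp_overlap"] is True

    def test_distant_snv_not_flagged(self, spcas9):
        g = _guide(100)
        ck.add_snp_annotation(GuideSet([g], spcas9),
                              [Variant("chr1", 113, "rs3", "A", "G", 0.1)])
        assert g.annotations["snp_overlap"] is False


class TestConservation:
    def test_constant_track(self, spcas9):
        g = _guide(100)
        track = {"chr1": np.full(200, 0.5)}
        ck.add_conservation(GuideSet([g], spcas9), track)
        assert g.annotations["conservation_score"] == pytest.approx(0.5)

    def test_half_window_mean(self, spcas9):
        g = _guide(100)  # cut 96, default window [87, 105)
        arr = np.zeros(200)
        arr[:96] = 1.0
        ck.add_conservation(GuideSet([g], spcas9), {"chr1": arr})
        assert g.annotations["conservation_score"] == pytest.approx(0.5)

    def test_missing_bases_excluded_not_imputed(self, spcas9):
        g = _guide(100)
        arr = np.full(200, np.nan)
        arr[87:96] = 1.0  # only half the window covered
        ck.add_conservation(GuideSet([g], spcas9), {"chr1": arr})
        assert g.annotations["conservation_score"] == pytest.approx(1.0)

    def test_fully_missing_window_is_nan(self, spcas9):
        g = _guide(100)
        ck.add_conservation(GuideSet([g], spcas9),
                            {"chr1": np.full(200, np.nan)})
        assert np.isnan(g.annotations["conservation_score"])


class TestInjectAlleles:
    def test_ref_is_major_keeps_genome(self):
        out = ck.inject_alleles({"c": "ACGT"},
                                [Variant("c", 1, "rs1", "C", "A", 0.4)],
                                mode="major")
        assert out["c"] == "ACGT"

    def test_alt_is_major_injected(self):
        out = ck.inject_alleles({"c": "ACGT"},
                                [Variant("c", 1, "rs1", "C", "A", 0.6)],
                                mode="major")
        assert out["c"] == "AAGT"

    def test_minor_mode_injects_minor_allele(self):
        out = ck.inject_alleles({"c": "ACGT"},
                                [Variant("c", 1, "rs1", "C", "A", 0.4)],
                                mode="minor")
        assert out["c"] == "AAGT"

    def test_ref_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="REF mismatch"):
            ck.inject_alleles({"c": "ACGT"},
                              [Variant("c", 1, "rs1", "G", "A", 0.4)])

    def test_indels_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-SNV"):
            out = ck.inject_alleles({"c": "ACGT"},
                                    [Variant("c", 1, "rs1", "CG", "C", 0.9)])
        assert out["c"] == "ACGT"

    def test_major_injection_idempotent_on_major_genome(self):
        # every REF is the major allele, so major-mode injection is a no-op
        # and trivially idempotent
        genome = {"c": "ACGTACGT"}
        variants = [Variant("c", 2, "rs1", "G", "T", 0.3),
                    Variant("c", 5, "rs2", "C", "A", 0.2)]
        once = ck.inject_alleles(genome, variants, mode="major")
        twice = ck.inject_alleles(once, variants, mode="major")
        assert once == twice == genome

    def test_minor_roundtrip_restores_input(self):
        # inject minor alleles, then re-inject records expressed relative to
        # the minor genome with swapped allele frequencies: the original
        # (major-allele) genome comes back
        genome = {"c": "ACGTACGT"}
        variants = [Variant("c", 2, "rs1", "G", "T", 0.3),
                    Variant("c", 5, "rs2", "C", "A", 0.2)]
        minor = ck.inject_alleles(genome, variants, mode="minor")
        assert minor["c"] == "ACTTAAGT"
        assert len(minor["c"]) == len(genome["c"])
        swapped = [Variant("c", 2, "rs1", "T", "G", 0.7),
                   Variant("c", 5, "rs2", "A", "C", 0.8)]
        restored = ck.inject_alleles(minor, swapped, mode="major")
        assert restored["c"] == genome["c"]
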