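import pytest

from fhresponse.errors import (
    ClassificationInputError,
    HGVSParseError,
    UnsupportedGenotypeError,
)
from fhresponse.variants import (
    PVClass,
    PVGroup,
    VariantClass,
    VariantRecord,
    classify_patient,
    classify_variant,
    infer_variant_class,
    parse_hgvs_lite,
)


class TestParseHgvsLite:
    def test_substitution_with_stop_gain(self):
        p = parse_hgvs_lite("c.682G>T", "p.E228X")
        assert p.kind == "substitution"
        assert (p.cdna_position, p.ref, p.alt) == (682, "G", "T")
        assert p.protein_position == 228
        assert p.is_stop_gain

    def test_promoter_offset_substitution(self):
        p = parse_hgvs_lite("c.-136C>T")
        assert p.kind == "substitution"
        assert p.cdna_position == -136

    @pytest.mark.parametrize(
        "protein, stop, fs",
        [
            ("p.G558X", True, False),
            ("p.W23*", True, False),
            ("p.(Gln12Ter)", True, False),
            ("p.C173W", False, False),
            ("p.D221Tfs*2", False, True),
        ],
    )
    def test_protein_stop_and_frameshift_detection(self, protein, stop, fs):
        p = parse_hgvs_lite("c.1G>A", protein)
        assert p.is_stop_gain is stop
        assert p.is_frameshift is fs

    def test_exon_level_rearrangement_free_text(self):
        assert parse_hgvs_lite("CNV, exon 8-12").kind == "large_rearrangement"

    @pytest.mark.parametrize("bad", ["c.682G>", "", "nonsense text"])
    def test_malformed_notation_raises(self, bad):
        with pytest.raises(HGVSParseError):
            parse_hgvs_lite(bad)

    def test_small_indel(self):
        p = parse_hgvs_lite("c.660del", "p.D221Tfs*2")
        assert p.kind == "indel"
        assert infer_variant_class(p) is VariantClass.FRAMESHIFT_INDEL


# The six distinct genotypes of the evolocumab subgroup, with their
# published null/defective assignments.
TABLE_VARIANTS = [
    (VariantRecord("LDLR", "c.682G>T", "p.E228X", "nonsense"), PVClass.NULL),
    (VariantRecord("LDLR", "CNV, exon 8-12", None, "large_rearrangement"), PVClass.NULL),
    (VariantRecord("LDLR", "c.1672G>T", "p.G558X", "nonsense"), PVClass.NULL),
    (VariantRecord("LDLR", "c.519C>G", "p.C173W", "missense"), PVClass.DEFECTIVE),
    (VariantRecord("LDLR", "c.1567G>A", "p.V523M", "missense"), PVClass.DEFECTIVE),
    (VariantRecord("LDLR", "c.-136C>T", None, "promoter_regulatory"), PVClass.DEFECTIVE),
]


class TestClassifyVariant:
    @pytest.mark.parametrize("variant, expected", TABLE_VARIANTS)
    def test_published_genotypes(self, variant, expected):
        assert classify_variant(variant) is expected

    def test_repeat5_missense_is_null(self):
        v = VariantRecord("LDLR", "c.664T>C", "p.C222R", "missense")
        assert classify_variant(v) is PVClass.NULL
        # same variant outside a narrower configured interval -> defective
        assert classify_variant(v, repeat5_range=(195, 210)) is PVClass.DEFECTIVE

    def test_frameshift_and_inframe_indels(self):
        fs = VariantRecord("LDLR", "c.660del", "p.D221Tfs*2", "frameshift_indel")
        inframe = VariantRecord("LDLR", "c.660_662del", "p.D221del", "inframe_indel")
        assert classify_variant(fs) is PVClass.NULL
        assert classify_variant(inframe) is PVClass.DEFECTIVE

    @pytest.mark.parametrize("gene, cdna, prot", [("APOB", "c.10580G>A", "p.R3527Q"), ("PCSK9", "c.1120G>T", "p.D374Y")])
    def test_other_genes_not_applicable(self, gene, cdna, prot):
        v = VariantRecord(gene, cdna, prot, "missense")
        assert classify_variant(v) is PVClass.NOT_APPLICABLE

    def test_class_inferred_from_notation_when_missing(self):
        assert classify_variant(VariantRecord("LDLR", "c.682G>T", "p.E228X")) is PVClass.NULL
        assert classify_variant(VariantRecord("LDLR", "c.-136C>T")) is PVClass.DEFECTIVE

    @pytest.mark.parametrize("vclass", list(VariantClass))
    def test_totality_every_class_gets_one_label(self, vclass):
        v = VariantRecord("LDLR", "c.682G>T", "p.E228W", vclass)
        assert classify_variant(v) in (PVClass.NULL, PVClass.DEFECTIVE)

    def test_unknown_gene_rejected(self):
        with pytest.raises(ClassificationInputError):
            VariantRecord("APOE", "c.1G>A", None, "missense")


class TestClassifyPatient:
    def test_no_variants_is_pv_negative(self):
        g = classify_patient([])
        assert g.group is PVGroup.PV_NEGATIVE
        assert not g.has_any_null

    def test_single_heterozygous_variants(self):
        null = VariantRecord("LDLR", "c.682G>T", "p.E228X", "nonsense")
        defective = VariantRecord("LDLR", "c.519C>G", "p.C173W", "missense")
        other = VariantRecord("PCSK9", "c.1120G>T", "p.D374Y", "missense")
        assert classify_patient([null]).group is PVGroup.LDLR_NULL
        assert classify_patient([defective]).group is PVGroup.LDLR_DEFECTIVE
        assert classify_patient([other]).group is PVGroup.APOB_PCSK9

    def test_compound_null_plus_defective(self):
        g = classify_patient(
            [
                VariantRecord("LDLR", "c.1672G>T", "p.G558X", "nonsense"),
                VariantRecord("LDLR", "c.-136C>T", None, "promoter_regulatory"),
            ]
        )
        assert g.group is PVGroup.COMPOUND_OR_HOMOZYGOUS
        assert g.has_any_null

    def test_compound_two_defective(self):
        g = classify_patient(
            [
                VariantRecord("LDLR", "c.1567G>A", "p.V523M", "missense"),
                VariantRecord("LDLR", "c.-136C>T", None, "promoter_regulatory"),
            ]
        )
        assert g.group is PVGroup.COMPOUND_OR_HOMOZYGOUS
        assert not g.has_any_null

    def test_true_homozygote_counts_two_alleles(self):
        v = VariantRecord("LDLR", "c.519C>G", "p.C173W", "missense", zygosity="homozygous")
        assert classify_patient([v]).group is PVGroup.COMPOUND_OR_HOMOZYGOUS

    def test_more_than_two_alleles_rejected(self):
        v = VariantRecord("LDLR", "c.519C>G", "p.C173W", "missense", zygosity="homozygous")
        het = VariantRecord("LDLR", "c.682G>T", "p.E228X", "nonsense")
        with pytest.raises(UnsupportedGenotypeError):
            classify_patient([v, het])
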