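import pytest
from hypothesis import given
from hypothesis import strategies as st

from tebias.annotations_io import (AnnotationValidationError, GeneRecord,
                                   RegionPartition, TEAnnotations, TERepeat,
                                   assign_chromosomal_region, infer_subgenome,
                                   normalize_intervals, parse_te_code,
                                   read_gene_models, read_region_partition,
                                   read_te_annotations, write_te_table)


class TestParseTECode:
    def test_copia_with_subfamily(self):
        c = parse_te_code("RLC_famc1.6")
        assert (c.class_, c.order, c.superfamily_code) == ("I", "LTR", "RLC")
        assert c.superfamily == "Copia"
        assert c.family == "famc1"
        assert c.subfamily == "6"

    def test_unknown_code_xxx(self):
        c = parse_te_code("XXX_famc13")
        assert (c.class_, c.order, c.superfamily) == ("unknown",) * 3
        assert c.superfamily_code == "XXX"

    def test_helitron(self):
        c = parse_te_code("DHH_fam1")
        assert (c.class_, c.order, c.superfamily) == ("II", "Helitron", "Helitron")

    @pytest.mark.parametrize("code,class_,order,superfamily", [
        ("RLG", "I", "LTR", "Gypsy"),
        ("RLC", "I", "LTR", "Copia"),
        ("RLX", "I", "LTR", "unknown"),
        ("RIX", "I", "LINE", "unknown"),
        ("SIX", "I", "SINE", "unknown"),
        ("DTC", "II", "TIR", "CACTA"),
        ("DTM", "II", "TIR", "Mutator"),
        ("DTX", "II", "TIR", "unknown"),
        ("DTH", "II", "TIR", "Harbinger"),
        ("DTT", "II", "TIR", "Mariner"),
        ("DTA", "II", "TIR", "hAT"),
        ("DXX", "II", "unknown", "unknown"),
        ("DHH", "II", "Helitron", "Helitron"),
        ("XXX", "unknown", "unknown", "unknown"),
    ])
    def test_code_table(self, code, class_, order, superfamily):
        c = parse_te_code(f"{code}_famc2")
        assert c.class_ == class_
        assert c.order == order
        assert c.superfamily == superfamily

    def test_unknown_three_letter_code_preserved(self):
        c = parse_te_code("QQQ_fam9")
        assert c.superfamily_code == "QQQ"
        assert c.class_ == "unknown"

    def test_empty_name_raises(self):
        with pytest.raises(ValueError):
            parse_te_code("")

    @given(st.text(alphabet="RDXLTISH_facmn0123456789.", min_size=1,
                   max_size=20))
    def test_total_and_idempotent(self, name):
        c = parse_te_code(name)
        assert c.superfamily_code
        again = parse_te_code(name)
        assert again == c


class TestReadGeneModels:
    def test_single_gene_two_exons(self, single_gene_gff):
        records, models = read_gene_models(single_gene_gff)
        assert list(records) == ["gene1"]
        g = records["gene1"]
        assert (g.chromosome, g.start, g.stop) == ("chr1A", 100, 200)
        assert g.subgenome == "A"
        assert len(models["gene1"].exons) == 2

    def test_invalid_coordinates_raise(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\n"
                        "chr1A\tsrc\tgene\t300\t200\t.\t+\t.\tID=badgene\n")
        with pytest.raises(AnnotationValidationError) as err:
            read_gene_models(path)
        assert "badgene" in str(err.value)

    def test_twelve_genes_subgenomes_inferred(self, twelve_gene_gff):
        records, _ = read_gene_models(twelve_gene_gff)
        assert len(records) == 12
        for sub in "ABD":
            assert sum(1 for r in records.values() if r.subgenome == sub) == 4

    def test_lc_genes_excluded_by_default(self, tmp_path):
        path = tmp_path / "lc.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1A\tsrc\tgene\t100\t200\t.\t+\t.\tID=hc1;confidence=HC\n"
            "chr1A\tsrc\tgene\t300\t400\t.\t+\t.\tID=lc1;confidence=LC\n")
        records, _ = read_gene_models(path)
        assert set(records) == {"hc1"}
        records, _ = read_gene_models(path, include_lc=True)
        assert set(records) == {"hc1", "lc1"}

    def test_tsv_dialect_roundtrip(self, tmp_path):
        from tebias.annotations_io import write_gene_table
        recs = {"g1": GeneRecord("g1", "1A", "A", 10, 99, "+"),
                "g2": GeneRecord("g2", "2B", "B", 5, 50, "-")}
        path = tmp_path / "genes.tsv"
        write_gene_table(recs, path)
        again, _ = read_gene_models(path)
        assert {g.gene_id: (g.chromosome, g.start, g.stop, g.subgenome)
                for g in again.values()} == \
               {g.gene_id: (g.chromosome, g.start, g.stop, g.subgenome)
                for g in recs.values()}


class TestReadTEAnnotations:
    def test_status_filter_view(self, te_tsv):
        anns = read_te_annotations(te_tsv)
        assert len(anns.all) == 3
        assert len(anns.repeat_regions) == 1
        assert anns.n_removed == 2
        assert anns.repeat_regions[0].te_id == "t1"

    def test_superfamily_from_name(self, te_tsv):
        anns = read_te_annotations(te_tsv)
        assert anns.all[0].classification.superfamily_code == "DTT"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        anns = read_te_annotations(path)
        assert anns.all == []

    def test_roundtrip(self, te_tsv, tmp_path):
        anns = read_te_annotations(te_tsv)
        out = tmp_path / "roundtrip.tsv"
        write_te_table(anns, out)
        again = read_te_annotations(out)
        assert again.to_frame().equals(anns.to_frame())

    def test_partition_invariant(self, te_tsv):
        anns = read_te_annotations(te_tsv)
        assert len(anns.repeat_regions) + anns.n_removed == len(anns.all)

    def test_te_start_after_stop_raises(self):
        with pytest.raises(ValueError):
            TERepeat("t", "1A", 50, 10, "repeat_region", "DTT_fam1")


class TestRegionPartition:
    def test_midpoint_in_c_is_proximal(self, partition_5regions):
        g = GeneRecord("g", "chr1A", "A", 450, 550)
        assert assign_chromosomal_region(g, partition_5regions) == "C"
        assert partition_5regions.macro("C") == "proximal"

    def test_midpoint_in_r1_is_distal(self, partition_5regions):
        g = GeneRecord("g", "chr1A", "A", 50, 150)
        assert assign_chromosomal_region(g, partition_5regions) == "R1"
        assert partition_5regions.macro("R1") == "distal"

    def test_boundary_goes_left(self, partition_5regions):
        # midpoint (floor) == 200 == last base of R1
        g = GeneRecord("g", "chr1A", "A", 150, 251)
        assert g.midpoint == 200
        assert assign_chromosomal_region(g, partition_5regions) == "R1"

    def test_missing_chromosome_named_in_error(self, partition_5regions):
        g = GeneRecord("g", "chr9D", "D", 10, 20)
        with pytest.raises(KeyError, match="chr9D"):
            assign_chromosomal_region(g, partition_5regions)

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            RegionPartition({"c": [("R1", 1, 100), ("C", 150, 300)]})

    def test_read_tsv(self, tmp_path, partition_5regions):
        path = tmp_path / "regions.tsv"
        partition_5regions.to_frame().to_csv(path, sep="\t", index=False)
        again = read_region_partition(path)
        assert again.region_at("chr1A", 500) == "C"


class TestHelpers:
    def test_infer_subgenome(self):
        assert infer_subgenome("chr5A") == "A"
        assert infer_subgenome("3D") == "D"
        assert infer_subgenome("chrUn") is None

    def test_normalize_intervals_merges(self):
        assert normalize_intervals([(10, 20), (15, 30), (40, 50)]) == \
            [(10, 30), (40, 50)]

    def test_gene_record_validates(self):
        with pytest.raises(ValueError):
            GeneRecord("g", "1A", "A", 100, 50)
        with pytest.raises(ValueError):
            GeneRecord("g", "1A", "Z", 1, 50)
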