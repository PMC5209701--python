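"""Format round-trips, coordinate conventions and malformed-input reporting."""

import pytest

from repeathet import genomeio
from repeathet.genomeio import (
    BedRecord,
    FormatError,
    GeneModel,
    GenomicInterval,
    RepeatLocus,
)
from repeathet.rescue import ExpressionRecord


class TestGenomicInterval:
    def test_half_open_length(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length == 100

    @pytest.mark.parametrize("start,end", [(5, 5), (10, 3), (-1, 10)])
    def test_degenerate_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_overlap_zero_across_chromosomes(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr2", 0, 100)
        assert a.overlap_bp(b) == 0


class TestBed:
    def test_bed6_line_parses_verbatim(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tr1\t0\t+\n")
        (rec,) = genomeio.read_bed(p)
        assert rec.interval == GenomicInterval("chr1", 100, 200, "+")
        assert rec.name == "r1"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert genomeio.read_bed(p) == []

    @pytest.mark.parametrize(
        "line",
        ["chr1\t100\t100\tx\t0\t+", "chr1\tabc\t200", "chr1\t100", "chr1\t100\t200\tx\t0\t?"],
    )
    def test_malformed_line_reports_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t50\n" + line + "\n")
        with pytest.raises(FormatError) as err:
            genomeio.read_bed(p)
        assert err.value.line == 2

    def test_chrom_size_table_enforced(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrUn\t0\t50\n")
        with pytest.raises(FormatError):
            genomeio.read_bed(p, chrom_sizes={"chr1": 1000})

    def test_round_trip(self, tmp_path):
        records = [
            BedRecord(GenomicInterval("chr1", 0, 50, "+"), "a", 1.0),
            BedRecord(GenomicInterval("chr2", 10, 500, "-"), "b", 0.0),
        ]
        p = tmp_path / "rt.bed"
        genomeio.write_bed(records, p)
        assert genomeio.read_bed(p) == records


class TestRmsk:
    def _write(self, tmp_path, rows):
        p = tmp_path / "rep.tsv"
        header = "genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n"
        p.write_text(header + "".join(rows))
        return p

    def test_zero_based_coordinates_kept(self, tmp_path):
        p = self._write(tmp_path, ["chr2\t5000\t5300\t+\tID_B1\tSINE\tAlu\n"])
        (locus,) = genomeio.read_rmsk(p)
        assert locus.interval.length == 300
        assert (locus.rep_name, locus.rep_class, locus.rep_family) == ("ID_B1", "SINE", "Alu")

    def test_id_synthesis_distinguishes_same_coords_different_name(self, tmp_path):
        p = self._write(
            tmp_path,
            ["chr1\t100\t400\t+\tA\tSINE\tAlu\n", "chr1\t100\t400\t+\tB\tLINE\tL1\n"],
        )
        loci = genomeio.read_rmsk(p)
        assert len({l.locus_id for l in loci}) == 2

    def test_missing_column_is_an_error(self, tmp_path):
        p = tmp_path / "rep.tsv"
        p.write_text("genoName\tgenoStart\tgenoEnd\n" "chr1\t0\t10\n")
        with pytest.raises(FormatError):
            genomeio.read_rmsk(p)

    def test_class_filter(self, tmp_path):
        p = self._write(
            tmp_path,
            ["chr1\t100\t400\t+\tA\tSINE\tAlu\n", "chr1\t600\t900\t+\tB\tLINE\tL1\n"],
        )
        loci = genomeio.read_rmsk(p, keep_classes=["LINE"])
        assert [l.rep_name for l in loci] == ["B"]

    def test_round_trip_preserves_all_fields(self, tmp_path):
        loci = [
            RepeatLocus(GenomicInterval("chr1", 10, 400, "+"), "r0", "B1", "SINE", "Alu"),
            RepeatLocus(GenomicInterval("chr2", 0, 5000, "-"), "r1", "L1", "LINE", "L1"),
        ]
        p = tmp_path / "rt.tsv"
        genomeio.write_rmsk(loci, p)
        assert genomeio.read_rmsk(p) == loci


class TestGeneAndAssociationTables:
    def test_gene_round_trip(self, tmp_path):
        genes = [
            GeneModel("g1", "Pgc1a", GenomicInterval("chr1", 1000, 9000, "+")),
            GeneModel("g2", "Acadm", GenomicInterval("chr2", 500, 800, "-")),
        ]
        p = tmp_path / "genes.tsv"
        genomeio.write_gene_table(genes, p)
        assert genomeio.read_gene_table(p) == genes

    def test_inverted_gene_coordinates_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tsymbol\tchrom\tstrand\ttxStart\ttxEnd\ng1\tX\tchr1\t+\t900\t100\n")
        with pytest.raises(FormatError):
            genomeio.read_gene_table(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text(
            "gene_id\tsymbol\tchrom\tstrand\ttxStart\ttxEnd\n"
            "g1\tX\tchr1\t+\t100\t900\ng1\tY\tchr1\t+\t100\t900\n"
        )
        with pytest.raises(FormatError):
            genomeio.read_gene_table(p)

    def test_association_deduplicates_repeated_pairs(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("gene_id\tterm_id\ng1\tmito\ng1\tmito\ng2\tmito\n")
        assoc, _ = genomeio.read_go_association(p)
        assert assoc == {"g1": {"mito"}, "g2": {"mito"}}

    def test_expression_round_trip_and_negative_rejected(self, tmp_path):
        records = [ExpressionRecord("g1", "Myh6", 100.0, 110.0, 20.0, 32.0)]
        p = tmp_path / "expr.tsv"
        genomeio.write_expression(records, p)
        (back,) = genomeio.read_expression(p)
        assert back == records[0]
        p.write_text(
            "gene_id\tsymbol\texpr_NS\texpr_NSch\texpr_HS\texpr_HSch\ng1\tX\t-1\t0\t0\t0\n"
        )
        with pytest.raises(FormatError):
            genomeio.read_expression(p)


def test_simulated_dataset_reparses_losslessly(small_exact_dataset, tmp_path):
    """Everything the generator writes comes back through the readers intact."""
    ds = small_exact_dataset
    paths = ds.write(tmp_path / "sim")
    assert genomeio.read_rmsk(paths["repeats_rmsk"]) == ds.repeats
    assert genomeio.read_gene_table(paths["genes"]) == ds.genes
    assoc, names = genomeio.read_go_association(paths["association"])
    assert assoc == ds.association
    assert names == ds.term_names
    assert genomeio.read_expression(paths["expression"]) == ds.expression
    for role in ("input", "ctrl", "hf", "treat"):
        reads = genomeio.read_reads(paths[f"reads_{role}"], role)
        assert [r.interval for r in reads] == [r.interval for r in ds.reads[role]]
    sizes = genomeio.read_chrom_sizes(paths["chrom_sizes"])
    assert sizes == ds.chrom_sizes
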