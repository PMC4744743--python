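"""File readers/writers: VCF, depth tables, array tables, pedigree,
unified dataset TSV, gene models."""

import numpy as np
import pytest

from autozygmap.dataset import build_unified_dataset
from autozygmap.errors import DataFormatError
from autozygmap.formats import (
    PedigreeRecord, pair_vcf_and_depth_files, read_array_genotypes,
    read_depth_file, read_gene_models, read_pedigree, read_unified_dataset,
    read_vcf, write_pedigree, write_unified_dataset,
)


class TestReadVcf:
    def test_field_mapping(self, write_vcf):
        path = write_vcf("a.vcf", ["1\t1000\trs123\tA\tG\t.\t.\t.\tGT:AD\t0/1:12,14"])
        records, sample = read_vcf(path)
        assert sample == "S1"
        (rec,) = records
        assert (rec.chrom, rec.pos, rec.id, rec.ref, rec.alt) == ("1", 1000, "rs123", "A", "G")
        assert (rec.ref_depth, rec.alt_depth) == (12, 14)
        assert rec.declared_genotype == "0/1"

    def test_empty_body(self, write_vcf):
        assert read_vcf(write_vcf("e.vcf", []))[0] == []

    def test_multiallelic_split_shares_ref_depth(self, write_vcf):
        path = write_vcf("m.vcf", ["1\t500\t.\tA\tG,T\t.\t.\t.\tGT:AD\t1/2:10,5,5"])
        records, _ = read_vcf(path)
        assert [(r.alt, r.ref_depth, r.alt_depth) for r in records] == \
            [("G", 10, 5), ("T", 10, 5)]

    def test_output_sorted_and_chr_prefix_stripped(self, write_vcf):
        path = write_vcf("s.vcf", [
            "2\t100\t.\tA\tC\t.\t.\t.\tGT:AD\t0/1:5,5",
            "1\t900\t.\tG\tT\t.\t.\t.\tGT:AD\t0/1:5,5",
            "1\t200\t.\tG\tA\t.\t.\t.\tGT:AD\t0/1:5,5",
        ])
        records, _ = read_vcf(path)
        assert [(r.chrom, r.pos) for r in records] == [("1", 200), ("1", 900), ("2", 100)]

    def test_missing_ad_is_flagged_not_dropped(self, write_vcf):
        path = write_vcf("f.vcf", [
            "1\t100\t.\tA\tC\t.\t.\t.\tGT:AD\t0/1:5,5",
            "1\t200\t.\tG\tA\t.\t.\t.\tGT\t0/1",
        ])
        records, _ = read_vcf(path)
        assert len(records) == 2
        flagged = [r for r in records if r.depth_missing]
        assert [r.pos for r in flagged] == [200]

    def test_no_depths_anywhere_is_hard_error(self, tmp_path, write_vcf):
        path = write_vcf("bad.vcf", ["1\t100\t.\tA\tC\t.\t.\t.\tGT\t0/1"])
        with pytest.raises(DataFormatError, match="bad.vcf"):
            read_vcf(path)

    def test_multisample_rejected(self, tmp_path):
        path = tmp_path / "two.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
        )
        with pytest.raises(DataFormatError, match="single-sample"):
            read_vcf(path)


class TestDepthFiles:
    def test_row_parse_and_header_skip(self, tmp_path):
        path = tmp_path / "d.txt"
        path.write_text("Locus\tTotal_Depth\tAverage\nchr2:500\t37\t37.0\n1:10\t5\t5.0\n")
        table = read_depth_file(path)
        assert table.depths[("2", 500)] == 37      # chr prefix normalised
        assert table.get("chr1", 10) == 5

    def test_header_only(self, tmp_path):
        path = tmp_path / "h.txt"
        path.write_text("Locus\tTotal_Depth\n")
        assert read_depth_file(path).depths == {}

    def test_bad_locus_reports_line_number(self, tmp_path):
        path = tmp_path / "b.txt"
        path.write_text("Locus\tTotal_Depth\n1:10\t5\nnot-a-locus\t3\n")
        with pytest.raises(DataFormatError, match="line 3"):
            read_depth_file(path)

    def test_duplicate_last_wins(self, tmp_path, caplog):
        path = tmp_path / "dup.txt"
        path.write_text("1:10\t5\n1:10\t9\n")
        with caplog.at_level("WARNING"):
            table = read_depth_file(path)
        assert table.depths[("1", 10)] == 9
        assert "duplicate" in caplog.text

    def test_large_table_spot_checked(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = [(int(p), int(d)) for p, d in
                zip(rng.choice(10**6, size=1000, replace=False), rng.integers(0, 200, 1000))]
        path = tmp_path / "big.txt"
        path.write_text("".join(f"1:{p}\t{d}\n" for p, d in rows))
        table = read_depth_file(path)
        assert len(table.depths) == 1000
        for p, d in (rows[17], rows[500], rows[-1]):
            assert table.depths[("1", p)] == d


class TestPairing:
    def test_pairs_and_unpaired_txt_logged(self, tmp_path, caplog):
        for name in ("a.vcf", "a.txt", "b.vcf", "stray.txt"):
            (tmp_path / name).touch()
        with caplog.at_level("WARNING"):
            pairs = pair_vcf_and_depth_files(tmp_path)
        assert [(v.name, d.name if d else None) for v, d in pairs] == \
            [("a.vcf", "a.txt"), ("b.vcf", None)]
        assert "stray.txt" in caplog.text

    def test_no_vcfs_is_error(self, tmp_path):
        (tmp_path / "a.txt").touch()
        with pytest.raises(DataFormatError, match="no VCF files"):
            pair_vcf_and_depth_files(tmp_path)


class TestArrayGenotypes:
    def _write(self, tmp_path, rows, header="marker\tchrom\tpos\tS1\tS2"):
        path = tmp_path / "array.tsv"
        path.write_text(header + "\n" + "".join(r + "\n" for r in rows))
        return path

    def test_basic_table(self, tmp_path):
        path = self._write(tmp_path, [
            "m1\t1\t100\tAA\tAB",
            "m3\t1\t900\tBB\tNC",
            "m2\t1\t400\t--\tNoCall",
        ])
        table = read_array_genotypes(path, n_snps_on_design=20_000)
        assert table.positions.tolist() == [100, 400, 900]    # sorted by position
        assert table.states("S1") == ["AA", "NC", "BB"]       # "--" normalised
        assert table.states("S2") == ["AB", "NC", "NC"]
        assert table.n_snps == 20_000

    def test_small_design_rejected(self, tmp_path):
        path = self._write(tmp_path, ["m1\t1\t100\tAA\tAA"])
        with pytest.raises(DataFormatError, match="10,?000|10000"):
            read_array_genotypes(path, n_snps_on_design=9000)

    def test_unknown_token_rejected(self, tmp_path):
        path = self._write(tmp_path, ["m1\t1\t100\tAA\tZZ"])
        with pytest.raises(DataFormatError, match="ZZ"):
            read_array_genotypes(path, n_snps_on_design=20_000)


class TestPedigree:
    def test_round_trip(self, tmp_path):
        records = [
            PedigreeRecord("P1", status="unaffected", sources=("exome",)),
            PedigreeRecord("P2", status="unaffected", sources=("exome", "array")),
            PedigreeRecord("C1", "P1", "P2", status="affected", sources=("exome",)),
        ]
        path = tmp_path / "ped.tsv"
        write_pedigree(records, path)
        assert read_pedigree(path) == records

    def test_unknown_parent_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("C1\tP1\tP9\taffected\texome\nP1\t.\t.\tunaffected\texome\n")
        with pytest.raises(DataFormatError, match="P9"):
            read_pedigree(path)


class TestUnifiedDatasetTsv:
    def _dataset(self, write_vcf, quartet_pedigree):
        paths = {
            "C1": write_vcf("c1.vcf", [
                "1\t100\trs5\tA\tG\t.\t.\t.\tGT:AD\t1/1:0,30",
                "1\t700\t.\tT\tC\t.\t.\t.\tGT:AD\t0/1:15,15",
            ], sample="C1"),
            "P1": write_vcf("p1.vcf", [
                "1\t100\trs5\tA\tG\t.\t.\t.\tGT:AD\t0/1:14,16",
            ], sample="P1"),
        }
        records = {}
        for sid, p in paths.items():
            recs, _ = read_vcf(p)
            records[sid] = recs
        return build_unified_dataset(records, {}, quartet_pedigree)

    def test_round_trip_identity(self, tmp_path, write_vcf, quartet_pedigree):
        ds = self._dataset(write_vcf, quartet_pedigree)
        path = tmp_path / "unified.tsv"
        write_unified_dataset(ds, path)
        back = read_unified_dataset(path)
        assert back.sample_ids == ds.sample_ids
        assert back.sites.equals(ds.sites)
        assert (back.states == ds.states).all()
        # re-export reproduces identical bytes
        path2 = tmp_path / "unified2.tsv"
        write_unified_dataset(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_no_call_token_in_column(self, tmp_path, write_vcf, quartet_pedigree):
        ds = self._dataset(write_vcf, quartet_pedigree)
        path = tmp_path / "unified.tsv"
        write_unified_dataset(ds, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "#chrom\tpos\trsid\tref\talt\tC1\tP1"
        # P1 has no call at 1:700 (absent from VCF, no depth table)
        row = [l for l in lines if l.startswith("1\t700")][0]
        assert row.split("\t")[6] == "NC"


class TestGeneModels:
    def test_two_exon_plus_strand(self, toy_gene):
        refflat, fasta, cds = toy_gene
        records, fetch = read_gene_models(refflat, fasta)
        (rec,) = records
        assert rec.valid and rec.exons == [(10, 31), (60, 72)]
        assert fetch("1", 10, 13) == "ATG"

    def test_minus_strand_exons_stay_in_genomic_order(self, tmp_path):
        path = tmp_path / "g.refFlat"
        path.write_text("G1\tT1\tchr3\t-\t100\t500\t100\t500\t2\t100,300,\t200,500,\n")
        records, _ = read_gene_models(path)
        (rec,) = records
        assert rec.strand == "-" and rec.exons == [(100, 200), (300, 500)]
        assert rec.chrom == "3"

    def test_cds_outside_exons_flagged(self, tmp_path):
        path = tmp_path / "g.refFlat"
        path.write_text("G1\tT1\t1\t+\t100\t200\t50\t150\t1\t100,\t200,\n")
        records, _ = read_gene_models(path)
        assert not records[0].valid
        assert any("CDS" in issue for issue in records[0].issues)

    def test_malformed_exon_list_names_transcript(self, tmp_path):
        path = tmp_path / "g.refFlat"
        path.write_text("G1\tTX9\t1\t+\t100\t200\t100\t200\t2\t100,\t200,\n")
        with pytest.raises(DataFormatError, match="TX9"):
            read_gene_models(path)

    def test_chrom_missing_from_fasta_flagged(self, toy_gene, tmp_path):
        _refflat, fasta, _cds = toy_gene
        path = tmp_path / "g2.refFlat"
        path.write_text("G1\tT1\t99\t+\t10\t72\t10\t72\t1\t10,\t72,\n")
        records, _ = read_gene_models(path, fasta)
        assert not records[0].valid
        assert any("FASTA" in issue for issue in records[0].issues)
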