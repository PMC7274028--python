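import pytest

from varscope.errors import (
    ContigError,
    ParseError,
    RangeError,
    ReservedNameError,
    UnknownSampleError,
    ValidationError,
)
from varscope.io import (
    GenotypeCall,
    GTClass,
    parse_gff3,
    read_fasta_region,
    read_sample_catalog,
    read_variants,
    validate_instance,
)
from varscope.query import RegionQuery

from .oracles import scan_vcf_text


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "ref.fa"
    path.write_text(">1A\nACGTACGT\n")
    return str(path)


class TestReadFastaRegion:
    def test_inner_slice(self, small_fasta):
        assert read_fasta_region(small_fasta, "1A", 3, 6) == "GTAC"

    def test_identity(self, small_fasta):
        assert read_fasta_region(small_fasta, "1A", 1, 8) == "ACGTACGT"

    def test_out_of_bounds(self, small_fasta):
        with pytest.raises(RangeError):
            read_fasta_region(small_fasta, "1A", 7, 10)

    def test_unknown_contig(self, small_fasta):
        with pytest.raises(ContigError):
            read_fasta_region(small_fasta, "9Z", 1, 2)

    def test_single_base_property(self, small_fasta):
        contig = "ACGTACGT"
        for k in range(1, 9):
            assert read_fasta_region(small_fasta, "1A", k, k) == contig[k - 1]


class TestGenotypeCall:
    @pytest.mark.parametrize(
        "gt,klass",
        [
            ("0/0", GTClass.REF_HOM),
            ("0/1", GTClass.HET),
            ("1/0", GTClass.HET),
            ("1/1", GTClass.ALT_HOM),
            ("2/2", GTClass.ALT_HOM),
            ("1/2", GTClass.HET),
            ("./.", GTClass.MISSING),
            ("./1", GTClass.MISSING),
            (".", GTClass.MISSING),
        ],
    )
    def test_class_from_alleles(self, gt, klass):
        assert GenotypeCall.from_string(gt).klass is klass

    def test_phase_recorded_not_classifying(self):
        call = GenotypeCall.from_string("1|1")
        assert call.phased and call.klass is GTClass.ALT_HOM
        assert GenotypeCall.from_string("1|0").state_key() == "0/1"

    def test_haploid_promoted(self):
        assert GenotypeCall.from_indices((1,)).klass is GTClass.ALT_HOM


GFF_OK = """##gff-version 3
1A\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1
1A\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=m1;Parent=g1
1A\tsrc\texon\t1000\t2000\t.\t+\t.\tID=m1.e1;Parent=m1
1A\tsrc\tCDS\t1100\t1900\t.\t+\t0\tID=m1.c1;Parent=m1
"""

GFF_MINUS = """##gff-version 3
1A\tsrc\tgene\t100\t399\t.\t-\t.\tID=g2
1A\tsrc\tmRNA\t100\t399\t.\t-\t.\tID=m2;Parent=g2
1A\tsrc\texon\t300\t399\t.\t-\t.\tID=m2.e1;Parent=m2
1A\tsrc\texon\t100\t199\t.\t-\t.\tID=m2.e2;Parent=m2
"""

GFF_ORPHAN_CDS = """##gff-version 3
1A\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1
1A\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=m1;Parent=g1
1A\tsrc\tCDS\t1100\t1900\t.\t+\t0\tID=c1;Parent=mX
"""

GFF_DUP_GENE = """##gff-version 3
1A\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1
1A\tsrc\tgene\t3000\t4000\t.\t+\t.\tID=g1
"""


class TestParseGff3:
    def test_single_gene(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(GFF_OK)
        models, index = parse_gff3(str(path))
        assert len(models) == 1
        m = models[0]
        assert m.exons == [(1000, 2000)]
        assert m.cds == [(1100, 1900, 0)]
        span = index["g1"]
        assert (span.chrom, span.start, span.end, span.strand) == ("1A", 1000, 2000, "+")

    def test_minus_strand_exons_sorted(self, tmp_path):
        path = tmp_path / "b.gff3"
        path.write_text(GFF_MINUS)
        models, _ = parse_gff3(str(path))
        assert models[0].strand == "-"
        assert models[0].exons == [(100, 199), (300, 399)]

    def test_orphan_cds(self, tmp_path):
        path = tmp_path / "c.gff3"
        path.write_text(GFF_ORPHAN_CDS)
        with pytest.raises(ParseError):
            parse_gff3(str(path))

    def test_duplicate_gene_id(self, tmp_path):
        path = tmp_path / "d.gff3"
        path.write_text(GFF_DUP_GENE)
        with pytest.raises(ValidationError):
            parse_gff3(str(path))


VCF_SMALL = """##fileformat=VCFv4.2
##contig=<ID=1A,length=100>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1A\t5\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1
1A\t15\t.\tC\tG\t.\tPASS\t.\tGT\t1|1\t./.
1A\t25\t.\tG\tA,C\t.\tPASS\t.\tGT\t1/2\t0/0
"""


@pytest.fixture
def small_vcf(tmp_path):
    path = tmp_path / "v.vcf"
    path.write_text(VCF_SMALL)
    return str(path)


class TestReadVariants:
    def test_interval_membership(self, small_vcf):
        recs = read_variants(small_vcf, RegionQuery("1A", 10, 20))
        assert [r.pos for r in recs] == [15]

    def test_phased_alt_hom(self, small_vcf):
        rec = read_variants(small_vcf, RegionQuery("1A", 15, 15))[0]
        call = rec.calls["s1"]
        assert call.klass is GTClass.ALT_HOM and call.phased

    def test_multiallelic_kept_single_record(self, small_vcf):
        rec = read_variants(small_vcf, RegionQuery("1A", 25, 25))[0]
        assert rec.alts == ("A", "C")
        assert rec.calls["s1"].klass is GTClass.HET

    def test_unknown_sample(self, small_vcf):
        with pytest.raises(UnknownSampleError):
            read_variants(small_vcf, None, ["nope"])

    def test_partition_equals_whole(self, fx):
        whole = read_variants(fx.paths["vcf"], RegionQuery("1A", 1, 3000))
        parts = []
        for lo, hi in [(1, 400), (401, 1100), (1101, 3000)]:
            parts.extend(read_variants(fx.paths["vcf"], RegionQuery("1A", lo, hi)))
        assert [(r.pos, r.ref, r.alts) for r in whole] == [
            (r.pos, r.ref, r.alts) for r in parts
        ]

    def test_against_text_scan(self, fx):
        _, text_records = scan_vcf_text(fx.paths["vcf"])
        expected = [r for r in text_records if r["chrom"] == "1B"]
        got = read_variants(fx.paths["vcf"], RegionQuery("1B", 1, 10**9))
        assert [(r.pos, r.ref) for r in got] == [
            (r["pos"], r["ref"]) for r in expected
        ]

    def test_symbolic_alt_skipped(self, tmp_path):
        path = tmp_path / "sym.vcf"
        path.write_text(
            VCF_SMALL.replace("1A\t15\t.\tC\tG", "1A\t15\t.\tC\t<DEL>")
        )
        recs = read_variants(str(path), RegionQuery("1A", 1, 100))
        assert [r.pos for r in recs] == [5, 25]


SAMPLES_TSV = (
    "vcfID\taccessionName\tdisplayName\tnote\n"
    "sampleA_run1\tS01\tChinese Spring\tfirst\n"
    "sampleB_run1\tS02\tAccession Two\t\n"
    "sampleC_run1\tS03\t\t\n"
)


class TestReadSampleCatalog:
    def test_direct_parse(self, tmp_path):
        sp = tmp_path / "s.tsv"
        sp.write_text(SAMPLES_TSV)
        gp = tmp_path / "g.tsv"
        gp.write_text("landrace\tS01,S02\n")
        cat = read_sample_catalog(str(sp), str(gp))
        assert len(cat.entries) == 3
        assert cat.groups == {"landrace": ["S01", "S02"]}
        assert cat.display_of("S01") == "Chinese Spring"
        assert cat.display_of("S03") == "S03"  # fallback
        assert cat.entry("S01").meta["note"] == "first"

    def test_reserved_raw(self, tmp_path):
        sp = tmp_path / "s.tsv"
        sp.write_text(SAMPLES_TSV.replace("S03", "#RAW"))
        with pytest.raises(ReservedNameError):
            read_sample_catalog(str(sp))

    def test_reserved_all_group(self, tmp_path):
        sp = tmp_path / "s.tsv"
        sp.write_text(SAMPLES_TSV)
        gp = tmp_path / "g.tsv"
        gp.write_text("ALL\tS01\n")
        with pytest.raises(ReservedNameError):
            read_sample_catalog(str(sp), str(gp))

    def test_duplicate_accession(self, tmp_path):
        sp = tmp_path / "s.tsv"
        sp.write_text(SAMPLES_TSV.replace("S02", "S01"))
        with pytest.raises(ValidationError):
            read_sample_catalog(str(sp))

    def test_unknown_group_member(self, tmp_path):
        sp = tmp_path / "s.tsv"
        sp.write_text(SAMPLES_TSV)
        gp = tmp_path / "g.tsv"
        gp.write_text("landrace\tS01,S99\n")
        with pytest.raises(ValidationError):
            read_sample_catalog(str(sp), str(gp))

    def test_coordinates_parsed(self, fx, catalog):
        entry = catalog.entry("S01")
        assert entry.latitude is not None and -90 <= entry.latitude <= 90
        assert entry.longitude is not None and -180 <= entry.longitude <= 180


class TestValidateInstance:
    def test_consistent_fixture(self, fx):
        report = validate_instance(
            fx.paths["vcf"], fx.paths["fasta"], fx.paths["gff"],
            fx.paths["samples"], fx.paths["groups"],
        )
        assert report.ok
        assert not report.errors()

    def test_contig_mismatch(self, fx, tmp_path):
        bad_fa = tmp_path / "only1a.fa"
        with open(fx.paths["fasta"]) as fh:
            content = fh.read()
        bad_fa.write_text(content.split(">1B")[0])
        report = validate_instance(
            fx.paths["vcf"], str(bad_fa), fx.paths["gff"],
            fx.paths["samples"], fx.paths["groups"],
        )
        assert not report.ok
        assert any(f.code == "contig-mismatch" for f in report.errors())

    def test_missing_ann_is_warning(self, tmp_path, fx):
        vp = tmp_path / "noann.vcf"
        vp.write_text(VCF_SMALL)
        fa = tmp_path / "r.fa"
        fa.write_text(">1A\n" + "A" * 100 + "\n")
        sp = tmp_path / "s.tsv"
        sp.write_text(
            "vcfID\taccessionName\tdisplayName\ns1\tS01\tOne\ns2\tS02\tTwo\n"
        )
        report = validate_instance(str(vp), str(fa), fx.paths["gff"], str(sp))
        assert report.ok
        assert any(f.code == "no-ann" for f in report.warnings())

    def test_unknown_vcf_id(self, tmp_path, fx):
        vp = tmp_path / "v.vcf"
        vp.write_text(VCF_SMALL)
        fa = tmp_path / "r.fa"
        fa.write_text(">1A\n" + "A" * 100 + "\n")
        sp = tmp_path / "s.tsv"
        sp.write_text("vcfID\taccessionName\tdisplayName\nzz\tS01\tOne\n")
        report = validate_instance(str(vp), str(fa), fx.paths["gff"], str(sp))
        assert any(f.code == "unknown-vcf-id" for f in report.errors())
        assert any(f.code == "uncatalogued-sample" for f in report.warnings())
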