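import itertools

import pytest

from varscope.effects import (
    CODON_TABLE,
    annotate_variant,
    effective_annotations,
    group_frequencies,
    lollipop_data,
    most_severe,
    parse_ann_field,
    severity_rank,
)
from varscope.errors import ParameterError
from varscope.genotype import GenotypeMatrix, SiteInfo
from varscope.io import GenotypeCall, TranscriptModel, VariantRecord
from varscope.query import RegionQuery

from .oracles import classify_substitution

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def record(pos, ref, alt, chrom="c"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=(alt,),
        calls={"s": GenotypeCall((1, 1))},
    )


def fetch_from(seq, offset=0):
    """reference_fetch over a string laid out at 1-based position offset+1."""

    def fetch(chrom, start, end):
        return seq[start - 1 - offset : end - offset]

    return fetch


def single_codon_transcript(strand):
    # 9-bp contig; exon 1-9, CDS 4-6 (one codon)
    return TranscriptModel(
        gene_id="g", transcript_id="m", chrom="c", strand=strand,
        exons=[(1, 9)], cds=[(4, 6, 0)],
    )


class TestCodonClassification:
    def test_missense_example(self):
        # codon ATG, third base G->A on + strand => ATA (M -> I)
        seq = "NNN" + "ATG" + "NNN"
        tx = single_codon_transcript("+")
        anns = annotate_variant(record(6, "G", "A"), [tx], fetch_from(seq))
        assert anns[0].effect_class == "missense"
        assert anns[0].aa_change == "M1I"

    def test_synonymous_example(self):
        seq = "NNN" + "GGA" + "NNN"
        tx = single_codon_transcript("+")
        anns = annotate_variant(record(6, "A", "G"), [tx], fetch_from(seq))
        assert anns[0].effect_class == "synonymous"

    def test_stop_gained_example(self):
        seq = "NNN" + "CAG" + "NNN"
        tx = single_codon_transcript("+")
        anns = annotate_variant(record(4, "C", "T"), [tx], fetch_from(seq))
        assert anns[0].effect_class == "stop_gained"

    def test_stop_lost(self):
        seq = "NNN" + "TAA" + "NNN"
        tx = single_codon_transcript("+")
        anns = annotate_variant(record(6, "A", "C"), [tx], fetch_from(seq))
        assert anns[0].effect_class == "stop_lost"

    def test_exhaustive_both_strands(self):
        """All 64 codons x 3 positions x 3 alts, on + and - strand, against
        the Biopython translation oracle."""
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            for k in range(3):
                for alt in BASES:
                    if alt == codon[k]:
                        continue
                    expected = classify_substitution(
                        codon, codon[:k] + alt + codon[k + 1 :]
                    )
                    # plus strand: genome carries the codon directly
                    seq = "AAA" + codon + "AAA"
                    tx = single_codon_transcript("+")
                    anns = annotate_variant(
                        record(4 + k, codon[k], alt), [tx], fetch_from(seq)
                    )
                    assert anns[0].effect_class == expected, (codon, k, alt, "+")
                    # minus strand: genome carries the reverse complement
                    rc = "".join(COMP[b] for b in reversed(codon))
                    seq = "AAA" + rc + "AAA"
                    tx = single_codon_transcript("-")
                    gpos = 6 - k  # coding index k maps to genomic 6-k
                    anns = annotate_variant(
                        record(gpos, COMP[codon[k]], COMP[alt]),
                        [tx],
                        fetch_from(seq),
                    )
                    assert anns[0].effect_class == expected, (codon, k, alt, "-")


TWO_EXON = TranscriptModel(
    gene_id="g", transcript_id="m", chrom="c", strand="+",
    exons=[(11, 40), (61, 90)], cds=[(21, 40, 0), (61, 80, 0)],
)


class TestNonCodingClasses:
    SEQ = "A" * 100

    def test_splice_region_window(self):
        # intron is 41..60; bases 41,42 and 59,60 are splice region
        for pos in (41, 42, 59, 60):
            anns = annotate_variant(record(pos, "A", "G"), [TWO_EXON], fetch_from(self.SEQ))
            assert anns[0].effect_class == "splice_region", pos
        anns = annotate_variant(record(50, "A", "G"), [TWO_EXON], fetch_from(self.SEQ))
        assert anns[0].effect_class == "intron"

    def test_non_coding_exon(self):
        anns = annotate_variant(record(15, "A", "G"), [TWO_EXON], fetch_from(self.SEQ))
        assert anns[0].effect_class == "non_coding_exon"

    def test_intergenic(self):
        anns = annotate_variant(record(99, "A", "G"), [TWO_EXON], fetch_from(self.SEQ))
        assert anns[0].effect_class == "intergenic"
        assert anns[0].transcript_id is None

    def test_frameshift_indel(self):
        anns = annotate_variant(record(25, "A", "AG"), [TWO_EXON], fetch_from(self.SEQ))
        assert anns[0].effect_class == "frameshift"

    def test_inframe_indel(self):
        anns = annotate_variant(record(25, "A", "AGGG"), [TWO_EXON], fetch_from(self.SEQ))
        assert anns[0].effect_class == "missense"
        assert anns[0].aa_change == "inframe"

    def test_n_context_unknown(self):
        seq = "NNN" + "ANG" + "NNN"
        tx = single_codon_transcript("+")
        anns = annotate_variant(record(4, "A", "G"), [tx], fetch_from(seq))
        assert anns[0].effect_class == "unknown"


class TestParseAnnField:
    def test_missense_mapping(self):
        rec = record(5, "A", "T")
        rec.ann = ("T|missense_variant|MODERATE|g1|g1|transcript|m1||",)
        anns = parse_ann_field(rec)
        assert anns[0].effect_class == "missense"
        assert anns[0].transcript_id == "m1"

    def test_synonymous_mapping(self):
        rec = record(5, "A", "T")
        rec.ann = ("T|synonymous_variant|LOW|g1|g1|transcript|m1||",)
        assert parse_ann_field(rec)[0].effect_class == "synonymous"

    def test_unknown_term_passthrough(self):
        rec = record(5, "A", "T")
        rec.ann = ("T|weird_thing|LOW|g1|g1|transcript|m1||",)
        assert parse_ann_field(rec)[0].effect_class == "weird_thing"

    def test_empty_ann_falls_back_to_internal(self):
        rec = record(99, "A", "G")
        anns = effective_annotations(rec, [TWO_EXON], fetch_from("A" * 100))
        assert anns[0].effect_class == "intergenic"

    def test_ann_takes_precedence(self):
        rec = record(99, "A", "G")
        rec.ann = ("G|missense_variant|MODERATE|g|g|transcript|m||",)
        anns = effective_annotations(rec, [TWO_EXON], fetch_from("A" * 100))
        assert anns[0].effect_class == "missense"
        anns = effective_annotations(
            rec, [TWO_EXON], fetch_from("A" * 100), prefer_ann=False
        )
        assert anns[0].effect_class == "intergenic"


def gm(rows, samples):
    sites = [SiteInfo("1A", 10 * (i + 1), "A", ("T",)) for i in range(len(rows))]
    cells = [[GenotypeCall.from_string(g) for g in row] for row in rows]
    return GenotypeMatrix(sites=sites, samples=samples, cells=cells)


class TestGroupFrequencies:
    def test_hand_count(self):
        m = gm([["0/0", "0/1", "1/1", "./."]], ["A", "B", "C", "D"])
        freqs = group_frequencies(m, {"g": ["A", "B", "C", "D"]})
        assert freqs[0].alt_freq == pytest.approx(0.5)
        assert freqs[0].missing_rate == 0.25
        assert freqs[0].n_samples == 4

    def test_zero_is_present(self):
        m = gm([["0/0", "0/0"]], ["A", "B"])
        assert group_frequencies(m, {"g": ["A", "B"]})[0].alt_freq == 0.0

    def test_all_missing_is_absent(self):
        m = gm([["./.", "./."]], ["A", "B"])
        assert group_frequencies(m, {"g": ["A", "B"]})[0].alt_freq is None

    def test_empty_group_error(self):
        m = gm([["0/0"]], ["A"])
        with pytest.raises(ParameterError):
            group_frequencies(m, {"g": []})

    def test_alt_count_conservation(self):
        m = gm(
            [["0/1", "1/1", "0/0", "./.", "0/1", "1/1"]],
            ["A", "B", "C", "D", "E", "F"],
        )
        groups = {"g1": ["A", "B", "C"], "g2": ["D", "E", "F"]}
        freqs = group_frequencies(m, groups)
        total = 0.0
        for f in freqs:
            if f.alt_freq is None:
                continue
            called = f.n_samples - round(f.missing_rate * f.n_samples)
            total += f.alt_freq * 2 * called
        assert total == pytest.approx(6)  # 0/1 + 1/1 + 0/1 + 1/1 alleles


class TestSeverity:
    def test_total_order(self):
        from varscope.effects import SEVERITY_ORDER

        ranks = [severity_rank(c) for c in SEVERITY_ORDER]
        assert ranks == sorted(ranks, reverse=True)
        assert len(set(ranks)) == len(ranks)

    def test_most_severe_rule(self):
        assert most_severe(["synonymous", "stop_gained"]) == "stop_gained"
        assert most_severe(["missense", "frameshift"]) == "frameshift"
        assert most_severe(["intron"]) == "intron"


class TestLollipopData:
    def test_minimal_structure(self):
        m = gm([["0/1", "1/1"]], ["A", "B"])
        freqs = group_frequencies(m, {"g": ["A", "B"]})
        from varscope.effects import EffectAnnotation

        anns = [EffectAnnotation("1A", 10, "A", "T", "m1", "missense")]
        data = lollipop_data(RegionQuery("1A", 1, 100), freqs, anns, [])
        assert len(data["sites"]) == 1
        site = data["sites"][0]
        assert site["class"] == "missense"
        assert site["stems"]["g"] == pytest.approx(0.75)

    def test_multi_transcript_max_severity(self):
        from varscope.effects import EffectAnnotation

        m = gm([["0/1", "1/1"]], ["A", "B"])
        freqs = group_frequencies(m, {"g": ["A", "B"]})
        anns = [
            EffectAnnotation("1A", 10, "A", "T", "m1", "synonymous"),
            EffectAnnotation("1A", 10, "A", "T", "m2", "stop_gained"),
        ]
        data = lollipop_data(RegionQuery("1A", 1, 100), freqs, anns, [])
        assert data["sites"][0]["class"] == "stop_gained"

    def test_transcript_tracks_in_order(self):
        m = gm([["0/1", "1/1"]], ["A", "B"])
        freqs = group_frequencies(m, {"g": ["A", "B"]})
        t1 = TranscriptModel("g1", "m1", "1A", "+", [(5, 50)], [])
        t2 = TranscriptModel("g2", "m2", "1A", "-", [(60, 90)], [])
        data = lollipop_data(RegionQuery("1A", 1, 100), freqs, [], [t1, t2])
        assert [t["transcript"] for t in data["transcripts"]] == ["m1", "m2"]
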