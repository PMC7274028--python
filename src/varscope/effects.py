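"""Variant effect classification against transcript models, and per-group
site frequencies for lollipop-style output.

The internal annotator is a deliberately minimal codon-level classifier
(standard genetic code only): CDS SNPs are translated strand-aware; CDS
indels are frameshift when the length change is not a multiple of 3; the
splice-region window is the 2 intronic bases flanking each exon boundary.
When an INFO/ANN field is present it takes precedence by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ParameterError
from .genotype import GenotypeMatrix
from .io import ReferenceFetch, TranscriptModel, VariantRecord

log = logging.getLogger(__name__)

# severity: high to low; anything unlisted ranks below intergenic
SEVERITY_ORDER = (
    "frameshift",
    "stop_gained",
    "stop_lost",
    "missense",
    "splice_region",
    "synonymous",
    "non_coding_exon",
    "intron",
    "intergenic",
    "unknown",
)
_SEVERITY_RANK = {c: len(SEVERITY_ORDER) - i for i, c in enumerate(SEVERITY_ORDER)}

SPLICE_WINDOW = 2  # intronic bases adjacent to each exon boundary

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def severity_rank(effect_class: str) -> int:
    return _SEVERITY_RANK.get(effect_class, 0)


def most_severe(classes: Sequence[str]) -> Optional[str]:
    classes = [c for c in classes if c]
    if not classes:
        return None
    return max(classes, key=severity_rank)


@dataclass(frozen=True)
class EffectAnnotation:
    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: Optional[str]
    effect_class: str
    aa_change: Optional[str] = None


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _coding_positions(model: TranscriptModel) -> list[int]:
    """Genomic positions of coding bases in translation order."""
    if model.strand == "-":
        out = []
        for s, e, _ in sorted(model.cds, key=lambda c: -c[0]):
            out.extend(range(e, s - 1, -1))
        return out
    out = []
    for s, e, _ in model.cds:
        out.extend(range(s, e + 1))
    return out


def _first_phase(model: TranscriptModel) -> int:
    if not model.cds:
        return 0
    if model.strand == "-":
        return max(model.cds, key=lambda c: c[0])[2]
    return min(model.cds, key=lambda c: c[0])[2]


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e, *_ in intervals)


def _classify_cds_snp(
    record: VariantRecord,
    alt: str,
    model: TranscriptModel,
    fetch: ReferenceFetch,
) -> tuple[str, Optional[str]]:
    positions = _coding_positions(model)
    phase = _first_phase(model)
    try:
        ci = positions.index(record.pos)
    except ValueError:
        return "unknown", None
    ci_adj = ci - phase
    if ci_adj < 0:
        return "unknown", None
    codon_idx = ci_adj // 3
    codon_slice = positions[phase + codon_idx * 3 : phase + codon_idx * 3 + 3]
    if len(codon_slice) < 3:
        return "unknown", None

    def base_at(gpos: int) -> str:
        b = fetch(record.chrom, gpos, gpos).upper()
        return b.translate(_COMPLEMENT) if model.strand == "-" else b

    ref_codon = "".join(base_at(p) for p in codon_slice)
    offset = codon_slice.index(record.pos)
    alt_base = alt.translate(_COMPLEMENT) if model.strand == "-" else alt
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    if "N" in ref_codon or "N" in alt_codon:
        return "unknown", None
    ref_aa = CODON_TABLE.get(ref_codon)
    alt_aa = CODON_TABLE.get(alt_codon)
    if ref_aa is None or alt_aa is None:
        return "unknown", None
    aa_change = f"{ref_aa}{codon_idx + 1}{alt_aa}"
    if ref_aa == alt_aa:
        return "synonymous", aa_change
    if alt_aa == "*":
        return "stop_gained", aa_change
    if ref_aa == "*":
        return "stop_lost", aa_change
    return "missense", aa_change


def _splice_region_hit(pos: int, model: TranscriptModel) -> bool:
    for s, e in model.introns():
        w = min(SPLICE_WINDOW, e - s + 1)
        if s <= pos <= s + w - 1 or e - w + 1 <= pos <= e:
            return True
    return False


def annotate_variant(
    record: VariantRecord,
    transcripts: Sequence[TranscriptModel],
    reference_fetch: ReferenceFetch,
) -> list[EffectAnnotation]:
    """One annotation per overlapping transcript (intergenic when none).

    Classification uses the FIRST ALT allele; precedence within a
    transcript: CDS > splice region > intron > non-coding exon.
    """
    if not record.alts:
        return []
    alt = record.alts[0]
    span_end = record.pos + len(record.ref) - 1
    is_snp = len(record.ref) == 1 and len(alt) == 1 and alt in "ACGT"
    is_indel = len(record.ref) != len(alt)

    out: list[EffectAnnotation] = []
    for model in transcripts:
        if model.chrom != record.chrom:
            continue
        t_start, t_end = model.span
        if span_end < t_start or record.pos > t_end:
            continue

        in_cds = any(
            not (span_end < s or record.pos > e) for s, e, _ in model.cds
        )
        effect: str
        aa: Optional[str] = None
        if in_cds and is_snp:
            effect, aa = _classify_cds_snp(record, alt, model, reference_fetch)
        elif in_cds and is_indel:
            effect = (
                "frameshift"
                if (len(alt) - len(record.ref)) % 3 != 0
                else "missense"
            )
            aa = None if effect == "frameshift" else "inframe"
        elif in_cds:
            # same-length MNV in CDS: treat per-base worst case, keep simple
            effect = "missense"
        elif _splice_region_hit(record.pos, model):
            effect = "splice_region"
        elif _in_intervals(record.pos, model.introns()):
            effect = "intron"
        elif _in_intervals(record.pos, model.exons):
            effect = "non_coding_exon"
        else:
            continue
        out.append(
            EffectAnnotation(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alt=alt,
                transcript_id=model.transcript_id,
                effect_class=effect,
                aa_change=aa,
            )
        )
    if not out:
        out.append(
            EffectAnnotation(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alt=alt,
                transcript_id=None,
                effect_class="intergenic",
            )
        )
    return out


# ---------------------------------------------------------------------------
# ANN field parsing

_ANN_TERM_MAP = {
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "frameshift_variant": "frameshift",
    "splice_region_variant": "splice_region",
    "intron_variant": "intron",
    "intergenic_region": "intergenic",
    "intergenic_variant": "intergenic",
    "non_coding_exon_variant": "non_coding_exon",
    "non_coding_transcript_exon_variant": "non_coding_exon",
}


def parse_ann_field(record: VariantRecord) -> list[EffectAnnotation]:
    """Map SnpEff-style pipe-delimited ANN entries onto effect classes.

    Unknown effect terms pass through as raw labels; malformed entries are
    skipped with a warning.
    """
    out: list[EffectAnnotation] = []
    for entry in record.ann:
        fields = entry.split("|")
        if len(fields) < 2 or not fields[1]:
            log.warning("malformed ANN entry at %s:%d", record.chrom, record.pos)
            continue
        term = fields[1].split("&")[0].strip()
        effect = _ANN_TERM_MAP.get(term, term)
        transcript = fields[6].strip() if len(fields) > 6 and fields[6] else None
        out.append(
            EffectAnnotation(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alt=fields[0] or (record.alts[0] if record.alts else ""),
                transcript_id=transcript,
                effect_class=effect,
            )
        )
    return out


def effective_annotations(
    record: VariantRecord,
    transcripts: Sequence[TranscriptModel],
    reference_fetch: ReferenceFetch,
    prefer_ann: bool = True,
) -> list[EffectAnnotation]:
    """ANN field when present (and preferred), else the internal annotator."""
    if prefer_ann and record.ann:
        parsed = parse_ann_field(record)
        if parsed:
            return parsed
    return annotate_variant(record, transcripts, reference_fetch)


# ---------------------------------------------------------------------------
# Group frequencies and lollipop structure


@dataclass(frozen=True)
class SiteGroupFreq:
    chrom: str
    pos: int
    group_id: str
    alt_freq: Optional[float]  # None = group entirely missing (absent ≠ 0)
    missing_rate: float
    n_samples: int


def group_frequencies(
    matrix: GenotypeMatrix, groups: dict[str, list[str]]
) -> list[SiteGroupFreq]:
    """Per-site, per-group ALT-allele frequency over non-missing alleles.

    A group with no called genotype at a site reports ``alt_freq=None`` to
    keep "undetected" distinguishable from "absent".
    """
    for gid, members in groups.items():
        if not members:
            raise ParameterError(f"group {gid!r} is empty")
        unknown = [m for m in members if m not in matrix.samples]
        if unknown:
            raise ParameterError(f"group {gid!r} has non-matrix samples: {unknown}")
    col_idx = {acc: j for j, acc in enumerate(matrix.samples)}
    out: list[SiteGroupFreq] = []
    for i, site in enumerate(matrix.sites):
        row = matrix.cells[i]
        for gid, members in groups.items():
            total = 0
            alt = 0
            missing = 0
            for acc in members:
                call = row[col_idx[acc]]
                if call.alleles is None:
                    missing += 1
                    continue
                for a in call.alleles:
                    total += 1
                    if a != 0:
                        alt += 1
            out.append(
                SiteGroupFreq(
                    chrom=site.chrom,
                    pos=site.pos,
                    group_id=gid,
                    alt_freq=(alt / total) if total else None,
                    missing_rate=missing / len(members),
                    n_samples=len(members),
                )
            )
    return out


def lollipop_data(
    region,
    freqs: Sequence[SiteGroupFreq],
    annotations: Sequence[EffectAnnotation],
    transcripts: Sequence[TranscriptModel],
) -> dict:
    """Plot-ready structure: stems per group per site, coloured by the most
    severe effect class; transcript tracks in input (GFF) order."""
    by_pos: dict[int, dict] = {}
    for f in freqs:
        entry = by_pos.setdefault(
            f.pos, {"pos": f.pos, "ref": None, "alt": None, "class": None, "stems": {}}
        )
        entry["stems"][f.group_id] = f.alt_freq
    ann_by_pos: dict[int, list[EffectAnnotation]] = {}
    for a in annotations:
        ann_by_pos.setdefault(a.pos, []).append(a)
    for pos, entry in by_pos.items():
        anns = ann_by_pos.get(pos, [])
        if anns:
            entry["ref"] = anns[0].ref
            entry["alt"] = anns[0].alt
            entry["class"] = most_severe([a.effect_class for a in anns])
            entry["transcript_effects"] = {
                a.transcript_id: a.effect_class for a in anns if a.transcript_id
            }
    tracks = [
        {
            "transcript": m.transcript_id,
            "gene": m.gene_id,
            "strand": m.strand,
            "exons": list(m.exons),
            "cds": [(s, e) for s, e, _ in m.cds],
        }
        for m in transcripts
        if m.chrom == region.chrom
        and not (m.span[1] < region.start or m.span[0] > region.end)
    ]
    return {
        "region": str(region),
        "sites": [by_pos[p] for p in sorted(by_pos)],
        "transcripts": tracks,
    }
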