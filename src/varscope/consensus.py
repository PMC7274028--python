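"""Sample-specific consensus sequences.

Variants are substituted into the reference region in descending reference
position, so earlier substitutions never shift the coordinates of later
ones. Heterozygous SNPs become IUPAC ambiguity codes by default; het indels
and missing calls keep the reference and are logged, keeping the caveat that
a consensus may not reflect the true sequence auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional, Sequence

from .errors import ParameterError
from .io import GTClass, ReferenceFetch, VariantRecord
from .query import RegionQuery

HET_POLICIES = ("iupac", "alt", "ref")

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class LedgerEntry:
    pos: int
    ref: str
    alt: Optional[str]
    zygosity: str  # REF_HOM | HET | ALT_HOM | MISSING
    action: str  # substituted | iupac | skipped:<reason>


@dataclass
class ConsensusResult:
    sequence: str
    coord_map: list[tuple[int, int]]  # (refPos, consensusPos) anchors
    applied: list[LedgerEntry] = field(default_factory=list)
    skipped: list[LedgerEntry] = field(default_factory=list)
    region: Optional[RegionQuery] = None
    sample_label: str = ""


def _sample_of(records: Sequence[VariantRecord]) -> Optional[str]:
    ids = {sid for rec in records for sid in rec.calls}
    if len(ids) > 1:
        raise ParameterError(f"records span multiple samples: {sorted(ids)}")
    return next(iter(ids)) if ids else None


def make_consensus(
    region: RegionQuery,
    reference_fetch: ReferenceFetch,
    sample_records: Sequence[VariantRecord],
    het_policy: str = "iupac",
    sample_label: str = "",
) -> ConsensusResult:
    """Apply one sample's variants to the reference region.

    Application order is descending reference position. ALT_HOM SNPs/indels
    substitute the alt allele; het SNPs follow ``het_policy``; het indels and
    missing calls keep the reference (ledgered); variants whose REF span
    crosses the region boundary are skipped; when applied spans overlap, the
    rightmost (first applied) wins.
    """
    if het_policy not in HET_POLICIES:
        raise ParameterError(f"unknown het policy {het_policy!r}")
    sid = _sample_of(sample_records)

    ref_seq = reference_fetch(region.chrom, region.start, region.end)
    seq = list(ref_seq)
    applied: list[LedgerEntry] = []
    skipped: list[LedgerEntry] = []

    lowest_applied_start = region.end + 1  # ref pos of leftmost applied variant
    for rec in sorted(sample_records, key=lambda r: -r.pos):
        call = rec.calls[sid]
        zyg = call.klass.value
        span_end = rec.pos + len(rec.ref) - 1

        def skip(reason: str, alt: Optional[str] = None) -> None:
            skipped.append(LedgerEntry(rec.pos, rec.ref, alt, zyg, f"skipped:{reason}"))

        if call.klass is GTClass.MISSING:
            skip("missing")
            continue
        if call.klass is GTClass.REF_HOM:
            skip("ref_genotype")
            continue
        if rec.pos < region.start or span_end > region.end:
            skip("boundary")
            continue
        if span_end >= lowest_applied_start:
            skip("overlap")
            continue

        if call.klass is GTClass.ALT_HOM:
            alt = rec.alts[call.alleles[0] - 1]
            if not set(alt) <= _DNA:
                skip("non_sequence_alt", alt)
                continue
            replacement = alt
            action = "substituted"
        else:  # HET
            a, b = call.alleles
            allele_seqs = []
            for ai in (a, b):
                allele_seqs.append(rec.ref if ai == 0 else rec.alts[ai - 1])
            is_snp = len(rec.ref) == 1 and all(len(s) == 1 for s in allele_seqs)
            if het_policy == "ref":
                skip("het_policy_ref", allele_seqs[-1])
                continue
            if not is_snp:
                if het_policy == "alt":
                    alt = next((s for s in allele_seqs if s != rec.ref), None)
                    if alt is None or not set(alt) <= _DNA:
                        skip("het_indel", alt)
                        continue
                    replacement = alt
                    action = "substituted"
                else:
                    skip("het_indel", allele_seqs[-1])
                    continue
            elif het_policy == "iupac":
                bases = frozenset(allele_seqs)
                if not bases <= _DNA:
                    skip("non_sequence_alt", allele_seqs[-1])
                    continue
                replacement = _IUPAC[bases]
                action = "iupac"
            else:  # alt
                alt = next((s for s in allele_seqs if s != rec.ref), allele_seqs[-1])
                if not set(alt) <= _DNA:
                    skip("non_sequence_alt", alt)
                    continue
                replacement = alt
                action = "substituted"

        offset = rec.pos - region.start
        expected = ref_seq[offset : offset + len(rec.ref)]
        if expected != rec.ref.upper():
            skip("ref_mismatch", replacement)
            continue
        seq[offset : offset + len(rec.ref)] = list(replacement)
        applied.append(
            LedgerEntry(rec.pos, rec.ref, replacement, zyg, action)
        )
        lowest_applied_start = rec.pos

    applied.reverse()  # ascending position in the ledger

    # coordinate anchors: region start, then each applied variant start and
    # the position just past its REF span
    coord_map: list[tuple[int, int]] = [(region.start, 1)]
    offset = 0
    for entry in applied:
        cons_start = entry.pos - region.start + 1 + offset
        coord_map.append((entry.pos, cons_start))
        delta = len(entry.alt) - len(entry.ref)
        offset += delta
        after_ref = entry.pos + len(entry.ref)
        if after_ref <= region.end + 1:
            coord_map.append((after_ref, after_ref - region.start + 1 + offset))

    return ConsensusResult(
        sequence="".join(seq),
        coord_map=coord_map,
        applied=applied,
        skipped=skipped,
        region=region,
        sample_label=sample_label,
    )


def raw_sequence(region: RegionQuery, reference_fetch: ReferenceFetch) -> str:
    """The unmodified reference subsequence (the reserved #RAW semantics)."""
    return reference_fetch(region.chrom, region.start, region.end)


def write_consensus_fasta(
    results: Sequence[ConsensusResult],
    path: str,
    het_policy: str = "iupac",
    stamp: bool = True,
) -> None:
    """One wrapped FASTA record per sample; headers carry the query region
    and parameters, plus an ISO-8601 time stamp unless suppressed."""
    if not results:
        raise ParameterError("no consensus results to write")
    with open(path, "w") as fh:
        for res in results:
            header = f">{res.sample_label} {res.region} het={het_policy}"
            if stamp:
                ts = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
                header += f" timestamp={ts}"
            fh.write(header + "\n")
            for i in range(0, len(res.sequence), 60):
                fh.write(res.sequence[i : i + 60] + "\n")
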