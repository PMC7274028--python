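"""Input readers, validators, and the domain records they produce.

Covers the four input formats (VCF, FASTA, GFF3, metadata TSV). All
coordinates at this interface are 1-based inclusive. Plain or bgzipped VCF
is the storage contract; an index is used opportunistically when present,
otherwise region queries fall back to a filtered scan.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

import gffutils
import pyfaidx
import pysam

from .errors import (
    ContigError,
    ParseError,
    RangeError,
    ReservedNameError,
    UnknownSampleError,
    ValidationError,
)

log = logging.getLogger(__name__)

RESERVED_IDS = frozenset({"#ALL", "#RAW", "ALL", "RAW"})

_DNA = frozenset("ACGTN")


class GTClass(Enum):
    """Four-way genotype encoding used throughout."""

    REF_HOM = "REF_HOM"
    HET = "HET"
    ALT_HOM = "ALT_HOM"
    MISSING = "MISSING"


@dataclass(frozen=True)
class GenotypeCall:
    """A single diploid genotype call.

    ``alleles`` is a pair of allele indices (0 = REF) or ``None`` when the
    call is missing. Half-calls (one missing allele) are treated as MISSING;
    haploid calls are promoted to homozygous diploid.
    """

    alleles: Optional[tuple[int, int]]
    phased: bool = False

    @property
    def klass(self) -> GTClass:
        if self.alleles is None:
            return GTClass.MISSING
        a, b = self.alleles
        if a == 0 and b == 0:
            return GTClass.REF_HOM
        if a == b:
            return GTClass.ALT_HOM
        return GTClass.HET

    def state_key(self) -> str:
        """Phase-insensitive state string, e.g. ``0/1`` (``1|0`` maps equal)."""
        if self.alleles is None:
            return "./."
        a, b = sorted(self.alleles)
        return f"{a}/{b}"

    @classmethod
    def from_indices(cls, raw: tuple, phased: bool = False) -> "GenotypeCall":
        if raw is None or len(raw) == 0 or any(a is None for a in raw):
            return cls(None, phased)
        if len(raw) == 1:  # haploid -> homozygous diploid
            return cls((int(raw[0]), int(raw[0])), phased)
        return cls((int(raw[0]), int(raw[1])), phased)

    @classmethod
    def from_string(cls, text: str) -> "GenotypeCall":
        phased = "|" in text
        parts = text.replace("|", "/").split("/")
        if any(p in (".", "") for p in parts):
            return cls(None, phased)
        return cls.from_indices(tuple(int(p) for p in parts), phased)


@dataclass
class VariantRecord:
    """One VCF site restricted to the requested sample columns."""

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alts: tuple[str, ...]
    calls: dict[str, GenotypeCall]  # keyed by vcf-ID
    depth: Optional[dict[str, Optional[int]]] = None
    quality: Optional[dict[str, Optional[int]]] = None
    ann: tuple[str, ...] = ()

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass
class TranscriptModel:
    """Gene-model geometry for one mRNA: exons plus phased CDS intervals."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # sorted ascending, 1-based inclusive
    cds: list[tuple[int, int, int]]  # (start, end, phase), sorted ascending

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass(frozen=True)
class GeneSpan:
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class CatalogEntry:
    vcf_id: str
    accession_name: str
    display_name: str
    meta: dict[str, str] = field(default_factory=dict)

    @property
    def latitude(self) -> Optional[float]:
        return _float_or_none(self.meta.get("latitude"))

    @property
    def longitude(self) -> Optional[float]:
        return _float_or_none(self.meta.get("longitude"))


def _float_or_none(v: Optional[str]) -> Optional[float]:
    if v is None or v == "" or v == ".":
        return None
    try:
        return float(v)
    except ValueError:
        return None


@dataclass
class SampleCatalog:
    """Triple-name registry plus group definitions and passport metadata."""

    entries: list[CatalogEntry]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vcf_ids = [e.vcf_id for e in self.entries]
        accs = [e.accession_name for e in self.entries]
        if len(set(vcf_ids)) != len(vcf_ids):
            raise ValidationError("duplicate vcfID in sample catalog")
        if len(set(accs)) != len(accs):
            raise ValidationError("duplicate accessionName in sample catalog")
        for name in accs + vcf_ids + list(self.groups):
            if name in RESERVED_IDS or name.startswith("#"):
                raise ReservedNameError(f"reserved or #-prefixed name: {name!r}")
        known = set(accs)
        for gid, members in self.groups.items():
            for m in members:
                if m not in known:
                    raise ValidationError(
                        f"group {gid!r} references unknown accession {m!r}"
                    )

    @property
    def accessions(self) -> list[str]:
        return [e.accession_name for e in self.entries]

    def entry(self, accession: str) -> CatalogEntry:
        for e in self.entries:
            if e.accession_name == accession:
                return e
        raise KeyError(accession)

    def vcf_id_of(self, accession: str) -> str:
        return self.entry(accession).vcf_id

    def display_of(self, accession: str) -> str:
        e = self.entry(accession)
        return e.display_name if e.display_name else e.accession_name


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]


# ---------------------------------------------------------------------------
# FASTA


class FastaSource:
    """Random-access reference reader with 1-based inclusive coordinates."""

    def __init__(self, path: str):
        if not os.path.exists(path):
            raise OSError(f"cannot read FASTA: {path}")
        self._fasta = pyfaidx.Fasta(path)

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def contig_length(self, chrom: str) -> int:
        try:
            return len(self._fasta[chrom])
        except KeyError:
            raise ContigError(f"unknown contig {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 1 or start > end:
            raise RangeError(f"invalid range {start}-{end}")
        n = self.contig_length(chrom)
        if end > n:
            raise RangeError(f"{chrom}:{start}-{end} exceeds contig length {n}")
        return str(self._fasta[chrom][start - 1 : end]).upper()


def read_fasta_region(fasta_path: str, chrom: str, start: int, end: int) -> str:
    """Uppercase subsequence of ``chrom`` over 1-based inclusive coordinates."""
    return FastaSource(fasta_path).fetch(chrom, start, end)


# ---------------------------------------------------------------------------
# GFF3


def parse_gff3(gff_path: str) -> tuple[list[TranscriptModel], dict[str, GeneSpan]]:
    """Parse gene/mRNA/exon/CDS features into transcript models.

    Returns one :class:`TranscriptModel` per mRNA (in file order) and a gene
    index mapping each gene id to its span. The span of a gene is the union
    of its mRNA spans, falling back to the gene feature's own coordinates.
    """
    if not os.path.exists(gff_path):
        raise OSError(f"cannot read GFF3: {gff_path}")
    try:
        db = gffutils.create_db(
            gff_path, ":memory:", merge_strategy="error", keep_order=True
        )
    except ValueError as exc:
        raise ValidationError(f"duplicate feature id in GFF3: {exc}") from exc

    mrna_types = ("mRNA", "transcript")
    models: list[TranscriptModel] = []
    mrna_parent: dict[str, str] = {}
    known_mrnas: set[str] = set()
    for mrna in db.features_of_type(mrna_types, order_by="start"):
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else mrna.id
        mrna_parent[mrna.id] = gene_id
        known_mrnas.add(mrna.id)
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end, int(f.frame) if f.frame in "012" else 0)
            for f in db.children(mrna, featuretype="CDS")
        )
        if not exons:  # tolerate exon-less mRNA: synthesize from span
            exons = [(mrna.start, mrna.end)]
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
            )
        )

    for f in db.features_of_type("CDS"):
        for parent in f.attributes.get("Parent", []) or [None]:
            if parent is None or parent not in known_mrnas:
                raise ParseError(
                    f"CDS at {f.seqid}:{f.start} has no parent mRNA ({parent!r})"
                )

    gene_index: dict[str, GeneSpan] = {}
    seen_gene_ids: set[str] = set()
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.id in seen_gene_ids:
            raise ValidationError(f"duplicate gene id {gene.id!r}")
        seen_gene_ids.add(gene.id)
        spans = [m.span for m in models if m.gene_id == gene.id]
        if spans:
            start = min(s for s, _ in spans)
            end = max(e for _, e in spans)
        else:
            start, end = gene.start, gene.end
        gene_index[gene.id] = GeneSpan(gene.seqid, start, end, gene.strand)
    # mRNAs whose gene has no explicit gene feature still get an index entry
    for m in models:
        if m.gene_id not in gene_index:
            s, e = m.span
            gene_index[m.gene_id] = GeneSpan(m.chrom, s, e, m.strand)
    return models, gene_index


# ---------------------------------------------------------------------------
# VCF


def _vcf_header_info(vcf_path: str) -> tuple[list[str], list[str], bool]:
    """(samples, contigs, has ANN) from the header without reading records."""
    with pysam.VariantFile(vcf_path) as vf:
        samples = list(vf.header.samples)
        contigs = list(vf.header.contigs)
        has_ann = "ANN" in vf.header.info
    return samples, contigs, has_ann


def read_variants(vcf_path, region=None, vcf_ids=None) -> list[VariantRecord]:
    """Region-scoped variant fetch restricted to the requested sample columns.

    ``region`` is any object with ``chrom``/``start``/``end`` attributes (or
    None for the whole file). Records are returned sorted by position with
    DP/GQ/ANN captured when present. Symbolic ALT records are skipped with a
    warning.
    """
    if not os.path.exists(vcf_path):
        raise OSError(f"cannot read VCF: {vcf_path}")
    with pysam.VariantFile(vcf_path) as vf:
        header_samples = list(vf.header.samples)
        if vcf_ids is None:
            vcf_ids = header_samples
        else:
            vcf_ids = list(vcf_ids)
            missing = [s for s in vcf_ids if s not in set(header_samples)]
            if missing:
                raise UnknownSampleError(
                    f"sample id(s) absent from VCF header: {', '.join(missing)}"
                )
        has_dp = "DP" in vf.header.formats
        has_gq = "GQ" in vf.header.formats
        has_ann = "ANN" in vf.header.info

        iterator = vf
        scan_filter = None
        if region is not None:
            indexed = os.path.exists(str(vcf_path) + ".tbi") or os.path.exists(
                str(vcf_path) + ".csi"
            )
            if indexed:
                if region.chrom not in vf.header.contigs:
                    return []
                iterator = vf.fetch(region.chrom, region.start - 1, region.end)
            else:
                scan_filter = (region.chrom, region.start, region.end)

        out: list[VariantRecord] = []
        for rec in iterator:
            if scan_filter is not None:
                chrom, start, end = scan_filter
                if rec.chrom != chrom or not (start <= rec.pos <= end):
                    continue
            alts = rec.alts or ()
            if any(a is None or "<" in a or "[" in a or "]" in a for a in alts):
                log.warning(
                    "skipping symbolic ALT record at %s:%d", rec.chrom, rec.pos
                )
                continue
            calls: dict[str, GenotypeCall] = {}
            depth: dict[str, Optional[int]] = {}
            quality: dict[str, Optional[int]] = {}
            for sid in vcf_ids:
                sample = rec.samples[sid]
                gt = sample.get("GT")
                calls[sid] = GenotypeCall.from_indices(gt, bool(sample.phased))
                if has_dp:
                    depth[sid] = sample.get("DP")
                if has_gq:
                    quality[sid] = sample.get("GQ")
            ann = rec.info.get("ANN", ()) if has_ann else ()
            if isinstance(ann, str):
                ann = (ann,)
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(alts),
                    calls=calls,
                    depth=depth if has_dp else None,
                    quality=quality if has_gq else None,
                    ann=tuple(ann),
                )
            )
        out.sort(key=lambda r: (r.chrom, r.pos))
        return out


# ---------------------------------------------------------------------------
# Sample catalog TSVs

REQUIRED_SAMPLE_COLUMNS = ("vcfID", "accessionName", "displayName")


def read_sample_catalog(samples_tsv: str, groups_tsv: Optional[str] = None) -> SampleCatalog:
    """Read the triple-name sample TSV and the optional group TSV.

    Extra sample columns become per-entry metadata; ``latitude``/``longitude``
    are recognized downstream as decimal degrees.
    """
    if not os.path.exists(samples_tsv):
        raise OSError(f"cannot read samples TSV: {samples_tsv}")
    entries: list[CatalogEntry] = []
    with open(samples_tsv, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in header:
                raise ParseError(f"samples TSV missing column {col!r}")
        meta_cols = [c for c in header if c not in REQUIRED_SAMPLE_COLUMNS]
        for row in reader:
            entries.append(
                CatalogEntry(
                    vcf_id=(row["vcfID"] or "").strip(),
                    accession_name=(row["accessionName"] or "").strip(),
                    display_name=(row["displayName"] or "").strip(),
                    meta={c: (row.get(c) or "").strip() for c in meta_cols},
                )
            )

    groups: dict[str, list[str]] = {}
    if groups_tsv is not None:
        if not os.path.exists(groups_tsv):
            raise OSError(f"cannot read groups TSV: {groups_tsv}")
        with open(groups_tsv) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"malformed groups line: {line!r}")
                gid = parts[0].strip()
                members = [t.strip() for t in parts[1].split(",") if t.strip()]
                if gid in groups:
                    raise ValidationError(f"duplicate group id {gid!r}")
                groups[gid] = members
    return SampleCatalog(entries=entries, groups=groups)


# ---------------------------------------------------------------------------
# Instance validation


def validate_instance(
    vcf_path: str,
    fasta_path: str,
    gff_path: str,
    samples_tsv: str,
    groups_tsv: Optional[str] = None,
) -> ValidationReport:
    """Cross-check the five input files for mutual consistency."""
    findings: list[Finding] = []

    def err(code: str, msg: str) -> None:
        findings.append(Finding("error", code, msg))

    def warn(code: str, msg: str) -> None:
        findings.append(Finding("warning", code, msg))

    fasta = FastaSource(fasta_path)
    fasta_contigs = set(fasta.contigs())

    vcf_samples, vcf_contigs, has_ann = _vcf_header_info(vcf_path)
    for contig in vcf_contigs:
        if contig not in fasta_contigs:
            err("contig-mismatch", f"VCF contig {contig!r} absent from FASTA")
    if not has_ann:
        warn(
            "no-ann",
            "VCF lacks INFO/ANN; effect annotation will be computed internally",
        )

    try:
        parse_gff3(gff_path)
    except ValidationError as exc:
        err("duplicate-gene-id", str(exc))
    except ParseError as exc:
        err("gff-parse", str(exc))

    try:
        catalog = read_sample_catalog(samples_tsv, groups_tsv)
    except (ValidationError, ParseError) as exc:
        err("catalog-error", str(exc))
        catalog = None

    if catalog is not None:
        vcf_sample_set = set(vcf_samples)
        for e in catalog.entries:
            if e.vcf_id not in vcf_sample_set:
                err(
                    "unknown-vcf-id",
                    f"catalog vcfID {e.vcf_id!r} absent from VCF header",
                )
        catalogued = {e.vcf_id for e in catalog.entries}
        for sid in vcf_samples:
            if sid not in catalogued:
                warn("uncatalogued-sample", f"VCF sample {sid!r} has no catalog row")

    return ValidationReport(findings=findings)


# ---------------------------------------------------------------------------
# Shared typing helper

ReferenceFetch = Callable[[str, int, int], str]
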