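"""In-memory genotype matrix, per-site statistics, filters, and table export.

The matrix is the intermediate data every analysis consumes: sites ordered by
position, columns ordered as the sample selection, cells holding the four-way
genotype classes with optional DP/GQ payloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ParameterError
from .io import GenotypeCall, GTClass, SampleCatalog, VariantRecord
from .query import SampleSelection

CATEGORIES = ("must_vary", "must_match_ref", "unfiltered")


@dataclass(frozen=True)
class SiteInfo:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    ann: tuple[str, ...] = ()


@dataclass(frozen=True)
class SiteStats:
    alt_freq: float
    maf: float
    missing_rate: float


@dataclass
class GenotypeMatrix:
    sites: list[SiteInfo]
    samples: list[str]  # accessionNames, selection order
    cells: list[list[GenotypeCall]]  # sites x samples
    depth: Optional[list[list[Optional[int]]]] = None
    quality: Optional[list[list[Optional[int]]]] = None

    def __post_init__(self) -> None:
        for row in self.cells:
            if len(row) != len(self.samples):
                raise ParameterError("cell row width != sample count")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def column(self, accession: str) -> list[GenotypeCall]:
        j = self.samples.index(accession)
        return [row[j] for row in self.cells]

    def subset_sites(self, mask: Sequence[bool]) -> "GenotypeMatrix":
        keep = [i for i, m in enumerate(mask) if m]
        return GenotypeMatrix(
            sites=[self.sites[i] for i in keep],
            samples=list(self.samples),
            cells=[self.cells[i] for i in keep],
            depth=[self.depth[i] for i in keep] if self.depth else None,
            quality=[self.quality[i] for i in keep] if self.quality else None,
        )


def build_matrix(
    records: list[VariantRecord],
    selection: SampleSelection,
    catalog: SampleCatalog,
) -> GenotypeMatrix:
    """Assemble the site × sample matrix in selection column order.

    An empty record list yields an empty matrix, not an error; sites where
    every selected sample is missing are retained (filters decide later).
    """
    samples = list(selection.members)
    vcf_ids = [catalog.vcf_id_of(a) for a in samples]
    sites: list[SiteInfo] = []
    cells: list[list[GenotypeCall]] = []
    depth: list[list[Optional[int]]] = []
    quality: list[list[Optional[int]]] = []
    any_dp = any(r.depth is not None for r in records)
    any_gq = any(r.quality is not None for r in records)
    for rec in records:
        sites.append(SiteInfo(rec.chrom, rec.pos, rec.ref, rec.alts, rec.ann))
        cells.append([rec.calls[v] for v in vcf_ids])
        if any_dp:
            depth.append([(rec.depth or {}).get(v) for v in vcf_ids])
        if any_gq:
            quality.append([(rec.quality or {}).get(v) for v in vcf_ids])
    return GenotypeMatrix(
        sites=sites,
        samples=samples,
        cells=cells,
        depth=depth if any_dp else None,
        quality=quality if any_gq else None,
    )


def _stats_for_calls(calls: Sequence[GenotypeCall]) -> SiteStats:
    counts: dict[int, int] = {}
    missing = 0
    for c in calls:
        if c.alleles is None:
            missing += 1
        else:
            for a in c.alleles:
                counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return SiteStats(alt_freq=0.0, maf=0.0, missing_rate=1.0 if calls else 0.0)
    alt = total - counts.get(0, 0)
    maf = 1.0 - max(counts.values()) / total
    return SiteStats(
        alt_freq=alt / total,
        maf=maf,
        missing_rate=missing / len(calls),
    )


def site_stats(matrix: GenotypeMatrix) -> list[SiteStats]:
    """Allele-counting statistics per site.

    Each non-missing diploid call contributes 2 alleles; missing calls are
    excluded from the frequency denominator. MAF = 1 − max per-allele
    frequency (reduces to min(p, 1−p) for biallelic sites).
    """
    return [_stats_for_calls(row) for row in matrix.cells]


def filter_sites(
    matrix: GenotypeMatrix, maf_min: float = 0.0, missing_max: float = 1.0
) -> GenotypeMatrix:
    """Keep sites with maf ≥ maf_min and missingRate ≤ missing_max."""
    if not 0.0 <= maf_min <= 0.5:
        raise ParameterError("maf_min must be in [0, 0.5]")
    if not 0.0 <= missing_max <= 1.0:
        raise ParameterError("missing_max must be in [0, 1]")
    stats = site_stats(matrix)
    mask = [
        s.maf >= maf_min and s.missing_rate <= missing_max for s in stats
    ]
    return matrix.subset_sites(mask)


def sample_category_filter(
    matrix: GenotypeMatrix,
    category: str,
    focal_accessions: Sequence[str] = (),
    mode: str = "every",
) -> list[bool]:
    """Site mask for the three sample categories.

    ``must_vary`` keeps sites where every focal sample is HET or ALT_HOM;
    ``must_match_ref`` keeps sites where every focal sample is REF_HOM;
    MISSING fails both. ``mode="any"`` relaxes the conjunction to a
    disjunction (non-default).
    """
    if category not in CATEGORIES:
        raise ParameterError(f"unknown category {category!r}")
    if mode not in ("every", "any"):
        raise ParameterError(f"unknown mode {mode!r}")
    if category == "unfiltered":
        return [True] * matrix.n_sites
    unknown = [a for a in focal_accessions if a not in matrix.samples]
    if unknown:
        raise ParameterError(f"focal samples not in matrix: {unknown}")
    idx = [matrix.samples.index(a) for a in focal_accessions]
    if category == "must_vary":
        ok = lambda k: k in (GTClass.HET, GTClass.ALT_HOM)
    else:
        ok = lambda k: k is GTClass.REF_HOM
    combine = all if mode == "every" else any
    return [
        combine(ok(row[j].klass) for j in idx) if idx else True
        for row in matrix.cells
    ]


# ---------------------------------------------------------------------------
# Table export

_IUPAC_HET = None  # genotype cells print alleles, not ambiguity codes


def _genotype_cell(call: GenotypeCall, site: SiteInfo, form: str) -> str:
    if form == "raw":
        if call.alleles is None:
            return "./."
        sep = "|" if call.phased else "/"
        return f"{call.alleles[0]}{sep}{call.alleles[1]}"
    # bases form
    if call.alleles is None:
        return "./."
    alleles = (site.ref,) + site.alts

    def base(i: int) -> str:
        return alleles[i] if i < len(alleles) else "?"

    sep = "|" if call.phased else "/"
    return f"{base(call.alleles[0])}{sep}{base(call.alleles[1])}"


def export_table(
    matrix: GenotypeMatrix,
    display_map: Optional[dict[str, str]] = None,
    include_depth: bool = False,
    include_quality: bool = False,
    include_ann: bool = False,
    genotype_form: str = "raw",
) -> tuple[list[str], list[list[str]]]:
    """One row per site; genotype columns headed by display names.

    ``genotype_form="raw"`` emits ``0/0``-style strings; ``"bases"`` emits
    allele letters like ``A/T``. DP/GQ columns follow the genotype block when
    requested; blank when the payload is absent.
    """
    if genotype_form not in ("raw", "bases"):
        raise ParameterError(f"unknown genotype form {genotype_form!r}")
    display_map = display_map or {}
    labels = [display_map.get(a, a) for a in matrix.samples]
    header = ["chrom", "pos", "ref", "alt"]
    if include_ann:
        header.append("ann")
    header.extend(labels)
    if include_depth:
        header.extend(f"{lab}:DP" for lab in labels)
    if include_quality:
        header.extend(f"{lab}:GQ" for lab in labels)

    rows: list[list[str]] = []
    for i, site in enumerate(matrix.sites):
        row = [site.chrom, str(site.pos), site.ref, ",".join(site.alts)]
        if include_ann:
            row.append(";".join(site.ann))
        row.extend(
            _genotype_cell(c, site, genotype_form) for c in matrix.cells[i]
        )
        if include_depth:
            payload = matrix.depth[i] if matrix.depth else [None] * matrix.n_samples
            row.extend("" if v is None else str(v) for v in payload)
        if include_quality:
            payload = (
                matrix.quality[i] if matrix.quality else [None] * matrix.n_samples
            )
            row.extend("" if v is None else str(v) for v in payload)
        rows.append(row)
    return header, rows


def write_table_csv(path: str, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def load_genotype_classes_csv(path: str, n_samples: int) -> list[list[GTClass]]:
    """Re-read a raw-form export back into genotype classes (round-trip aid)."""
    out: list[list[GTClass]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        has_ann = "ann" in header[:5]
        off = 5 if has_ann else 4
        for row in reader:
            out.append(
                [GenotypeCall.from_string(v).klass for v in row[off : off + n_samples]]
            )
    return out
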