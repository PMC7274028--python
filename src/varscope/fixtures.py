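"""Synthetic fixture generation: coherent VCF + FASTA + GFF3 + metadata with
planted structure, plus machine-readable truth tables.

Everything is driven by one RNG seed; identical specs produce byte-identical
files. Truth tables live beside the fixtures so tests never re-derive ground
truth from generator internals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .effects import CODON_TABLE
from .errors import ParameterError, ValidationError
from .io import FastaSource, TranscriptModel

_BASES = "ACGT"


@dataclass
class FixtureSpec:
    seed: int = 1
    contigs: dict[str, int] = field(
        default_factory=lambda: {"1A": 3000, "1B": 1200}
    )
    n_samples: int = 12
    n_sites: int = 40
    groups: dict[str, int] = field(
        default_factory=lambda: {"grpA": 6, "grpB": 6}
    )
    planted_haplotypes: int = 3  # 0 => iid per-sample genotypes
    divergence: float = 0.5
    indel_fraction: float = 0.1
    missing_rate: float = 0.05
    het_rate: float = 0.1
    noise_rate: float = 0.0
    with_effects: bool = True
    with_ann: bool = True
    geo_clusters: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(35.0, 100.0, 60.0), (-5.0, 30.0, 60.0)]
    )
    site_freqs: Optional[list[float]] = None  # iid mode only

    def validate(self) -> None:
        for r in (self.indel_fraction, self.missing_rate, self.het_rate,
                  self.noise_rate, self.divergence):
            if not 0.0 <= r <= 1.0:
                raise ParameterError("rates must be in [0, 1]")
        if self.groups and sum(self.groups.values()) != self.n_samples:
            raise ParameterError("group sizes must sum to n_samples")
        if self.with_effects and self.contigs.get("1A", 0) < 1500:
            raise ParameterError("contig 1A must be >= 1500 bp for gene models")


@dataclass(frozen=True)
class PlantedEffect:
    chrom: str
    pos: int
    ref: str
    alt: str
    effect_class: str
    transcript_id: Optional[str]


@dataclass(frozen=True)
class TruthSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    planted_freq: Optional[float]  # iid mode only
    empirical_freq: float
    missing_rate: float


@dataclass
class FixtureResult:
    paths: dict[str, str]
    truth_sites: list[TruthSite]
    truth_haplotypes: dict[str, int]  # accessionName -> planted class
    truth_effects: list[PlantedEffect]
    accessions: list[str]


# ---------------------------------------------------------------------------
# Gene models

_GENE_LAYOUT = [
    # (gene, mrna, strand, exons, cds) on contig 1A
    ("g1", "m1", "+", [(201, 320), (401, 520)], [(231, 320, 0), (401, 490, 0)]),
    ("g2", "m2", "-", [(1001, 1120), (1201, 1320)], [(1031, 1120, 0), (1201, 1290, 0)]),
]


def _fixture_transcripts() -> list[TranscriptModel]:
    return [
        TranscriptModel(
            gene_id=g, transcript_id=m, chrom="1A", strand=strand,
            exons=list(exons), cds=list(cds),
        )
        for g, m, strand, exons, cds in _GENE_LAYOUT
    ]


def _write_gff3(path: str) -> None:
    lines = ["##gff-version 3"]
    for g, m, strand, exons, cds in _GENE_LAYOUT:
        start = min(s for s, _ in exons)
        end = max(e for _, e in exons)
        lines.append(f"1A\tfixture\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={g}")
        lines.append(
            f"1A\tfixture\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={m};Parent={g}"
        )
        for i, (s, e) in enumerate(exons, 1):
            lines.append(
                f"1A\tfixture\texon\t{s}\t{e}\t.\t{strand}\t.\tID={m}.exon{i};Parent={m}"
            )
        for i, (s, e, phase) in enumerate(cds, 1):
            lines.append(
                f"1A\tfixture\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\tID={m}.cds{i};Parent={m}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Planted effect variants (construction-time codon scan; the classes are
# decided here from the codon table directly, independent of the annotator's
# control flow)

_COMP = str.maketrans("ACGT", "TGCA")


def _coding_map(model: TranscriptModel) -> list[int]:
    if model.strand == "-":
        out = []
        for s, e, _ in sorted(model.cds, key=lambda c: -c[0]):
            out.extend(range(e, s - 1, -1))
        return out
    out = []
    for s, e, _ in model.cds:
        out.extend(range(s, e + 1))
    return out


def plant_effect_variants(
    transcripts: list[TranscriptModel], reference_fetch
) -> list[PlantedEffect]:
    """Find one variant of each effect class by scanning the actual CDS.

    Classes covered: synonymous, missense (both strands), stop_gained,
    frameshift, splice_region, intron, intergenic.
    """
    models = {m.transcript_id: m for m in transcripts}
    planted: list[PlantedEffect] = []
    used: set[int] = set()

    def base_at(chrom: str, pos: int) -> str:
        return reference_fetch(chrom, pos, pos).upper()

    def scan_snp(model: TranscriptModel, want: str) -> Optional[PlantedEffect]:
        positions = _coding_map(model)
        coding = "".join(
            base_at(model.chrom, p).translate(_COMP) if model.strand == "-" else base_at(model.chrom, p)
            for p in positions
        )
        for ci in range(0, len(coding) - 2, 3):
            codon = coding[ci : ci + 3]
            ref_aa = CODON_TABLE[codon]
            for k in range(3):
                gpos = positions[ci + k]
                if gpos in used:
                    continue
                for b in _BASES:
                    if b == codon[k]:
                        continue
                    alt_codon = codon[:k] + b + codon[k + 1 :]
                    alt_aa = CODON_TABLE[alt_codon]
                    if want == "synonymous" and alt_aa == ref_aa:
                        pass
                    elif want == "missense" and alt_aa != ref_aa and "*" not in (ref_aa, alt_aa):
                        pass
                    elif want == "stop_gained" and alt_aa == "*" and ref_aa != "*":
                        pass
                    else:
                        continue
                    genomic_alt = b.translate(_COMP) if model.strand == "-" else b
                    used.add(gpos)
                    return PlantedEffect(
                        model.chrom, gpos, base_at(model.chrom, gpos),
                        genomic_alt, want, model.transcript_id,
                    )
        return None

    m1, m2 = models["m1"], models["m2"]
    for want, model in (
        ("synonymous", m1),
        ("missense", m1),
        ("stop_gained", m1),
        ("missense", m2),
    ):
        hit = scan_snp(model, want)
        if hit is None:
            raise ValidationError(f"could not plant a {want} variant")
        planted.append(hit)

    # frameshift: 1-bp insertion inside m1's first CDS
    fs_pos = next(p for p in range(232, 320) if p not in used)
    used.add(fs_pos)
    ref_base = base_at("1A", fs_pos)
    planted.append(
        PlantedEffect("1A", fs_pos, ref_base, ref_base + "A", "frameshift", "m1")
    )

    def snp_at(pos: int, effect: str, transcript: Optional[str]) -> PlantedEffect:
        used.add(pos)
        ref = base_at("1A", pos)
        alt = next(b for b in _BASES if b != ref)
        return PlantedEffect("1A", pos, ref, alt, effect, transcript)

    planted.append(snp_at(321, "splice_region", "m1"))  # 1st intronic base
    planted.append(snp_at(360, "intron", "m1"))  # intron interior
    planted.append(snp_at(50, "intergenic", None))  # outside all genes
    return sorted(planted, key=lambda p: p.pos)


_ANN_TERMS = {
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "frameshift": "frameshift_variant",
    "splice_region": "splice_region_variant",
    "intron": "intron_variant",
    "intergenic": "intergenic_region",
}


# ---------------------------------------------------------------------------
# Main generator


def generate_fixture(spec: FixtureSpec, out_dir: str) -> FixtureResult:
    """Write the four standard inputs plus truth TSVs into ``out_dir``."""
    spec.validate()
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")
    rng = np.random.default_rng(spec.seed)

    # --- reference FASTA
    fasta_path = os.path.join(out_dir, "reference.fa")
    sequences = {
        name: "".join(rng.choice(list(_BASES), size=length))
        for name, length in spec.contigs.items()
    }
    with open(fasta_path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    def fetch(chrom: str, start: int, end: int) -> str:
        return sequences[chrom][start - 1 : end]

    # --- gene models + planted effect variants
    gff_path = os.path.join(out_dir, "annotation.gff3")
    _write_gff3(gff_path)
    transcripts = _fixture_transcripts()
    effects = (
        plant_effect_variants(transcripts, fetch) if spec.with_effects else []
    )
    effect_positions = {(e.chrom, e.pos) for e in effects}

    # --- sample names, groups, geography
    n = spec.n_samples
    accessions = [f"S{i + 1:02d}" for i in range(n)]
    vcf_ids = [f"run_{a}" for a in accessions]
    displays = [f"Sample {i + 1:02d}" for i in range(n)]

    samples_path = os.path.join(out_dir, "samples.tsv")
    with open(samples_path, "w") as fh:
        fh.write("vcfID\taccessionName\tdisplayName\torigin\tlatitude\tlongitude\n")
        for i in range(n):
            if spec.geo_clusters:
                clat, clon, spread = spec.geo_clusters[i % len(spec.geo_clusters)]
                lat = float(np.clip(clat + rng.normal(0, spread / 111.0), -90, 90))
                lon = float(np.clip(clon + rng.normal(0, spread / 111.0), -180, 180))
                lat_s, lon_s = f"{lat:.5f}", f"{lon:.5f}"
                origin = f"cluster{i % len(spec.geo_clusters) + 1}"
            else:
                lat_s = lon_s = ""
                origin = "unknown"
            fh.write(
                f"{vcf_ids[i]}\t{accessions[i]}\t{displays[i]}\t{origin}\t{lat_s}\t{lon_s}\n"
            )

    groups_path = os.path.join(out_dir, "groups.tsv")
    with open(groups_path, "w") as fh:
        cursor = 0
        for gid, size in spec.groups.items():
            members = accessions[cursor : cursor + size]
            cursor += size
            fh.write(f"{gid}\t{','.join(members)}\n")

    # --- random site positions (spacing >= 6 bp, clear of planted effects)
    blocked = set()
    for chrom, pos in effect_positions:
        for p in range(pos - 8, pos + 9):
            blocked.add((chrom, p))
    sites: list[tuple[str, int]] = []
    contig_names = sorted(spec.contigs)
    per_contig = {c: 0 for c in contig_names}
    for i in range(spec.n_sites):
        per_contig[contig_names[i % len(contig_names)]] += 1
    for chrom in contig_names:
        length = spec.contigs[chrom]
        want = per_contig[chrom]
        chosen: list[int] = []
        attempts = 0
        while len(chosen) < want and attempts < 20000:
            attempts += 1
            pos = int(rng.integers(10, length - 8))
            if (chrom, pos) in blocked:
                continue
            if any(abs(pos - p) < 6 for p in chosen):
                continue
            chosen.append(pos)
            for p in range(pos - 5, pos + 6):
                blocked.add((chrom, p))
        if len(chosen) < want:
            raise ParameterError(f"cannot place {want} sites on {chrom}")
        sites.extend((chrom, p) for p in sorted(chosen))
    sites.sort()

    # --- alleles per random site
    site_alleles: list[tuple[str, int, str, str]] = []
    for chrom, pos in sites:
        ref_base = fetch(chrom, pos, pos)
        if rng.random() < spec.indel_fraction:
            if rng.random() < 0.5:  # insertion
                ins = "".join(rng.choice(list(_BASES), size=int(rng.integers(1, 4))))
                site_alleles.append((chrom, pos, ref_base, ref_base + ins))
            else:  # deletion
                dlen = int(rng.integers(2, 5))
                ref = fetch(chrom, pos, pos + dlen - 1)
                site_alleles.append((chrom, pos, ref, ref[0]))
        else:
            alt = str(rng.choice([b for b in _BASES if b != ref_base]))
            site_alleles.append((chrom, pos, ref_base, alt))

    # --- genotype assignment
    k = spec.planted_haplotypes
    hap_class = {accessions[i]: (i % k if k else -1) for i in range(n)}
    n_random = len(site_alleles)
    genotypes = np.empty((n_random, n), dtype=object)
    planted_freqs: list[Optional[float]] = []

    if k > 0:
        class_gt = np.empty((n_random, k), dtype=object)
        for s in range(n_random):
            if s < k - 1:  # barcode sites guarantee distinct class signatures
                for c in range(k):
                    class_gt[s, c] = (1, 1) if c > s else (0, 0)
            else:
                for c in range(k):
                    u = rng.random()
                    if u < spec.het_rate:
                        class_gt[s, c] = (0, 1)
                    elif rng.random() < spec.divergence:
                        class_gt[s, c] = (1, 1)
                    else:
                        class_gt[s, c] = (0, 0)
            planted_freqs.append(None)
        for s in range(n_random):
            for j in range(n):
                genotypes[s, j] = class_gt[s, hap_class[accessions[j]]]
    else:
        for s in range(n_random):
            p = (
                spec.site_freqs[s]
                if spec.site_freqs and s < len(spec.site_freqs)
                else float(rng.uniform(0.05, 0.45))
            )
            planted_freqs.append(p)
            for j in range(n):
                genotypes[s, j] = tuple(sorted(int(rng.random() < p) for _ in range(2)))

    # noise then missingness, per call
    gt_states = [(0, 0), (0, 1), (1, 1)]
    for s in range(n_random):
        for j in range(n):
            if spec.noise_rate and rng.random() < spec.noise_rate:
                others = [g for g in gt_states if g != genotypes[s, j]]
                genotypes[s, j] = others[int(rng.integers(0, len(others)))]
            if spec.missing_rate and rng.random() < spec.missing_rate:
                genotypes[s, j] = None

    # --- truth tables
    truth_sites: list[TruthSite] = []
    for s, (chrom, pos, ref, alt) in enumerate(site_alleles):
        called = [g for g in genotypes[s] if g is not None]
        total = 2 * len(called)
        alt_count = sum(a for g in called for a in g)
        truth_sites.append(
            TruthSite(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                planted_freq=planted_freqs[s],
                empirical_freq=alt_count / total if total else 0.0,
                missing_rate=1.0 - len(called) / n,
            )
        )

    # --- VCF
    vcf_path = os.path.join(out_dir, "variants.vcf")
    all_records: list[tuple[str, int, str, str, Optional[str], list]] = []
    for s, (chrom, pos, ref, alt) in enumerate(site_alleles):
        all_records.append((chrom, pos, ref, alt, None, list(genotypes[s])))
    for e in effects:
        calls = [(1, 1) if j == 0 else (0, 0) for j in range(n)]
        ann = None
        if spec.with_ann:
            term = _ANN_TERMS.get(e.effect_class, e.effect_class)
            tid = e.transcript_id or ""
            gene = tid[:-1].replace("m", "g") + tid[-1] if tid else ""
            ann = f"{e.alt}|{term}|MODERATE|{gene}|{gene}|transcript|{tid}||"
        all_records.append((e.chrom, e.pos, e.ref, e.alt, ann, calls))
    all_records.sort(key=lambda r: (r[0], r[1]))

    header = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c},length={l}>" for c, l in sorted(spec.contigs.items())],
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(vcf_ids),
    ]
    body = []
    for chrom, pos, ref, alt, ann, calls in all_records:
        info = f"ANN={ann}" if ann else "."
        cells = []
        for g in calls:
            dp = int(rng.poisson(30)) + 1
            gq = int(rng.integers(30, 100))
            if g is None:
                cells.append(f"./.:{0}:{0}")
            else:
                cells.append(f"{g[0]}/{g[1]}:{dp}:{gq}")
        body.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t{info}\tGT:DP:GQ\t"
            + "\t".join(cells)
        )
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(header + body) + "\n")

    # --- truth TSVs
    truth_sites_path = os.path.join(out_dir, "truth_sites.tsv")
    with open(truth_sites_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tplanted_freq\tempirical_freq\tmissing_rate\n")
        for t in truth_sites:
            pf = "" if t.planted_freq is None else f"{t.planted_freq:.6f}"
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{pf}"
                f"\t{t.empirical_freq:.6f}\t{t.missing_rate:.6f}\n"
            )
    truth_haps_path = os.path.join(out_dir, "truth_haplotypes.tsv")
    with open(truth_haps_path, "w") as fh:
        fh.write("accessionName\thapClass\n")
        for acc in accessions:
            fh.write(f"{acc}\t{hap_class[acc]}\n")
    truth_effects_path = os.path.join(out_dir, "truth_effects.tsv")
    with open(truth_effects_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\teffectClass\ttranscript\n")
        for e in effects:
            fh.write(
                f"{e.chrom}\t{e.pos}\t{e.ref}\t{e.alt}\t{e.effect_class}"
                f"\t{e.transcript_id or ''}\n"
            )

    return FixtureResult(
        paths={
            "fasta": fasta_path,
            "gff": gff_path,
            "vcf": vcf_path,
            "samples": samples_path,
            "groups": groups_path,
            "truth_sites": truth_sites_path,
            "truth_haplotypes": truth_haps_path,
            "truth_effects": truth_effects_path,
        },
        truth_sites=truth_sites,
        truth_haplotypes=hap_class,
        truth_effects=effects,
        accessions=accessions,
    )
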