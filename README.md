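# varscope

Region-scoped exploration of SNP/INDEL panels: genotype-table querying and
filtering, haplotype networks, neighbour-joining trees and principal
coordinates, per-group effect frequencies, geographic allele maps, and
sample-specific consensus sequences. Everything runs on plain-text inputs
(VCF, FASTA, GFF3, TSV metadata) and is testable end-to-end with the
built-in synthetic fixture generator — no external data required.

## Inputs

- **VCF v4.2** (plain or bgzipped) with `GT`; per-sample `DP`/`GQ` and
  pipe-delimited `INFO/ANN` are used when present.
- **Reference FASTA** (`.fai` index created on demand).
- **GFF3** gene models (gene/mRNA/exon/CDS linked by `ID`/`Parent`).
- **Samples TSV** with the triple-name columns `vcfID`, `accessionName`,
  `displayName`; extra columns are free metadata (`latitude`/`longitude`
  are recognized as decimal degrees).
- **Groups TSV**: `groupID <TAB> comma,separated,accessionNames`.

Sample expressions accept accession names, `#groupId` references, `#ALL`
(every sample), and inline definitions `NewGroupA{S01, S02, S03}`. Regions
are `chrom:start-end`, `chrom:pos`, or a gene id (widened by `--flank`).
`#RAW` is reserved for retrieving the unmodified reference sequence.

## CLI

```sh
# generate a synthetic instance with truth tables
varscope fixtures --seed 1 --out demo/

# consistency checks across the five inputs
varscope validate --vcf demo/variants.vcf --fasta demo/reference.fa \
    --gff demo/annotation.gff3 --samples-tsv demo/samples.tsv \
    --groups-tsv demo/groups.tsv

# genotype table with filters
varscope vartable --config inst.cfg --region g1 --flank 500 \
    --samples "#grpA,S07" --maf 0.05 --max-missing 0.2 \
    --genotype-form bases --out table.csv

# other tabs
varscope heatmap   ... --out classes.csv --fig heatmap.png
varscope hapnet    ... --out network.json
varscope phylotree ... --method nj  --out tree.nwk
varscope phylotree ... --method mds --out coords.csv
varscope snpfreq   ... --region g1 --groups grpA,grpB --out freqs.json
varscope hapmap    ... --site 1A:232 --radius-km 100 --out geo.json
varscope seqmaker  ... --region 1A:1-200 --samples "#RAW,S01" --out seqs.fa
```

Instance paths can be given per-flag or once in a `key = value` config file
(`--config`). Data outputs (CSV/JSON/Newick/FASTA) are byte-stable for
identical inputs; time stamps appear only in figure footers and FASTA
headers and are suppressed with `--no-stamp`.

## Package layout

| module | responsibility |
| --- | --- |
| `varscope.io` | VCF/FASTA/GFF3/TSV readers, validation report |
| `varscope.query` | region and sample-expression grammars |
| `varscope.genotype` | genotype matrix, site statistics, filters, CSV export |
| `varscope.haplotypes` | haplotype collapsing, MST network, heatmap ordering |
| `varscope.phylo` | IBS distances, neighbour-joining, classical MDS, Newick |
| `varscope.effects` | codon-level effect annotation, ANN parsing, group frequencies |
| `varscope.consensus` | variant substitution into reference regions |
| `varscope.geo` | single-site geographic projection and radius merging |
| `varscope.fixtures` | synthetic instance generator with truth tables |
| `varscope.cli` | subcommand CLI composing the above |
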