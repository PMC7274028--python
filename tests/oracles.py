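"""Independent reference implementations used to check the library.

These deliberately avoid the code paths under test: the VCF scanner is plain
string splitting, translation goes through Biopython, spanning trees are
enumerated exhaustively, and additive matrices come from explicit random
trees with path-length accumulation.
"""

from __future__ import annotations

import itertools
import random

import numpy as np
from Bio.Seq import Seq


# --- plain-text VCF scanning -------------------------------------------------

def scan_vcf_text(path):
    """Parse every record of a plain VCF by string splitting.

    Returns (sample_ids, records) where each record is a dict with chrom,
    pos, ref, alt list, and per-sample GT strings.
    """
    samples = []
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            records.append(
                {
                    "chrom": fields[0],
                    "pos": int(fields[1]),
                    "ref": fields[3],
                    "alts": fields[4].split(","),
                    "gts": {
                        s: cell.split(":")[gt_idx]
                        for s, cell in zip(samples, fields[9:])
                    },
                }
            )
    return samples, records


def gt_alleles(gt: str):
    """Allele index pair or None for a GT string (half-calls are missing)."""
    parts = gt.replace("|", "/").split("/")
    if any(p in (".", "") for p in parts):
        return None
    vals = [int(p) for p in parts]
    if len(vals) == 1:
        vals = vals * 2
    return tuple(vals)


def site_freqs_from_gts(gts: dict[str, str]):
    """(alt_freq, maf, missing_rate) by direct allele counting."""
    counts: dict[int, int] = {}
    missing = 0
    for gt in gts.values():
        alleles = gt_alleles(gt)
        if alleles is None:
            missing += 1
            continue
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0, 0.0, 1.0
    alt = total - counts.get(0, 0)
    return alt / total, 1.0 - max(counts.values()) / total, missing / len(gts)


# --- translation via Biopython ----------------------------------------------

def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_substitution(ref_codon: str, alt_codon: str) -> str:
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense"


# --- exhaustive minimum spanning tree ----------------------------------------

def exhaustive_mst_weight(dist: np.ndarray) -> int:
    """Minimum total weight over all spanning trees (n <= ~7)."""
    n = dist.shape[0]
    if n == 1:
        return 0
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = None
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[rb] = ra
        if not ok:
            continue
        w = sum(dist[a, b] for a, b in subset)
        if best is None or w < best:
            best = w
    return best


# --- random additive matrices -------------------------------------------------

def random_additive_matrix(n_taxa: int, rng: random.Random):
    """Distance matrix additive on an explicit random binary tree.

    Builds the tree by repeatedly joining two random active nodes, then
    accumulates leaf-to-leaf path lengths over the adjacency.
    """
    labels = [f"T{i:02d}" for i in range(n_taxa)]
    nodes = list(range(n_taxa))
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in nodes}
    next_id = n_taxa
    active = list(nodes)
    while len(active) > 2:
        i, j = rng.sample(active, 2)
        u = next_id
        next_id += 1
        adj[u] = []
        for x in (i, j):
            w = rng.uniform(0.1, 5.0)
            adj[u].append((x, w))
            adj[x].append((u, w))
        active = [x for x in active if x not in (i, j)] + [u]
    i, j = active
    w = rng.uniform(0.1, 5.0)
    adj[i].append((j, w))
    adj[j].append((i, w))

    d = np.zeros((n_taxa, n_taxa))
    for leaf in range(n_taxa):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            cur = stack.pop()
            for nbr, w in adj[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + w
                    stack.append(nbr)
        for other in range(n_taxa):
            d[leaf, other] = dist[other]
    np.fill_diagonal(d, 0.0)
    return labels, d
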