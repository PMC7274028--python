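"""Haplotype collapsing, the MST haplotype network, and heatmap ordering.

Haplotypes here are genotype-string equivalence classes (the data are
unphased, so HET is its own state). The network is the deterministic Kruskal
minimum spanning tree over pairwise Hamming distances; node pies carry group
composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import EmptyRegionError, ParameterError, VarscopeError
from .genotype import GenotypeMatrix
from .io import GTClass

MISSING_POLICIES = ("exclude_samples", "missing_as_state")


@dataclass
class Haplotype:
    hap_id: str  # H1, H2, ... by descending size then first-seen
    signature: tuple[str, ...]  # per-site genotype state strings
    members: list[str]
    group_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    nodes: list[Haplotype]
    edges: list[tuple[str, str, int]]  # (hapId a, hapId b, Hamming weight)
    excluded: list[tuple[str, str]]  # (accessionName, reason)

    def pies(self) -> dict[str, dict[str, float]]:
        return {
            h.hap_id: {g: c / h.size for g, c in h.group_counts.items()}
            for h in self.nodes
        }

    def to_json(self) -> str:
        pies = self.pies()
        payload = {
            "nodes": [
                {"id": h.hap_id, "size": h.size, "pies": pies[h.hap_id]}
                for h in self.nodes
            ],
            "edges": [{"a": a, "b": b, "w": w} for a, b, w in self.edges],
            "excluded": [
                {"sample": s, "reason": r} for s, r in self.excluded
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def collapse_haplotypes(
    matrix: GenotypeMatrix,
    groups: Optional[dict[str, list[str]]] = None,
    missing_policy: str = "exclude_samples",
) -> tuple[list[Haplotype], list[tuple[str, str]]]:
    """Group samples with identical per-site genotype signatures.

    Under the default policy, any sample with a missing call at a kept site
    is excluded (wildcard matching could merge distinct haplotypes). Ids are
    assigned by descending member count, ties by first occurrence.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ParameterError(f"unknown missing policy {missing_policy!r}")
    if matrix.n_sites == 0:
        raise EmptyRegionError("no sites in region after filtering")
    if groups is None:
        groups = {"#ALL": list(matrix.samples)}
    membership = {
        acc: gid for gid, members in groups.items() for acc in members
    }

    sig_members: dict[tuple[str, ...], list[str]] = {}
    excluded: list[tuple[str, str]] = []
    for j, acc in enumerate(matrix.samples):
        states = tuple(row[j].state_key() for row in matrix.cells)
        if missing_policy == "exclude_samples" and "./." in states:
            excluded.append((acc, "missing_call"))
            continue
        sig_members.setdefault(states, []).append(acc)

    ordered = sorted(
        sig_members.items(),
        key=lambda kv: (-len(kv[1]), list(sig_members).index(kv[0])),
    )
    haplotypes = []
    for i, (sig, members) in enumerate(ordered, start=1):
        counts: dict[str, int] = {}
        for acc in members:
            gid = membership.get(acc)
            if gid is not None:
                counts[gid] = counts.get(gid, 0) + 1
        haplotypes.append(
            Haplotype(
                hap_id=f"H{i}",
                signature=sig,
                members=members,
                group_counts=counts,
            )
        )
    return haplotypes, excluded


def hamming(hap_a: Haplotype, hap_b: Haplotype) -> int:
    """Count of sites with differing genotype states."""
    if len(hap_a.signature) != len(hap_b.signature):
        raise VarscopeError("haplotype signature length mismatch")
    return sum(a != b for a, b in zip(hap_a.signature, hap_b.signature))


def haplotype_distance_matrix(haplotypes: list[Haplotype]) -> np.ndarray:
    n = len(haplotypes)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hamming(haplotypes[i], haplotypes[j])
    return d


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_network(
    haplotypes: list[Haplotype],
    excluded: Optional[list[tuple[str, str]]] = None,
) -> HaplotypeNetwork:
    """Kruskal MST over the complete Hamming graph.

    Edges are sorted by (weight, ordinal node-id pair), making the tree fully
    deterministic under tied weights.
    """
    if not haplotypes:
        raise ParameterError("need at least one haplotype")
    d = haplotype_distance_matrix(haplotypes)
    n = len(haplotypes)
    ids = [h.hap_id for h in haplotypes]
    candidates = sorted(
        (
            (int(d[i, j]), *sorted((ids[i], ids[j])), i, j)
            for i in range(n)
            for j in range(i + 1, n)
        ),
        key=lambda e: (e[0], e[1], e[2]),
    )
    uf = _UnionFind(n)
    edges: list[tuple[str, str, int]] = []
    for w, a, b, i, j in candidates:
        if uf.union(i, j):
            edges.append((a, b, w))
            if len(edges) == n - 1:
                break
    return HaplotypeNetwork(
        nodes=list(haplotypes), edges=edges, excluded=list(excluded or [])
    )


# ---------------------------------------------------------------------------
# Heatmap ordering

_CLASS_CODE = {
    GTClass.REF_HOM: 0,
    GTClass.HET: 1,
    GTClass.ALT_HOM: 2,
    GTClass.MISSING: 3,
}


@dataclass
class HeatmapLayout:
    sample_order: list[str]
    site_positions: list[int]
    grid: list[list[int]]  # class codes; sites x samples unless transposed
    orientation: str


def _pairwise_deletion_distance(col_a, col_b) -> float:
    comparable = 0
    diff = 0
    for a, b in zip(col_a, col_b):
        if a.alleles is None or b.alleles is None:
            continue
        comparable += 1
        if a.state_key() != b.state_key():
            diff += 1
    if comparable == 0:
        return 1.0
    return diff / comparable


def heatmap_layout(
    matrix: GenotypeMatrix,
    groups: Optional[dict[str, list[str]]] = None,
    orientation: str = "sites_by_rows",
) -> HeatmapLayout:
    """Within-group average-linkage ordering over normalized Hamming distance.

    Groups keep their given order; within a group the sample order is the
    dendrogram leaf order (ties resolved by scipy's deterministic algorithm,
    which preserves input order for equal merges).
    """
    if orientation not in ("sites_by_rows", "transposed"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    if groups is None:
        groups = {"#ALL": list(matrix.samples)}

    columns = {acc: matrix.column(acc) for acc in matrix.samples}
    sample_order: list[str] = []
    for gid, members in groups.items():
        members = [m for m in members if m in columns]
        if len(members) <= 1:
            sample_order.extend(members)
            continue
        n = len(members)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _pairwise_deletion_distance(
                    columns[members[i]], columns[members[j]]
                )
        order = leaves_list(linkage(squareform(d, checks=False), method="average"))
        sample_order.extend(members[i] for i in order)

    idx = [matrix.samples.index(a) for a in sample_order]
    grid = [
        [_CLASS_CODE[row[j].klass] for j in idx] for row in matrix.cells
    ]
    if orientation == "transposed":
        grid = [list(col) for col in zip(*grid)] if grid else []
    return HeatmapLayout(
        sample_order=sample_order,
        site_positions=[s.pos for s in matrix.sites],
        grid=grid,
        orientation=orientation,
    )
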