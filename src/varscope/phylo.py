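"""Sample distances, neighbour-joining, and classical multidimensional scaling.

The default distance is the identity-by-state allele-sharing distance for
unphased diploid genotypes; a p-distance (any-difference) mode is available.
NJ is the classical Q-criterion agglomeration and is exact on additive
matrices; ties are broken by the lexicographically smallest leaf label so the
result is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError, VarscopeError
from .genotype import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise VarscopeError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise VarscopeError("distance matrix not symmetric")


@dataclass
class TreeNode:
    """Unrooted tree node; the top node has 3 children for n ≥ 3 leaves."""

    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def _site_ibs(a, b) -> Optional[float]:
    """Per-site allele-sharing distance, None when not comparable."""
    if a.alleles is None or b.alleles is None:
        return None
    sa, sb = sorted(a.alleles), sorted(b.alleles)
    shared = 0
    used = [False, False]
    for x in sa:
        for k, y in enumerate(sb):
            if not used[k] and x == y:
                used[k] = True
                shared += 1
                break
    return 1.0 - shared / 2.0


def _site_pdist(a, b) -> Optional[float]:
    if a.alleles is None or b.alleles is None:
        return None
    return 0.0 if a.state_key() == b.state_key() else 1.0


def distance_matrix(
    matrix: GenotypeMatrix,
    method: str = "ibs",
    labels: Optional[list[str]] = None,
) -> DistanceMatrix:
    """Pairwise sample distances averaged over comparable sites.

    Missing data is handled by pairwise deletion; a pair with zero comparable
    sites gets distance 1 with a warning.
    """
    if matrix.n_samples < 2:
        raise ParameterError("need at least 2 samples for a distance matrix")
    if matrix.n_sites < 1:
        raise ParameterError("need at least 1 site for a distance matrix")
    site_fn = {"ibs": _site_ibs, "pdist": _site_pdist}.get(method)
    if site_fn is None:
        raise ParameterError(f"unknown distance method {method!r}")
    labels = labels if labels is not None else list(matrix.samples)
    cols = [matrix.column(a) for a in matrix.samples]
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = [site_fn(a, b) for a, b in zip(cols[i], cols[j])]
            vals = [v for v in vals if v is not None]
            if not vals:
                log.warning(
                    "no comparable sites for pair (%s, %s); distance set to 1",
                    labels[i],
                    labels[j],
                )
                d[i, j] = d[j, i] = 1.0
            else:
                d[i, j] = d[j, i] = sum(vals) / len(vals)
    return DistanceMatrix(labels=list(labels), d=d)


# alias matching the operation surface
ibs_distance_matrix = distance_matrix


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Classical neighbour-joining; exact on additive matrices.

    Negative estimated branch lengths are clamped to 0 (the original value is
    logged). When several pairs minimize Q, the pair whose subtrees contain
    the lexicographically smallest leaf labels is merged.
    """
    n = len(D.labels)
    if n < 3:
        raise ParameterError("neighbour-joining needs at least 3 samples")

    nodes: dict[int, TreeNode] = {i: TreeNode(name=lab) for i, lab in enumerate(D.labels)}
    keys: dict[int, str] = {i: lab for i, lab in enumerate(D.labels)}  # min leaf label
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.d[i, j])

    def get(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return dist[(i, j) if i < j else (j, i)]

    def clamp(x: float) -> float:
        if x < 0:
            log.debug("clamping negative branch length %.6g to 0", x)
            return 0.0
        return x

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        dij = get(i, j)
        li = clamp(dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = clamp(dij - li)
        u = next_id
        next_id += 1
        nodes[u] = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        keys[u] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            duk = (get(i, k) + get(j, k) - dij) / 2.0
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = clamp((get(i, j) + get(i, k) - get(j, k)) / 2.0)
    lj = clamp((get(i, j) + get(j, k) - get(i, k)) / 2.0)
    lk = clamp((get(i, k) + get(j, k) - get(i, j)) / 2.0)
    return TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])


def tree_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (independent of NJ order)."""
    # build adjacency over object identity
    adj: dict[int, list[tuple[TreeNode, float]]] = {}
    index: dict[int, TreeNode] = {}

    def walk(node: TreeNode) -> None:
        index[id(node)] = node
        adj.setdefault(id(node), [])
        for child, length in node.children:
            adj[id(node)].append((child, length))
            adj.setdefault(id(child), []).append((node, length))
            walk(child)

    walk(tree)
    leaves = sorted(tree.leaves(), key=lambda l: l.name)
    labels = [l.name for l in leaves]
    n = len(leaves)
    d = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        # BFS from each leaf
        seen = {id(leaf): 0.0}
        stack = [leaf]
        while stack:
            cur = stack.pop()
            for nbr, length in adj[id(cur)]:
                if id(nbr) not in seen:
                    seen[id(nbr)] = seen[id(cur)] + length
                    stack.append(nbr)
        for j, other in enumerate(leaves):
            d[i, j] = seen[id(other)]
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=d)


def classical_mds(D: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Torgerson principal-coordinates embedding.

    Double-centers −½D², keeps the top-k eigenpairs with eigenvalues clipped
    at 0 (small negatives are warned about), and fixes each axis sign so its
    largest-magnitude coordinate is positive.
    """
    n = len(D.labels)
    if k < 1 or k >= n:
        raise ParameterError("need 1 <= k < number of labels")
    d2 = np.asarray(D.d) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.any(vals < -1e-8 * max(1.0, abs(vals[0]))):
        log.warning("negative eigenvalues in classical MDS; truncating at 0")
    vals = np.clip(vals[:k], 0.0, None)
    coords = vecs[:, :k] * np.sqrt(vals)
    for axis in range(k):
        col = coords[:, axis]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords


# ---------------------------------------------------------------------------
# Newick serialization

_NEEDS_QUOTE = set(" ()[]:;,'\"")


def _newick_label(name: str) -> str:
    if any(c in _NEEDS_QUOTE for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: TreeNode) -> str:
    """Serialize with branch lengths; labels with spaces are quoted."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return _newick_label(node.name or "")
        inner = ",".join(
            f"{fmt(child)}:{length:.10g}" for child, length in node.children
        )
        label = _newick_label(node.name) if node.name else ""
        return f"({inner}){label}"

    return fmt(tree) + ";"
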